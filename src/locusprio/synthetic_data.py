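"""Pedigree-sequencing simulator for end-to-end validation of the pipeline.

The generator emulates the study design the analysis assumes: an autosomal-
dominant, fully penetrant disorder segregating in a single family previously
mapped to a two-interval locus on chromosome 20; targeted sequencing of four
affected and four unaffected members plus unrelated unaffected controls; an
extended cohort (seven affected, twelve unaffected) genotyped for follow-up
screening; and two pseudo-callers that observe the same truth with
independent per-caller dropout and caller-private false-positive calls.

The family is modelled as one founder couple (one affected carrier, one
unaffected non-carrier) and their children. The planted causal variant is
heterozygous in every affected member and absent in unaffected members and
controls (dominance with full penetrance and no phenocopies). Background
polymorphisms receive population MAFs from a scaled Beta distribution,
founder genotypes under Hardy-Weinberg, and are transmitted through the
pedigree one random parental allele each, independently per variant (free
recombination; only the planted variant is linked to affection status).

Read evidence: per-sample depth is negative binomial (overdispersed
Poisson), alt reads binomial around the genotype's expected fraction, and
the site quality normal around a comfortably passing mean — so default data
mostly pass the evidence criteria, while the tails exercise them. Setting
``depth_dispersion=0`` / ``het_af_noise=0`` / ``quality_sd=0`` switches the
corresponding source of noise off deterministically (see
:func:`noiseless_config`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation_engine import GeneModel, TranscriptModel, write_gene_model_tsv
from .errors import ConfigurationError
from .filter_cascade import CascadeConfig, run_cascade
from .segregation_screen import CnvCall
from .variant_model import (
    CallSet,
    FrequencyEntry,
    FrequencyTable,
    Genotype,
    IntervalSet,
    Pedigree,
    PedigreeMember,
    ReferenceContext,
    SampleCall,
    Variant,
    VariantKey,
    merge_callsets,
    write_vcf,
)

_BASES = "ACGT"

#: the linked, capture-enriched locus: two intervals around the centromere
DEFAULT_LOCUS = (
    ("chr20", 17_316_434, 26_319_280),
    ("chr20", 29_420_138, 31_826_081),
)


@dataclass(frozen=True)
class PlantedVariant:
    """Where and what the causal variant is; default: an SNV 300 bp upstream
    of a synthetic coding gene (a promoter variant, the scenario the locus
    screen was designed to catch)."""

    chrom: str = "chr20"
    pos: int = 18_300_250
    ref: str = "T"
    alt: str = "C"


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Cohort sizes default to the emulated design: 4 + 4 NGS members,
    7 + 12 extended members, 100 unrelated unaffected controls.
    """

    seed: int = 0
    locus: tuple = DEFAULT_LOCUS
    n_affected_ngs: int = 4
    n_unaffected_ngs: int = 4
    n_extended_affected: int = 7
    n_extended_unaffected: int = 12
    n_controls: int = 100
    n_background_variants: int = 300
    #: fraction of background variants placed outside the enriched locus
    offtarget_fraction: float = 0.10
    #: fraction of background variants that are small indels
    indel_fraction: float = 0.10
    #: population MAF ~ 0.5 * Beta(a, b): mostly rare, some common
    maf_beta: tuple[float, float] = (0.8, 3.0)
    #: fraction of background variants absent from the frequency resource
    novel_fraction: float = 0.10
    #: deep targeted capture of a ~11 Mb locus in few samples
    mean_depth: float = 150.0
    #: negative-binomial size parameter; 0 = deterministic depth
    depth_dispersion: float = 10.0
    #: Beta concentration of the het alt-read fraction; 0 = exactly 0.5
    het_af_noise: float = 400.0
    #: site quality ~ Normal(quality_mean, quality_sd), clipped at 0
    quality_mean: float = 60.0
    quality_sd: float = 12.0
    #: per-caller probability of dropping a true variant record
    caller_dropout: float = 0.02
    #: caller-private false-positive calls per Mb of locus
    caller_fp_rate: float = 2.0
    planted: PlantedVariant = field(default_factory=PlantedVariant)
    #: when set, the planted variant appears in the frequency resource with
    #: this MAF (it is otherwise novel/private to the family)
    planted_maf: Optional[float] = None

    def __post_init__(self) -> None:
        counts = (
            self.n_affected_ngs,
            self.n_unaffected_ngs,
            self.n_extended_affected,
            self.n_extended_unaffected,
            self.n_controls,
            self.n_background_variants,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("cohort/variant counts must be >= 0")
        for p in (
            self.offtarget_fraction,
            self.indel_fraction,
            self.novel_fraction,
            self.caller_dropout,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability out of [0,1]: {p}")
        in_locus = any(
            chrom == self.planted.chrom and lo <= self.planted.pos <= hi
            for chrom, lo, hi in self.locus
        )
        if not in_locus:
            raise ConfigurationError("planted variant must lie inside the locus")


def noiseless_config(**overrides) -> SimConfig:
    """A configuration with every stochastic nuisance switched off:
    deterministic deep coverage, exact 0.5 het fractions, fixed quality,
    no caller dropout or false positives, and no background variants shared
    by the whole affected cohort (none are planted on the disease haplotype).
    """
    defaults = dict(
        depth_dispersion=0.0,
        het_af_noise=0.0,
        quality_sd=0.0,
        caller_dropout=0.0,
        caller_fp_rate=0.0,
        mean_depth=100.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

@dataclass
class Truth:
    """Per-sample genotypes for planted + background variants, plus every
    companion input the pipeline needs (pedigree, locus, frequencies,
    reference context, gene model, extended genotypes, CNV calls)."""

    config: SimConfig
    pedigree: Pedigree
    variants: dict[VariantKey, Variant]
    planted_key: VariantKey
    #: key -> sample -> (allele1, allele2); child order: (from father, from mother)
    haplotypes: dict[VariantKey, dict[str, tuple[int, int]]]
    mafs: dict[VariantKey, float]
    frequencies: FrequencyTable
    intervals: IntervalSet
    reference: ReferenceContext
    gene_model: GeneModel
    cnvs: list[CnvCall]

    def genotype(self, key: VariantKey, sample: str) -> Genotype:
        a1, a2 = self.haplotypes[key][sample]
        n = a1 + a2
        return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n]

    def n_alt(self, key: VariantKey, sample: str) -> int:
        a1, a2 = self.haplotypes[key][sample]
        return a1 + a2

    def ngs_and_control_samples(self) -> list[str]:
        return self.pedigree.samples("ngs") + self.pedigree.samples("control")

    def extended_genotypes(self) -> dict[VariantKey, dict[str, Genotype]]:
        ext = self.pedigree.samples("extended")
        return {
            key: {s: self.genotype(key, s) for s in ext}
            for key in self.variants
        }


def _build_pedigree(cfg: SimConfig) -> tuple[Pedigree, list[str], list[str]]:
    """One founder couple and their children, sized to the configured cohorts.

    Returns (pedigree, founder_ids, child_ids). The first affected NGS
    member and the first unaffected NGS member are the founder couple.
    """
    members = []
    aff_ngs = [f"A{i:02d}" for i in range(1, cfg.n_affected_ngs + 1)]
    unaff_ngs = [f"U{i:02d}" for i in range(1, cfg.n_unaffected_ngs + 1)]
    aff_ext = [f"EA{i:02d}" for i in range(1, cfg.n_extended_affected + 1)]
    unaff_ext = [f"EU{i:02d}" for i in range(1, cfg.n_extended_unaffected + 1)]
    controls = [f"C{i:03d}" for i in range(1, cfg.n_controls + 1)]
    members += [PedigreeMember(s, True, "ngs") for s in aff_ngs]
    members += [PedigreeMember(s, False, "ngs") for s in unaff_ngs]
    members += [PedigreeMember(s, True, "extended") for s in aff_ext]
    members += [PedigreeMember(s, False, "extended") for s in unaff_ext]
    members += [PedigreeMember(s, False, "control") for s in controls]
    ped = Pedigree(members)
    if cfg.n_affected_ngs < 1 or cfg.n_unaffected_ngs < 1:
        raise ConfigurationError("NGS cohort needs >= 1 affected and unaffected")
    founders = [aff_ngs[0], unaff_ngs[0]]
    children = aff_ngs[1:] + unaff_ngs[1:] + aff_ext + unaff_ext
    return ped, founders, children


def _default_gene_model(planted: PlantedVariant) -> GeneModel:
    """A minimal synthetic coding gene whose promoter contains the planted
    variant (TSS 300 bp downstream on the plus strand)."""
    tss = planted.pos + 300
    return GeneModel(
        [
            TranscriptModel(
                gene_symbol="SYNGENE1",
                transcript_id="SYNT0001",
                biotype="protein-coding",
                strand="+",
                exons=[(tss, tss + 1000)],
                chrom=planted.chrom,
                cds_start=tss + 100,
                cds_end=tss + 699,
            )
        ],
        tag="synthetic",
    )


def _locus_spans(cfg: SimConfig) -> list[tuple[str, int, int]]:
    return [(c, lo, hi) for c, lo, hi in cfg.locus]


_OFFTARGET_SPANS = (
    ("chr20", 16_800_000, 17_316_433),  # proximal flank
    ("chr20", 26_319_281, 29_420_137),  # centromeric gap
    ("chr20", 31_826_082, 32_500_000),  # distal flank
)


def _draw_positions(
    rng: np.random.Generator,
    spans: list[tuple[str, int, int]],
    n: int,
    taken: set[tuple[str, int]],
) -> list[tuple[str, int]]:
    lengths = np.array([hi - lo + 1 for _, lo, hi in spans], dtype=float)
    probs = lengths / lengths.sum()
    out: list[tuple[str, int]] = []
    while len(out) < n:
        i = rng.choice(len(spans), p=probs)
        chrom, lo, hi = spans[i]
        pos = int(rng.integers(lo, hi + 1))
        # resample on collision with an existing variant position
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        out.append((chrom, pos))
    return out


def simulate_truth(cfg: SimConfig) -> Truth:
    """Deterministically (given ``cfg.seed``) generate the full truth set."""
    rng = np.random.default_rng(cfg.seed)
    ped, founders, children = _build_pedigree(cfg)
    father, mother = founders  # affected founder, unaffected founder
    affected = set(
        m.sample_id for m in ped.members if m.affected and m.cohort != "control"
    )
    family = [father, mother] + children
    controls = ped.samples("control")

    reference = ReferenceContext()
    variants: dict[VariantKey, Variant] = {}
    mafs: dict[VariantKey, float] = {}
    freq_entries: dict[VariantKey, FrequencyEntry] = {}

    # --- planted variant -------------------------------------------------
    planted = cfg.planted
    seg_start = planted.pos - 60
    flank = "".join(rng.choice(list(_BASES), size=121))
    seg = flank[:60] + planted.ref + flank[61:]
    reference.add(planted.chrom, seg_start, seg)
    planted_v = Variant(planted.chrom, planted.pos, planted.ref, planted.alt)
    variants[planted_v.key] = planted_v
    mafs[planted_v.key] = 0.0  # private to the family; novel by default
    if cfg.planted_maf is not None:
        freq_entries[planted_v.key] = FrequencyEntry(
            "rsP00001", cfg.planted_maf
        )

    taken = {(planted.chrom, planted.pos)}
    n_off = int(round(cfg.offtarget_fraction * cfg.n_background_variants))
    n_on = cfg.n_background_variants - n_off
    positions = _draw_positions(rng, _locus_spans(cfg), n_on, taken)
    positions += _draw_positions(rng, list(_OFFTARGET_SPANS), n_off, taken)

    # --- background variants ---------------------------------------------
    a, b = cfg.maf_beta
    for chrom, pos in positions:
        ctx = "".join(rng.choice(list(_BASES), size=41))
        is_indel = rng.random() < cfg.indel_fraction
        anchor = ctx[20]
        if not is_indel:
            alt = rng.choice([x for x in _BASES if x != anchor])
            ref_allele, alt_allele = anchor, str(alt)
        elif rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 4))))
            ref_allele, alt_allele = anchor, anchor + ins
        else:  # deletion of 1-3 following bases
            d = int(rng.integers(1, 4))
            ref_allele, alt_allele = ctx[20 : 21 + d], anchor
        reference.add(chrom, pos - 20, ctx)
        maf = float(0.5 * rng.beta(a, b))
        v = Variant(chrom, pos, ref_allele, alt_allele)
        variants[v.key] = v
        mafs[v.key] = maf
        if rng.random() >= cfg.novel_fraction:
            rsid = f"rsS{len(freq_entries) + 1:05d}"
            v = Variant(chrom, pos, ref_allele, alt_allele, rsid)
            variants[v.key] = v
            freq_entries[v.key] = FrequencyEntry(rsid, round(maf, 4))

    # --- genotypes --------------------------------------------------------
    haplotypes: dict[VariantKey, dict[str, tuple[int, int]]] = {}
    child_list = list(children)
    for key in variants:
        hap: dict[str, tuple[int, int]] = {}
        if key == planted_v.key:
            # haplotype 0 of the affected founder carries the causal allele
            hap[father] = (1, 0)
            hap[mother] = (0, 0)
            for c in child_list:
                from_father = 1 if c in affected else 0
                hap[c] = (from_father, 0)
            for s in controls:
                hap[s] = (0, 0)
        else:
            p = mafs[key]
            for s in [father, mother] + controls:
                hap[s] = (
                    int(rng.random() < p),
                    int(rng.random() < p),
                )
            for c in child_list:
                hap[c] = (
                    hap[father][int(rng.integers(0, 2))],
                    hap[mother][int(rng.integers(0, 2))],
                )
        haplotypes[key] = hap

    # --- companion structures ---------------------------------------------
    intervals = IntervalSet(_locus_spans(cfg))
    gene_model = _default_gene_model(planted)
    # reference over the synthetic gene span (for consequence classification)
    t = gene_model.transcripts[0]
    span_seq = "".join(rng.choice(list(_BASES), size=t.tx_end - t.tx_start + 1))
    reference.add(t.chrom, t.tx_start, span_seq)

    cnvs = _simulate_cnvs(rng, ped, cfg)
    return Truth(
        config=cfg,
        pedigree=ped,
        variants=variants,
        planted_key=planted_v.key,
        haplotypes=haplotypes,
        mafs=mafs,
        frequencies=FrequencyTable(freq_entries),
        intervals=intervals,
        reference=reference,
        gene_model=gene_model,
        cnvs=cnvs,
    )


def _simulate_cnvs(
    rng: np.random.Generator, ped: Pedigree, cfg: SimConfig
) -> list[CnvCall]:
    """A CNV table with one event shared by all affected NGS members and a
    handful of private events."""
    affected = ped.affected("ngs")
    others = ped.unaffected("ngs")
    cnvs: list[CnvCall] = []
    chrom = cfg.planted.chrom
    shared_start = cfg.planted.pos + 50_000
    cnvs += [
        CnvCall(s, chrom, shared_start, shared_start + 317, "loss")
        for s in affected
    ]
    pool = affected + others
    for _ in range(6):
        s = pool[int(rng.integers(0, len(pool)))]
        start = int(rng.integers(17_400_000, 26_000_000))
        size = int(rng.integers(121, 413_067))
        kind = "gain" if rng.random() < 0.5 else "loss"
        cnvs.append(CnvCall(s, chrom, start, start + size - 1, kind))
    return cnvs


# ---------------------------------------------------------------------------
# Pseudo-callers
# ---------------------------------------------------------------------------

def _site_quality(rng: np.random.Generator, cfg: SimConfig) -> float:
    if cfg.quality_sd == 0:
        return cfg.quality_mean
    return float(max(0.0, rng.normal(cfg.quality_mean, cfg.quality_sd)))


def _sample_depth(rng: np.random.Generator, cfg: SimConfig) -> int:
    if cfg.depth_dispersion == 0:
        return int(round(cfg.mean_depth))
    r = cfg.depth_dispersion
    p = r / (r + cfg.mean_depth)
    return int(rng.negative_binomial(r, p))


def _het_fraction(rng: np.random.Generator, cfg: SimConfig) -> float:
    if cfg.het_af_noise == 0:
        return 0.5
    k = cfg.het_af_noise
    return float(rng.beta(0.5 * k, 0.5 * k))


def make_callsets(truth: Truth, cfg: Optional[SimConfig] = None) -> tuple[CallSet, CallSet]:
    """Emit two pseudo-caller call sets over the NGS + control samples.

    Each caller independently drops true variant records with probability
    ``caller_dropout`` and injects caller-private false-positive SNVs at
    ``caller_fp_rate`` per Mb (low quality, singleton carriers), so the
    expected concordance partition is predictable from the configuration.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    samples = truth.ngs_and_control_samples()
    locus_bp = sum(hi - lo + 1 for _, lo, hi in cfg.locus)
    callsets = []
    taken = {(c, p) for c, p, _, _ in truth.variants}
    for label in ("callerA", "callerB"):
        cs = CallSet(caller=label, reference=truth.reference)
        cs.samples = list(samples)
        for key in truth.variants:
            if rng.random() < cfg.caller_dropout:
                continue
            v = truth.variants[key]
            qual = _site_quality(rng, cfg)
            cs.add_variant(v, qual)
            for s in samples:
                gt = truth.genotype(key, s)
                depth = _sample_depth(rng, cfg)
                if depth == 0:
                    cs.add_call(
                        SampleCall(s, key, Genotype.MISSING, 0, qual, None)
                    )
                    continue
                if gt is Genotype.HET:
                    p_alt = _het_fraction(rng, cfg)
                elif gt is Genotype.HOM_ALT:
                    p_alt = 0.98
                else:
                    p_alt = 0.005
                if cfg.het_af_noise == 0 and cfg.depth_dispersion == 0:
                    alt_reads = int(round(depth * p_alt))
                else:
                    alt_reads = int(rng.binomial(depth, p_alt))
                cs.add_call(
                    SampleCall(
                        s,
                        key,
                        gt,
                        depth,
                        qual,
                        alt_reads / depth,
                        ad=(depth - alt_reads, alt_reads),
                    )
                )
        n_fp = (
            rng.poisson(cfg.caller_fp_rate * locus_bp / 1e6)
            if cfg.caller_fp_rate > 0
            else 0
        )
        for _ in range(int(n_fp)):
            spans = _locus_spans(cfg)
            while True:
                chrom, pos = _draw_positions(rng, spans, 1, set(taken))[0]
                if (chrom, pos) not in taken:
                    break
            taken.add((chrom, pos))
            ref, alt = rng.choice(list(_BASES), size=2, replace=False)
            fp = Variant(chrom, pos, str(ref), str(alt))
            qual = float(rng.exponential(8.0))
            cs.add_variant(fp, qual)
            lucky = samples[int(rng.integers(0, len(samples)))]
            depth = max(1, _sample_depth(rng, cfg))
            alt_reads = int(rng.binomial(depth, rng.beta(2, 2)))
            cs.add_call(
                SampleCall(
                    lucky,
                    fp.key,
                    Genotype.HET,
                    depth,
                    qual,
                    alt_reads / depth,
                    ad=(depth - alt_reads, alt_reads),
                )
            )
            for s in samples:
                if s != lucky:
                    cs.add_call(
                        SampleCall(
                            s, fp.key, Genotype.HOM_REF, _sample_depth(rng, cfg), qual, 0.0
                        )
                    )
        callsets.append(cs)
    return callsets[0], callsets[1]


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def emit_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write every pipeline input to ``outdir``.

    Identical configurations (including the seed) produce byte-identical
    files. Returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(cfg)
    cs_a, cs_b = make_callsets(truth, cfg)
    paths = {
        "caller_a": outdir / "caller_a.vcf",
        "caller_b": outdir / "caller_b.vcf",
        "pedigree": outdir / "family.ped",
        "intervals": outdir / "locus.bed",
        "frequencies": outdir / "frequencies.tsv",
        "gene_model": outdir / "gene_model.tsv",
        "reference": outdir / "reference.fa",
        "cnvs": outdir / "cnvs.tsv",
        "extended_genotypes": outdir / "extended_genotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(cs_a, paths["caller_a"])
    write_vcf(cs_b, paths["caller_b"])

    with open(paths["pedigree"], "w") as fh:
        father = truth.pedigree.affected("ngs")[0]
        mother = truth.pedigree.unaffected("ngs")[0]
        for m in truth.pedigree.members:
            fam = "CTRL" if m.cohort == "control" else "FAM1"
            is_founder = m.sample_id in (father, mother) or m.cohort == "control"
            pat = "0" if is_founder else father
            mat = "0" if is_founder else mother
            sex = "1" if m.sample_id == father else "2" if m.sample_id == mother else "0"
            pheno = "2" if m.affected else "1"
            fh.write(
                f"{fam}\t{m.sample_id}\t{pat}\t{mat}\t{sex}\t{pheno}\t{m.cohort}\n"
            )

    with open(paths["intervals"], "w") as fh:
        for chrom, lo, hi in cfg.locus:
            fh.write(f"{chrom}\t{lo - 1}\t{hi}\n")

    with open(paths["frequencies"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\trsid\tmaf\n")
        for key, entry in sorted(truth.frequencies.items()):
            chrom, pos, ref, alt = key
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{entry.rsid}\t{entry.maf}\n"
            )

    write_gene_model_tsv(truth.gene_model, paths["gene_model"])
    truth.reference.to_fasta(paths["reference"])

    with open(paths["cnvs"], "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tkind\n")
        for c in truth.cnvs:
            fh.write(f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.kind}\n")

    with open(paths["extended_genotypes"], "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\tgenotype\n")
        for key, by_sample in truth.extended_genotypes().items():
            chrom, pos, ref, alt = key
            for s, gt in by_sample.items():
                fh.write(f"{s}\t{chrom}\t{pos}\t{ref}\t{alt}\t{gt.value}\n")

    truth_doc = {
        "seed": cfg.seed,
        "planted": list(truth.planted_key),
        "n_variants": len(truth.variants),
        "genotypes": {
            "{}:{}:{}>{}".format(*key): {
                s: truth.n_alt(key, s)
                for s in truth.pedigree.samples()
            }
            for key in truth.variants
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# End-to-end recovery experiment
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    n_reps: int
    recovered: list[bool]
    background_survivors: list[int]

    @property
    def recovery_rate(self) -> float:
        return sum(self.recovered) / len(self.recovered) if self.recovered else 0.0


def run_replicate(
    cfg: SimConfig, cascade_config: Optional[CascadeConfig] = None
) -> tuple[Truth, set[VariantKey]]:
    """One simulate -> merge-callers -> cascade pass; returns survivors."""
    truth = simulate_truth(cfg)
    cs_a, cs_b = make_callsets(truth, cfg)
    merged = merge_callsets(cs_a, cs_b, mode="union")
    report = run_cascade(
        merged,
        truth.pedigree,
        truth.intervals,
        truth.frequencies,
        cascade_config,
    )
    return truth, report.survivors


def recovery_experiment(
    cfg: SimConfig,
    n_reps: int = 100,
    cascade_config: Optional[CascadeConfig] = None,
) -> RecoveryResult:
    """Fraction of replicates in which the planted variant survives all
    seven criteria, and the per-replicate count of surviving background
    variants. Replicate ``i`` reseeds the generator at ``cfg.seed + i``."""
    recovered, background = [], []
    for i in range(n_reps):
        rep_cfg = dataclasses.replace(cfg, seed=cfg.seed + i)
        truth, survivors = run_replicate(rep_cfg, cascade_config)
        recovered.append(truth.planted_key in survivors)
        background.append(len(survivors - {truth.planted_key}))
    return RecoveryResult(
        n_reps=n_reps, recovered=recovered, background_survivors=background
    )
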