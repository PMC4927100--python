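"""Transcript-aware functional classification of candidate variants.

A variant is classified against each overlapping transcript into one of:
missense, nonsense, synonymous, splice5, splice3, utr5, utr3, promoter,
intronic, ncRNA, intergenic. The per-transcript rows are the native output
(one variant may be, e.g., intronic for one gene and a promoter variant of a
neighbouring gene); a single "worst consequence" per variant is a derived
view.

Labels are simplified HGVS-like strings (c.327C>A, c.-307T>C, c.*351A>G,
n.-72A>T). The ref/alt alleles are printed exactly as supplied with the
variant — no strand complementing — matching the convention of caller-centric
candidate tables; strand affects only position arithmetic and which side of a
transcript counts as upstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Seq import Seq

from .errors import AnnotationError, GeneModelError
from .filter_cascade import ConcordancePartition, concordance
from .variant_model import (
    ReferenceContext,
    Variant,
    VariantClass,
    VariantKey,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

logger = logging.getLogger(__name__)


class Category(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    SPLICE5 = "splice5"
    SPLICE3 = "splice3"
    UTR5 = "utr5"
    UTR3 = "utr3"
    PROMOTER = "promoter"
    INTRONIC = "intronic"
    NCRNA = "ncRNA"
    INTERGENIC = "intergenic"


#: Derived-view precedence, most deleterious first.
SEVERITY_ORDER = [
    Category.NONSENSE,
    Category.MISSENSE,
    Category.SPLICE5,
    Category.SPLICE3,
    Category.SYNONYMOUS,
    Category.UTR5,
    Category.UTR3,
    Category.PROMOTER,
    Category.NCRNA,
    Category.INTRONIC,
    Category.INTERGENIC,
]

#: Categories that by default disqualify a variant when they are all it has.
NON_CANDIDATE_CATEGORIES = frozenset(
    {Category.INTRONIC, Category.NCRNA, Category.INTERGENIC}
)

PROTEIN_CODING = "protein-coding"


@dataclass
class TranscriptModel:
    """Minimal transcript structure: strand, exons, optional CDS, promoter.

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order regardless of strand; exon *numbering* follows transcript
    direction. ``promoter_window`` is the upstream span (bp from the
    transcript start site) within which a variant is called a promoter
    variant.
    """

    gene_symbol: str
    transcript_id: str
    biotype: str
    strand: str
    exons: list[tuple[int, int]]
    chrom: str = "chr20"
    cds_start: Optional[int] = None  # genomic low end of the CDS
    cds_end: Optional[int] = None  # genomic high end of the CDS
    refseq_id: Optional[str] = None
    promoter_window: int = 1000

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.transcript_id}: bad strand")
        if self.promoter_window <= 0:
            raise GeneModelError(f"{self.transcript_id}: promoter_window <= 0")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 >= s2:
                raise GeneModelError(
                    f"{self.transcript_id}: overlapping/unsorted exons"
                )
        self.exons = exons
        if (self.cds_start is None) != (self.cds_end is None):
            raise GeneModelError(
                f"{self.transcript_id}: CDS must give both ends"
            )
        if self.is_coding:
            if not any(
                s <= self.cds_start <= e for s, e in self.exons
            ) or not any(s <= self.cds_end <= e for s, e in self.exons):
                raise GeneModelError(
                    f"{self.transcript_id}: CDS ends outside exons"
                )

    # -- geometry ----------------------------------------------------------

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic position of the transcript start site (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_in_order(self) -> list[tuple[int, int]]:
        """Exons in transcript direction (exon 1 first)."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end

    def upstream_distance(self, pos: int) -> Optional[int]:
        """bp from the TSS if ``pos`` is upstream of the transcript, else None."""
        if self.strand == "+" and pos < self.tx_start:
            return self.tx_start - pos
        if self.strand == "-" and pos > self.tx_end:
            return pos - self.tx_end
        return None

    def exon_number(self, pos: int) -> Optional[int]:
        for i, (s, e) in enumerate(self.exons_in_order(), start=1):
            if s <= pos <= e:
                return i
        return None

    def tpos(self, pos: int) -> int:
        """1-based position in the spliced transcript (transcript direction)."""
        if self.exon_number(pos) is None:
            raise AnnotationError(f"{pos} not exonic in {self.transcript_id}")
        t = 0
        for s, e in self.exons_in_order():
            if s <= pos <= e:
                return t + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            t += e - s + 1
        raise AssertionError("unreachable")

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcript order."""
        if not self.is_coding:
            raise AnnotationError(f"{self.transcript_id} is non-coding")
        pieces = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                pieces.append(range(lo, hi + 1))
        out = [p for piece in pieces for p in piece]
        return out if self.strand == "+" else out[::-1]

    def in_cds(self, pos: int) -> bool:
        return (
            self.is_coding
            and self.cds_start <= pos <= self.cds_end
            and self.exon_number(pos) is not None
        )

    def cds_offset(self, pos: int) -> int:
        """1-based offset of an exonic CDS position in the coding sequence."""
        first = self.cds_end if self.strand == "-" else self.cds_start
        return self.tpos(pos) - self.tpos(first) + 1


@dataclass(frozen=True)
class AnnotationRow:
    """One (variant, transcript) classification."""

    variant_key: VariantKey
    gene_symbol: Optional[str]
    transcript_id: Optional[str]
    category: Category
    biotype: Optional[str] = None
    exon_number: Optional[int] = None
    intron_number: Optional[int] = None
    offset_label: str = "-"
    refseq_id: Optional[str] = None
    source: str = "default"


@dataclass(frozen=True)
class VariantMeta:
    rsid: Optional[str] = None
    maf: Optional[float] = None
    sources: tuple[str, ...] = ()


@dataclass
class CandidateTable:
    """Annotated surviving variants, one row per (variant, transcript)."""

    rows: list[AnnotationRow] = field(default_factory=list)
    variants: dict[VariantKey, Variant] = field(default_factory=dict)
    meta: dict[VariantKey, VariantMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple, AnnotationRow] = {}
        for row in self.rows:
            seen.setdefault(
                (row.variant_key, row.transcript_id, row.source), row
            )
        self.rows = list(seen.values())

    def keys(self) -> list[VariantKey]:
        return sorted({r.variant_key for r in self.rows})

    def rows_for(self, key: VariantKey) -> list[AnnotationRow]:
        return [r for r in self.rows if r.variant_key == key]

    def genes(self) -> set[str]:
        return {r.gene_symbol for r in self.rows if r.gene_symbol}

    def worst_consequence(self, key: VariantKey) -> Category:
        cats = {r.category for r in self.rows_for(key)}
        for cat in SEVERITY_ORDER:
            if cat in cats:
                return cat
        raise KeyError(key)

    def subset(self, keys: Iterable[VariantKey]) -> "CandidateTable":
        keep = set(keys)
        return CandidateTable(
            rows=[r for r in self.rows if r.variant_key in keep],
            variants={k: v for k, v in self.variants.items() if k in keep},
            meta={k: m for k, m in self.meta.items() if k in keep},
        )

    def to_frame(self):
        import pandas as pd

        records = []
        for row in self.rows:
            chrom, pos, ref, alt = row.variant_key
            m = self.meta.get(row.variant_key, VariantMeta())
            records.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene_symbol": row.gene_symbol,
                    "rsid": m.rsid,
                    "maf": m.maf,
                    "category": row.category.value,
                    "exon": row.exon_number,
                    "intron": row.intron_number,
                    "label": row.offset_label,
                    "refseq_id": row.refseq_id,
                    "transcript_id": row.transcript_id,
                    "biotype": row.biotype,
                    "sources": ",".join(m.sources),
                }
            )
        return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Gene model containers and readers
# ---------------------------------------------------------------------------

class GeneModel:
    def __init__(self, transcripts: Iterable[TranscriptModel], tag: str = "default"):
        self.transcripts = list(transcripts)
        self.tag = tag

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        """Transcripts whose span or promoter window covers ``pos``."""
        out = []
        for t in self.transcripts:
            if t.chrom != chrom:
                continue
            d = t.upstream_distance(pos)
            if t.contains(pos) or (d is not None and d <= t.promoter_window):
                out.append(t)
        return out


def read_gene_model_tsv(path: str | Path, tag: str = "default") -> GeneModel:
    """Read the simplified TSV gene model.

    Columns: gene, transcript, refseq, biotype, chrom, strand, exons
    (``start-end`` joined by ``;``), cds_start, cds_end, promoter_window.
    Empty / ``-`` CDS columns mean non-coding.
    """
    transcripts = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"gene", "transcript", "biotype", "chrom", "strand", "exons"}
        if not required <= set(idx):
            raise GeneModelError(f"{path}: missing columns {required - set(idx)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")

            def get(name: str, nullable: bool = True) -> Optional[str]:
                if name not in idx or idx[name] >= len(cols):
                    return None
                val = cols[idx[name]].strip()
                if nullable and val in ("", "-", "."):
                    return None
                return val or None

            try:
                exons = [
                    tuple(int(x.replace(",", "")) for x in part.split("-"))
                    for part in get("exons").split(";")
                ]
                cds_s, cds_e = get("cds_start"), get("cds_end")
                transcripts.append(
                    TranscriptModel(
                        gene_symbol=get("gene"),
                        transcript_id=get("transcript"),
                        biotype=get("biotype"),
                        strand=get("strand", nullable=False),
                        exons=exons,
                        chrom=get("chrom"),
                        cds_start=int(cds_s) if cds_s else None,
                        cds_end=int(cds_e) if cds_e else None,
                        refseq_id=get("refseq"),
                        promoter_window=int(get("promoter_window") or 1000),
                    )
                )
            except (ValueError, AttributeError) as exc:
                raise GeneModelError(f"{path}: line {lineno}: {exc}") from None
    return GeneModel(transcripts, tag=tag)


def write_gene_model_tsv(model: GeneModel, path: str | Path) -> None:
    """Write a gene model in the simplified TSV layout read back by
    :func:`read_gene_model_tsv`."""
    cols = [
        "gene",
        "transcript",
        "refseq",
        "biotype",
        "chrom",
        "strand",
        "exons",
        "cds_start",
        "cds_end",
        "promoter_window",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in model:
            exons = ";".join(f"{s}-{e}" for s, e in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.gene_symbol,
                        t.transcript_id,
                        t.refseq_id or "-",
                        t.biotype,
                        t.chrom,
                        t.strand,
                        exons,
                        str(t.cds_start) if t.cds_start else "-",
                        str(t.cds_end) if t.cds_end else "-",
                        str(t.promoter_window),
                    ]
                )
                + "\n"
            )


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path, tag: str = "default", promoter_window: int = 1000) -> GeneModel:
    """Read gene models from GTF (exon and CDS features).

    Requires ``gene_name``/``gene_id`` and ``transcript_id`` attributes;
    ``gene_biotype``/``transcript_biotype`` defaults to protein-coding when a
    CDS is present, else "processed transcript".
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise GeneModelError(f"{path}: malformed GTF line")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = cols[:9]
            if feature not in ("exon", "CDS"):
                continue
            a = dict(_GTF_ATTR.findall(attrs))
            tid = a.get("transcript_id")
            if tid is None:
                raise GeneModelError(f"{path}: {feature} without transcript_id")
            info.setdefault(
                tid,
                {
                    "gene": a.get("gene_name") or a.get("gene_id") or tid,
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": a.get("transcript_biotype")
                    or a.get("gene_biotype")
                    or "",
                },
            )
            target = exons if feature == "exon" else cds
            target.setdefault(tid, []).append((int(start), int(end)))
    transcripts = []
    for tid, meta in info.items():
        cds_ivs = cds.get(tid)
        biotype = meta["biotype"] or (
            PROTEIN_CODING if cds_ivs else "processed transcript"
        )
        transcripts.append(
            TranscriptModel(
                gene_symbol=meta["gene"],
                transcript_id=tid,
                biotype=biotype,
                strand=meta["strand"],
                exons=sorted(exons.get(tid, [])),
                chrom=meta["chrom"],
                cds_start=min(s for s, _ in cds_ivs) if cds_ivs else None,
                cds_end=max(e for _, e in cds_ivs) if cds_ivs else None,
                promoter_window=promoter_window,
            )
        )
    return GeneModel(transcripts, tag=tag)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

SPLICE_WINDOW = 2  # intronic bp adjacent to each exon boundary (GT/AG)


def _codon_effect(
    v: Variant, t: TranscriptModel, ref_context: ReferenceContext
) -> Category:
    """Translate ref vs alt codon for a CDS SNV."""
    if ref_context is None:
        raise AnnotationError(
            f"codon translation for {v} in {t.transcript_id} requires "
            "reference context"
        )
    positions = t.cds_positions()
    off = t.cds_offset(v.pos)  # 1-based
    codon_idx = (off - 1) // 3
    codon_pos = positions[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon_pos) < 3:
        raise AnnotationError(
            f"{t.transcript_id}: CDS length not a multiple of 3 at its end"
        )
    bases = [ref_context.base(v.chrom, p) for p in codon_pos]
    if t.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
    within = (off - 1) % 3
    ref_base = v.ref if t.strand == "+" else v.ref.translate(_COMPLEMENT)
    alt_base = v.alt if t.strand == "+" else v.alt.translate(_COMPLEMENT)
    if bases[within] != ref_base:
        logger.warning(
            "reference context mismatch at %s:%s (context %s vs variant ref "
            "%s, cDNA sense); using the variant's ref allele",
            v.chrom,
            v.pos,
            bases[within],
            ref_base,
        )
        bases[within] = ref_base
    alt_codon = list(bases)
    alt_codon[within] = alt_base
    ref_aa = str(Seq("".join(bases)).translate())
    alt_aa = str(Seq("".join(alt_codon)).translate())
    if alt_aa == "*" and ref_aa != "*":
        return Category.NONSENSE
    if alt_aa == ref_aa:
        return Category.SYNONYMOUS
    return Category.MISSENSE


def _allele_suffix(v: Variant) -> str:
    return f"{v.ref}>{v.alt}"


def classify(
    v: Variant,
    t: TranscriptModel,
    ref_context: Optional[ReferenceContext] = None,
    source: str = "default",
) -> Optional[AnnotationRow]:
    """Classify one variant against one transcript.

    Returns ``None`` when the variant lies outside both the transcript span
    and its promoter window (the caller then decides whether the variant is
    intergenic overall). Indels are anchored at their first reference base;
    an indel overlapping the CDS is reported as protein-altering
    (``missense`` in this category scheme — there is no dedicated frameshift
    class).
    """
    pos = v.pos
    prefix = "c." if t.is_coding else "n."
    alleles = _allele_suffix(v)

    d = t.upstream_distance(pos)
    if d is not None:
        if d <= t.promoter_window:
            return AnnotationRow(
                variant_key=v.key,
                gene_symbol=t.gene_symbol,
                transcript_id=t.transcript_id,
                category=Category.PROMOTER,
                biotype=t.biotype,
                offset_label=f"{prefix}-{d}{alleles}",
                refseq_id=t.refseq_id,
                source=source,
            )
        return None
    if not t.contains(pos):
        return None  # downstream of the transcript

    exon_n = t.exon_number(pos)
    if exon_n is not None:
        if t.in_cds(pos):
            if v.vclass is VariantClass.SNV:
                category = _codon_effect(v, t, ref_context)
            else:
                category = Category.MISSENSE  # protein-altering indel
            return AnnotationRow(
                variant_key=v.key,
                gene_symbol=t.gene_symbol,
                transcript_id=t.transcript_id,
                category=category,
                biotype=t.biotype,
                exon_number=exon_n,
                offset_label=f"c.{t.cds_offset(pos)}{alleles}",
                refseq_id=t.refseq_id,
                source=source,
            )
        if t.is_coding:
            # exonic but outside the CDS: UTR, side by transcript direction
            first_cds = t.cds_end if t.strand == "-" else t.cds_start
            last_cds = t.cds_start if t.strand == "-" else t.cds_end
            if t.tpos(pos) < t.tpos(first_cds):
                off = t.tpos(first_cds) - t.tpos(pos)
                category, label = Category.UTR5, f"c.-{off}{alleles}"
            else:
                off = t.tpos(pos) - t.tpos(last_cds)
                category, label = Category.UTR3, f"c.*{off}{alleles}"
            return AnnotationRow(
                variant_key=v.key,
                gene_symbol=t.gene_symbol,
                transcript_id=t.transcript_id,
                category=category,
                biotype=t.biotype,
                exon_number=exon_n,
                offset_label=label,
                refseq_id=t.refseq_id,
                source=source,
            )
        return AnnotationRow(
            variant_key=v.key,
            gene_symbol=t.gene_symbol,
            transcript_id=t.transcript_id,
            category=Category.NCRNA,
            biotype=t.biotype,
            exon_number=exon_n,
            offset_label=f"n.{t.tpos(pos)}{alleles}",
            refseq_id=t.refseq_id,
            source=source,
        )

    # intronic; check the +/-2 bp splice windows first
    ordered = t.exons_in_order()
    for i, exon in enumerate(ordered[:-1], start=1):
        nxt = ordered[i]
        if t.strand == "+":
            donor_edge, acceptor_edge = exon[1], nxt[0]
            in_intron = donor_edge < pos < acceptor_edge
            donor_dist, acceptor_dist = pos - donor_edge, acceptor_edge - pos
        else:
            donor_edge, acceptor_edge = exon[0], nxt[1]
            in_intron = acceptor_edge < pos < donor_edge
            donor_dist, acceptor_dist = donor_edge - pos, pos - acceptor_edge
        if not in_intron:
            continue
        if donor_dist <= SPLICE_WINDOW:
            category = Category.SPLICE5
            label = f"{prefix}intron {i} donor+{donor_dist}{alleles}"
        elif acceptor_dist <= SPLICE_WINDOW:
            category = Category.SPLICE3
            label = f"{prefix}intron {i} acceptor-{acceptor_dist}{alleles}"
        else:
            category = Category.INTRONIC
            label = f"intron {i}"
        return AnnotationRow(
            variant_key=v.key,
            gene_symbol=t.gene_symbol,
            transcript_id=t.transcript_id,
            category=category,
            biotype=t.biotype,
            intron_number=i,
            offset_label=label,
            refseq_id=t.refseq_id,
            source=source,
        )
    raise AssertionError(f"position {pos} unclassifiable in {t.transcript_id}")


def intergenic_row(v: Variant, source: str = "default") -> AnnotationRow:
    return AnnotationRow(
        variant_key=v.key,
        gene_symbol=None,
        transcript_id=None,
        category=Category.INTERGENIC,
        offset_label="-",
        source=source,
    )


def annotate_all(
    variants: Iterable[Variant],
    gene_model: Union[GeneModel, Sequence[GeneModel]],
    ref_context: Optional[ReferenceContext] = None,
    meta: Optional[Mapping[VariantKey, VariantMeta]] = None,
) -> CandidateTable:
    """Annotate variants against one or more tagged gene models.

    Every variant receives at least one row (intergenic at minimum, per
    source). With two gene models, per-source rows allow an annotation
    concordance partition (see :func:`annotation_concordance`).
    """
    models = [gene_model] if isinstance(gene_model, GeneModel) else list(gene_model)
    rows: list[AnnotationRow] = []
    table_variants: dict[VariantKey, Variant] = {}
    for v in variants:
        table_variants[v.key] = v
        for model in models:
            v_rows = []
            for t in model.overlapping(v.chrom, v.pos):
                row = classify(v, t, ref_context, source=model.tag)
                if row is not None:
                    v_rows.append(row)
            if not v_rows:
                v_rows = [intergenic_row(v, source=model.tag)]
            rows.extend(v_rows)
    return CandidateTable(
        rows=rows,
        variants=table_variants,
        meta=dict(meta) if meta else {},
    )


def annotation_concordance(
    table: CandidateTable, tag_a: str, tag_b: str
) -> ConcordancePartition:
    """Partition variant keys by which gene-model source annotated them.

    A variant counts as annotated by a source when it has at least one
    non-intergenic row from that source.
    """

    def annotated(tag: str) -> set[VariantKey]:
        return {
            r.variant_key
            for r in table.rows
            if r.source == tag and r.category is not Category.INTERGENIC
        }

    return concordance(annotated(tag_a), annotated(tag_b), tag_a, tag_b)


# ---------------------------------------------------------------------------
# Candidate exclusion and summarization
# ---------------------------------------------------------------------------

def exclude_noncandidate(
    table: CandidateTable,
    excluded: frozenset[Category] = NON_CANDIDATE_CATEGORIES,
) -> CandidateTable:
    """Drop variants whose every annotation row is in ``excluded``.

    The default excluded set is {intronic, ncRNA, intergenic} (the SNV rule);
    for indels annotated per-transcript the convention is to exclude only
    {intronic, intergenic}, keeping events whose only non-intronic context is
    a non-coding transcript exon — pass
    ``excluded=frozenset({Category.INTRONIC, Category.INTERGENIC})``.
    A variant with at least one row outside ``excluded`` is kept with all of
    its rows (including intronic ones), preserving multi-annotation output.
    """
    keep = {
        key
        for key in table.keys()
        if any(r.category not in excluded for r in table.rows_for(key))
    }
    return table.subset(keep)


INDEL_EXCLUDED_CATEGORIES = frozenset({Category.INTRONIC, Category.INTERGENIC})


@dataclass
class CategoryCount:
    n_variants: int
    n_genes: int


@dataclass
class Summary:
    n_variants: int
    n_genes: int
    n_protein_coding_genes: int
    per_category: dict[Category, CategoryCount]
    n_snvs: int
    n_insertions: int
    n_deletions: int

    def as_dict(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "n_protein_coding_genes": self.n_protein_coding_genes,
            "n_snvs": self.n_snvs,
            "n_insertions": self.n_insertions,
            "n_deletions": self.n_deletions,
            "per_category": {
                cat.value: {"n_variants": c.n_variants, "n_genes": c.n_genes}
                for cat, c in self.per_category.items()
            },
        }


def summarize(table: CandidateTable) -> Summary:
    """Candidate counts deduplicated on variant key across annotation rows.

    A gene counts as protein-coding when any of its annotated transcripts in
    the table has a protein-coding biotype. Per-category counts attribute a
    variant to every category it has at least one row in.
    """
    keys = table.keys()
    genes = table.genes()
    pc_genes = {
        r.gene_symbol
        for r in table.rows
        if r.gene_symbol and r.biotype == PROTEIN_CODING
    }
    per_category: dict[Category, CategoryCount] = {}
    for cat in Category:
        cat_rows = [r for r in table.rows if r.category is cat]
        if not cat_rows:
            continue
        per_category[cat] = CategoryCount(
            n_variants=len({r.variant_key for r in cat_rows}),
            n_genes=len({r.gene_symbol for r in cat_rows if r.gene_symbol}),
        )
    classes = [table.variants[k].vclass for k in keys if k in table.variants]
    return Summary(
        n_variants=len(keys),
        n_genes=len(genes),
        n_protein_coding_genes=len(pc_genes),
        per_category=per_category,
        n_snvs=sum(c is VariantClass.SNV for c in classes),
        n_insertions=sum(c is VariantClass.INSERTION for c in classes),
        n_deletions=sum(c is VariantClass.DELETION for c in classes),
    )


def protein_coding_candidates(table: CandidateTable) -> list[VariantKey]:
    """Variants with >= 1 candidate-category row on a protein-coding transcript.

    This is the set taken forward to extended-family screening: a variant
    annotated only to a non-coding transcript of an otherwise coding gene
    does not qualify.
    """
    out = []
    for key in table.keys():
        for r in table.rows_for(key):
            if (
                r.biotype == PROTEIN_CODING
                and r.category not in NON_CANDIDATE_CATEGORIES
            ):
                out.append(key)
                break
    return out
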