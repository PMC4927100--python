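"""Core data types, coordinate conventions and readers for the standard formats.

Conventions
-----------
* All internal coordinates are 1-based inclusive (VCF convention). BED input
  (0-based, half-open) is converted at the boundary.
* A variant is keyed by ``(chrom, pos, ref, alt)`` after normalization;
  the key is what caller-concordance and all downstream stages operate on.
* Affection status follows PED conventions: 2 = affected, 1 = unaffected;
  any other phenotype code is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

from intervaltree import IntervalTree

from .errors import (
    FrequencyTableError,
    IntervalError,
    NormalizationError,
    PedigreeError,
    VcfFormatError,
    VcfParseError,
)

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: ``(chrom, pos, ref, alt)`` — the canonical identity of a variant.
VariantKey = tuple[str, int, str, str]


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def is_carrier(self) -> bool:
        """True if the genotype carries at least one alternate allele."""
        return self in (Genotype.HET, Genotype.HOM_ALT)


@dataclass(frozen=True)
class Variant:
    """A normalized genomic sequence change.

    ``pos`` is the 1-based position of the first reference base. An absent
    ``rsid`` means the variant is novel with respect to the frequency
    resource in use.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - VALID_BASES or set(self.alt) - VALID_BASES:
            raise ValueError(
                f"alleles must be over A/C/G/T: {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == len(self.alt) == 1:
            return VariantClass.SNV
        if len(self.alt) > len(self.ref):
            return VariantClass.INSERTION
        return VariantClass.DELETION

    @property
    def is_novel(self) -> bool:
        return self.rsid is None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass
class SampleCall:
    """One sample's genotype evidence for one variant.

    ``quality`` holds, by default, the site-level QUAL of the record the
    call came from (the per-sample GQ can be selected at read time instead).
    ``allele_fraction`` is alt reads / (ref reads + alt reads) and is ``None``
    when no read-level evidence is available.
    """

    sample_id: str
    variant_key: VariantKey
    genotype: Genotype
    depth: int = 0
    quality: Optional[float] = None
    allele_fraction: Optional[float] = None
    ad: Optional[tuple[int, int]] = None  # (ref reads, alt reads)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.quality is not None and self.quality < 0:
            raise ValueError("quality must be >= 0")
        if self.allele_fraction is not None and not (
            0.0 <= self.allele_fraction <= 1.0
        ):
            raise ValueError("allele_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    affected: bool
    cohort: str  # "ngs", "extended" or "control"


@dataclass
class Pedigree:
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate sample_id(s): {', '.join(dup)}")

    def samples(self, cohort: Optional[str] = None) -> list[str]:
        return [
            m.sample_id
            for m in self.members
            if cohort is None or m.cohort == cohort
        ]

    def affected(self, cohort: str) -> list[str]:
        return [
            m.sample_id
            for m in self.members
            if m.cohort == cohort and m.affected
        ]

    def unaffected(self, cohort: str) -> list[str]:
        return [
            m.sample_id
            for m in self.members
            if m.cohort == cohort and not m.affected
        ]


class IntervalSet:
    """1-based inclusive genomic intervals; overlaps merged at construction."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start > end:
                raise IntervalError(
                    f"interval start > end: {chrom}:{start}-{end}"
                )
            # store half-open [start, end+1) in the tree
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos])

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end - 1))
        return out

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.intervals())

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


@dataclass(frozen=True)
class FrequencyEntry:
    rsid: Optional[str]
    maf: Optional[float]  # None when the resource lists the site without a MAF


class FrequencyTable:
    """Population minor-allele frequencies keyed by variant key.

    Absence from the table means the variant is treated as novel.
    """

    def __init__(self, entries: Mapping[VariantKey, FrequencyEntry]):
        for key, entry in entries.items():
            if entry.maf is not None and not (0.0 <= entry.maf <= 0.5):
                raise FrequencyTableError(
                    f"MAF out of [0, 0.5] for {key}: {entry.maf}"
                )
        self._entries = dict(entries)

    def get(self, key: VariantKey) -> Optional[FrequencyEntry]:
        return self._entries.get(key)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


class ReferenceContext:
    """Local reference sequence segments (1-based), enough for normalization
    and codon lookups without a full genome."""

    def __init__(self, segments: Iterable[tuple[str, int, str]] = ()):
        # per chrom: list of (start, seq), non-overlapping, sorted
        self._segments: dict[str, list[tuple[int, str]]] = {}
        for chrom, start, seq in segments:
            self.add(chrom, start, seq)

    def add(self, chrom: str, start: int, seq: str) -> None:
        seq = seq.upper()
        self._segments.setdefault(chrom, []).append((start, seq))
        self._segments[chrom].sort()

    def _segment_for(self, chrom: str, pos: int) -> Optional[tuple[int, str]]:
        for start, seq in self._segments.get(chrom, ()):
            if start <= pos < start + len(seq):
                return start, seq
        return None

    def has(self, chrom: str, start: int, end: Optional[int] = None) -> bool:
        end = start if end is None else end
        seg = self._segment_for(chrom, start)
        return seg is not None and end < seg[0] + len(seg[1])

    def base(self, chrom: str, pos: int) -> str:
        seg = self._segment_for(chrom, pos)
        if seg is None:
            raise NormalizationError(
                f"no reference context for {chrom}:{pos}"
            )
        start, seq = seg
        return seq[pos - start]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Inclusive slice; must fall within a single stored segment."""
        seg = self._segment_for(chrom, start)
        if seg is None or end >= seg[0] + len(seg[1]):
            raise NormalizationError(
                f"no reference context for {chrom}:{start}-{end}"
            )
        off = start - seg[0]
        return seg[1][off : off + (end - start + 1)]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceContext":
        """Load segments from FASTA. Headers ``name:start-end`` place the
        segment at 1-based ``start``; a bare name implies start 1."""
        from Bio import SeqIO

        ctx = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id
            if ":" in name:
                chrom, span = name.rsplit(":", 1)
                start = int(span.split("-")[0].replace(",", ""))
            else:
                chrom, start = name, 1
            ctx.add(chrom, start, str(rec.seq))
        return ctx

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._segments):
                for start, seq in self._segments[chrom]:
                    end = start + len(seq) - 1
                    fh.write(f">{chrom}:{start}-{end}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")


@dataclass
class CallSet:
    """All variants and per-sample calls from one caller (or a merge)."""

    caller: str
    samples: list[str] = field(default_factory=list)
    variants: dict[VariantKey, Variant] = field(default_factory=dict)
    calls: dict[VariantKey, dict[str, SampleCall]] = field(default_factory=dict)
    site_qual: dict[VariantKey, Optional[float]] = field(default_factory=dict)
    reference: Optional[ReferenceContext] = None
    #: per-variant provenance when this set is a merge of several callers
    sources: dict[VariantKey, tuple[str, ...]] = field(default_factory=dict)

    def add_variant(self, v: Variant, qual: Optional[float] = None) -> None:
        self.variants[v.key] = v
        self.calls.setdefault(v.key, {})
        self.site_qual.setdefault(v.key, qual)
        self.sources.setdefault(v.key, (self.caller,))

    def add_call(self, call: SampleCall) -> None:
        if call.sample_id not in self.samples:
            self.samples.append(call.sample_id)
        self.calls.setdefault(call.variant_key, {})[call.sample_id] = call

    def keys(self) -> set[VariantKey]:
        return set(self.variants)

    def call(self, key: VariantKey, sample: str) -> Optional[SampleCall]:
        return self.calls.get(key, {}).get(sample)

    def genotype(self, key: VariantKey, sample: str) -> Genotype:
        c = self.call(key, sample)
        return c.genotype if c is not None else Genotype.HOM_REF

    def sorted_keys(self) -> list[VariantKey]:
        return sorted(self.variants)


def merge_callsets(a: CallSet, b: CallSet, mode: str = "union") -> CallSet:
    """Combine two callers into one analysis set.

    ``union`` (default) keeps every key with source labels; when both callers
    report a key the evidence of the first caller is used. ``intersection``
    keeps concordant keys only.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown merge mode: {mode}")
    keys = a.keys() | b.keys() if mode == "union" else a.keys() & b.keys()
    merged = CallSet(caller=f"{a.caller}+{b.caller}", reference=a.reference or b.reference)
    merged.samples = list(dict.fromkeys(a.samples + b.samples))
    for key in sorted(keys):
        primary = a if key in a.variants else b
        merged.variants[key] = primary.variants[key]
        merged.calls[key] = dict(primary.calls.get(key, {}))
        merged.site_qual[key] = primary.site_qual.get(key)
        src = tuple(
            cs.caller for cs in (a, b) if key in cs.variants
        )
        merged.sources[key] = src
    return merged


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def normalize(v: Variant, reference: Optional[ReferenceContext] = None) -> Variant:
    """Left-align and parsimony-trim a variant against its reference context.

    SNVs are returned unchanged. Indels are first trimmed of shared
    suffix/prefix bases, then shifted left while the trailing base of the
    longer allele equals the base preceding the current position. The result
    is the canonical (smallest-position, shortest-allele) encoding; the
    operation is idempotent.

    Raises :class:`NormalizationError` when an indel needs context that the
    supplied reference does not cover.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    if len(ref) == 1 and len(alt) == 1:
        return v

    # trim shared suffix (keep at least one base on each allele)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-align: while alleles end with the same base, roll one base left
    while ref[-1] == alt[-1]:
        if reference is None or not reference.has(v.chrom, pos - 1):
            raise NormalizationError(
                f"reference context unavailable to left-align {v}"
            )
        prev = reference.base(v.chrom, pos - 1)
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(v.chrom, pos, ref, alt, v.rsid)


def normalize_callset(cs: CallSet) -> CallSet:
    """Normalize every variant of a call set in place-compatible fashion.

    Indels whose context is missing are passed through un-normalized with a
    warning (degraded mode), per the reader contract.
    """
    out = CallSet(
        caller=cs.caller,
        samples=list(cs.samples),
        reference=cs.reference,
    )
    for key in cs.sorted_keys():
        v = cs.variants[key]
        try:
            nv = normalize(v, cs.reference)
        except NormalizationError:
            logger.warning("could not normalize %s; passed through", v)
            nv = v
        out.variants[nv.key] = nv
        out.site_qual[nv.key] = cs.site_qual.get(key)
        out.sources[nv.key] = cs.sources.get(key, (cs.caller,))
        out.calls[nv.key] = {
            s: replace(c, variant_key=nv.key) for s, c in cs.calls[key].items()
        }
    return out


# ---------------------------------------------------------------------------
# VCF dialect reader / writer
# ---------------------------------------------------------------------------

def _parse_gt(gt: str, alt_index: int) -> Genotype:
    alleles = gt.replace("|", "/").split("/")
    if "." in alleles:
        return Genotype.MISSING
    n_alt = sum(1 for a in alleles if a == str(alt_index))
    if n_alt >= 2:
        return Genotype.HOM_ALT
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def read_vcf(
    path: str | Path,
    caller_label: str,
    reference: Optional[ReferenceContext] = None,
    quality_field: str = "QUAL",
) -> CallSet:
    """Read a multi-sample VCF 4.x text file into a :class:`CallSet`.

    Multiallelic records are split into biallelic variants. The allele
    fraction is AD_alt / (AD_ref + AD_alt) when allelic depths are present;
    otherwise a per-sample AF tag is used; failing both, the call set runs in
    genotype-only mode (allele fraction undefined, logged once).

    ``quality_field`` selects what fills ``SampleCall.quality``: the record
    QUAL (default) or the per-sample GQ.
    """
    if quality_field not in ("QUAL", "GQ"):
        raise ValueError("quality_field must be 'QUAL' or 'GQ'")
    cs = CallSet(caller=caller_label, reference=reference)
    genotype_only_warned = False
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise VcfParseError(f"{path}: line 1: missing ##fileformat header")
        samples: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise VcfFormatError(
                        f"{path}: line {lineno}: no genotype columns"
                    )
                samples = cols[9:]
                cs.samples = list(samples)
                continue
            if samples is None:
                raise VcfParseError(
                    f"{path}: line {lineno}: record before #CHROM header"
                )
            fields = line.split("\t")
            if len(fields) < 9 + len(samples):
                raise VcfParseError(
                    f"{path}: line {lineno}: expected "
                    f"{9 + len(samples)} columns, got {len(fields)}"
                )
            chrom, pos_s, vid, ref, alt_s, qual_s, _flt, _info, fmt = fields[:9]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfParseError(
                    f"{path}: line {lineno}: non-integer POS {pos_s!r}"
                ) from None
            qual = None if qual_s in (".", "") else float(qual_s)
            rsid = None if vid in (".", "") else vid
            fmt_keys = fmt.split(":")
            alts = alt_s.split(",")
            sample_fields = [
                dict(zip(fmt_keys, s.split(":"))) for s in fields[9:]
            ]
            if "GT" not in fmt_keys:
                raise VcfFormatError(
                    f"{path}: line {lineno}: FORMAT lacks GT"
                )
            for alt_index, alt in enumerate(alts, start=1):
                try:
                    variant = Variant(chrom, pos, ref, alt, rsid)
                except ValueError as exc:
                    raise VcfParseError(
                        f"{path}: line {lineno}: {exc}"
                    ) from None
                cs.add_variant(variant, qual)
                for sample, data in zip(samples, sample_fields):
                    gt = _parse_gt(data.get("GT", "."), alt_index)
                    depth = 0
                    if data.get("DP") not in (None, "."):
                        depth = int(data["DP"])
                    ad = None
                    af = None
                    if data.get("AD") not in (None, "."):
                        ad_vec = [
                            0 if x == "." else int(x)
                            for x in data["AD"].split(",")
                        ]
                        if len(ad_vec) > alt_index:
                            ad = (ad_vec[0], ad_vec[alt_index])
                            denom = ad[0] + ad[1]
                            af = ad[1] / denom if denom > 0 else None
                            if not depth:
                                depth = sum(ad_vec)
                    if af is None and data.get("AF") not in (None, "."):
                        af = float(data["AF"].split(",")[alt_index - 1])
                    if af is None and ad is None and gt.is_carrier:
                        if not genotype_only_warned:
                            logger.warning(
                                "%s: no AD/AF evidence; running in "
                                "genotype-only mode (allele fraction "
                                "undefined)",
                                path,
                            )
                            genotype_only_warned = True
                    if quality_field == "GQ":
                        q = data.get("GQ")
                        quality = None if q in (None, ".") else float(q)
                    else:
                        quality = qual
                    cs.add_call(
                        SampleCall(
                            sample_id=sample,
                            variant_key=variant.key,
                            genotype=gt,
                            depth=depth,
                            quality=quality,
                            allele_fraction=af,
                            ad=ad,
                        )
                    )
        if samples is None:
            raise VcfFormatError(f"{path}: missing #CHROM header line")
    return cs


def write_vcf(cs: CallSet, path: str | Path) -> None:
    """Write a call set as VCF 4.2 (biallelic records, GT:DP:AD)."""
    chroms = sorted({k[0] for k in cs.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=locusprio caller={cs.caller}\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cs.samples)
            + "\n"
        )
        gt_map = {
            Genotype.HOM_REF: "0/0",
            Genotype.HET: "0/1",
            Genotype.HOM_ALT: "1/1",
            Genotype.MISSING: "./.",
        }
        for key in cs.sorted_keys():
            v = cs.variants[key]
            qual = cs.site_qual.get(key)
            qual_s = "." if qual is None else f"{qual:g}"
            cols = [
                v.chrom,
                str(v.pos),
                v.rsid or ".",
                v.ref,
                v.alt,
                qual_s,
                "PASS",
                ".",
                "GT:DP:AD",
            ]
            for sample in cs.samples:
                call = cs.call(key, sample)
                if call is None:
                    cols.append("./.:.:.")
                    continue
                ad = call.ad
                if ad is None and call.allele_fraction is not None:
                    alt_reads = round(call.depth * call.allele_fraction)
                    ad = (call.depth - alt_reads, alt_reads)
                ad_s = f"{ad[0]},{ad[1]}" if ad is not None else "."
                cols.append(
                    f"{gt_map[call.genotype]}:{call.depth}:{ad_s}"
                )
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PED / BED / frequency-table readers
# ---------------------------------------------------------------------------

_AFFECTION = {"2": True, "1": False}


def read_pedigree(path: str | Path, default_cohort: str = "ngs") -> Pedigree:
    """Read a 6-column PED file with an extra cohort column.

    Column 7, when present, must be one of ``ngs``, ``extended``,
    ``control``; otherwise ``default_cohort`` applies. Affection codes:
    2 = affected, 1 = unaffected; 0/-9 (unknown) are rejected because every
    member must contribute to the segregation logic.
    """
    members: list[PedigreeMember] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected >= 6 columns"
                )
            sample_id, pheno = cols[1], cols[5]
            if pheno not in _AFFECTION:
                raise PedigreeError(
                    f"{path}: line {lineno}: unknown affection code "
                    f"{pheno!r} for {sample_id}"
                )
            cohort = cols[6] if len(cols) > 6 else default_cohort
            if cohort not in ("ngs", "extended", "control"):
                raise PedigreeError(
                    f"{path}: line {lineno}: unknown cohort {cohort!r}"
                )
            members.append(
                PedigreeMember(sample_id, _AFFECTION[pheno], cohort)
            )
    return Pedigree(members)


def read_intervals(path: str | Path) -> IntervalSet:
    """Read BED3 (0-based half-open) into the 1-based inclusive convention."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise IntervalError(
                    f"{path}: line {lineno}: expected >= 3 columns"
                )
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise IntervalError(
                    f"{path}: line {lineno}: BED start >= end "
                    f"({start} >= {end})"
                )
            intervals.append((chrom, start + 1, end))
    return IntervalSet(intervals)


def read_frequencies(path: str | Path) -> FrequencyTable:
    """Read a TSV of (chrom, pos, ref, alt, rsid, maf).

    ``rsid`` may be ``.``/empty (site known without an identifier is unusual;
    kept for generality) and ``maf`` may be ``NA``/``n/a``/empty when the
    resource lists the site without a frequency.
    """
    entries: dict[VariantKey, FrequencyEntry] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0].lower() in ("chrom", "chr"):
                continue
            if len(cols) < 6:
                raise FrequencyTableError(
                    f"{path}: line {lineno}: expected 6 columns"
                )
            chrom, pos_s, ref, alt, rsid, maf_s = cols[:6]
            key = (chrom, int(pos_s), ref, alt)
            rsid_v = None if rsid in (".", "", "-") else rsid
            maf_v = (
                None
                if maf_s.lower() in ("na", "n/a", ".", "", "-")
                else float(maf_s)
            )
            entries[key] = FrequencyEntry(rsid_v, maf_v)
    return FrequencyTable(entries)
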