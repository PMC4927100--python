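"""Extended-family screening of validated candidates and shared-CNV logic.

After the NGS cascade, candidates in protein-coding genes are screened in
additional family members who did not undergo sequencing: a candidate
segregates when every affected extended member carries it and no unaffected
member does. The same all-affected/no-unaffected logic applies to
copy-number calls: a CNV region is reported when every affected sample has
an overlapping same-kind event and no unaffected sample does. Array-derived
CNV regions are flagged ``requires_orthogonal_validation`` because
high-density array designs can produce shared false positives (competitive
hybridization), so a PCR-level check is always warranted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, IntervalError
from .variant_model import Genotype, Pedigree, VariantKey

#: genotype table: variant key -> {sample_id: Genotype}
GenotypeTable = Mapping[VariantKey, Mapping[str, Genotype]]


@dataclass
class ScreenResult:
    """Per-variant outcome of the extended-family screen."""

    variant_key: VariantKey
    carriers: dict[str, bool]
    segregates: bool
    discordant_members: list[str]


def screen_extended(
    candidates: Sequence[VariantKey],
    calls: GenotypeTable,
    ped: Pedigree,
    cohort: str = "extended",
    strict: bool = True,
) -> dict[VariantKey, ScreenResult]:
    """Screen candidate variants in the extended cohort.

    ``discordant_members`` lists affected non-carriers followed by
    unaffected carriers. In strict mode a cohort member entirely absent from
    the call table is an error (the screen cannot vouch for them); in
    non-strict mode absent members count as non-carriers.
    """
    affected = ped.affected(cohort)
    unaffected = ped.unaffected(cohort)
    if not affected or not unaffected:
        raise ConfigurationError(
            f"cohort {cohort!r} needs >= 1 affected and >= 1 unaffected member"
        )
    results: dict[VariantKey, ScreenResult] = {}
    for key in candidates:
        genotypes = calls.get(key, {})
        carriers: dict[str, bool] = {}
        for member in affected + unaffected:
            if member not in genotypes:
                if strict:
                    raise ConfigurationError(
                        f"member {member!r} has no genotype for "
                        f"{key[0]}:{key[1]} (strict mode)"
                    )
                carriers[member] = False
            else:
                carriers[member] = genotypes[member].is_carrier
        discordant = [m for m in affected if not carriers[m]] + [
            m for m in unaffected if carriers[m]
        ]
        results[key] = ScreenResult(
            variant_key=key,
            carriers=carriers,
            segregates=not discordant,
            discordant_members=discordant,
        )
    return results


def read_genotype_table(path: str | Path) -> dict[VariantKey, dict[str, Genotype]]:
    """Read a long-format genotype TSV: sample, chrom, pos, ref, alt, genotype."""
    table: dict[VariantKey, dict[str, Genotype]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "sample":
                continue
            if len(cols) < 6:
                raise IntervalError(
                    f"{path}: line {lineno}: expected 6 columns"
                )
            sample, chrom, pos, ref, alt, gt = cols[:6]
            key = (chrom, int(pos), ref, alt)
            table.setdefault(key, {})[sample] = Genotype(gt)
    return table


# ---------------------------------------------------------------------------
# Copy-number variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvCall:
    """One sample's copy-number call, 1-based inclusive."""

    sample_id: str
    chrom: str
    start: int
    end: int
    kind: str  # "gain" or "loss"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise IntervalError(
                f"CNV end < start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.kind not in ("gain", "loss"):
            raise IntervalError(f"CNV kind must be gain/loss: {self.kind!r}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SharedCnvRegion:
    """A maximal region shared by all affected and no unaffected sample.

    Always flagged for orthogonal (e.g. PCR) validation: array CNV calls
    shared across samples can still be platform artifacts.
    """

    chrom: str
    start: int
    end: int
    kind: str
    requires_orthogonal_validation: bool = True

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def read_cnvs(path: str | Path) -> list[CnvCall]:
    """Read a CNV TSV: sample, chrom, start, end, kind (1-based inclusive)."""
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "sample":
                continue
            if len(cols) < 5:
                raise IntervalError(f"{path}: line {lineno}: expected 5 columns")
            calls.append(
                CnvCall(cols[0], cols[1], int(cols[2]), int(cols[3]), cols[4])
            )
    return calls


def shared_cnv_filter(
    cnvs: Iterable[CnvCall],
    ped: Pedigree,
    cohort: str = "ngs",
    match: str = "overlap",
) -> list[SharedCnvRegion]:
    """Regions where every affected sample has a same-kind CNV and no
    unaffected sample does.

    ``match="overlap"``: sharing means >= 1 common bp (maximal shared regions
    are returned). ``match="exact"``: events match only when their intervals
    are identical (appropriate when all samples were assayed on identical
    probes).
    """
    if match not in ("overlap", "exact"):
        raise ValueError(f"unknown match mode {match!r}")
    affected = set(ped.affected(cohort))
    unaffected = set(ped.unaffected(cohort))
    if not affected:
        raise ConfigurationError(f"cohort {cohort!r} has no affected members")
    cnvs = list(cnvs)

    if match == "exact":
        by_event: dict[tuple, set[str]] = {}
        for c in cnvs:
            by_event.setdefault((c.chrom, c.start, c.end, c.kind), set()).add(
                c.sample_id
            )
        out = []
        for (chrom, start, end, kind), samples in sorted(by_event.items()):
            if affected <= samples and not (samples & unaffected):
                out.append(SharedCnvRegion(chrom, start, end, kind))
        return out

    regions: list[SharedCnvRegion] = []
    groups = sorted({(c.chrom, c.kind) for c in cnvs})
    for chrom, kind in groups:
        here = [c for c in cnvs if c.chrom == chrom and c.kind == kind]
        # elementary-segment sweep over all breakpoints
        points = sorted({c.start for c in here} | {c.end + 1 for c in here})
        passing: list[tuple[int, int]] = []
        for lo, hi_excl in zip(points, points[1:]):
            hi = hi_excl - 1
            covering = {
                c.sample_id for c in here if c.start <= lo and c.end >= hi
            }
            if affected <= covering and not (covering & unaffected):
                if passing and passing[-1][1] == lo - 1:
                    passing[-1] = (passing[-1][0], hi)
                else:
                    passing.append((lo, hi))
        regions.extend(
            SharedCnvRegion(chrom, lo, hi, kind) for lo, hi in passing
        )
    return regions
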