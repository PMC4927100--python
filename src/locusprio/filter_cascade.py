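"""The seven-criterion candidate filter cascade and caller concordance logic.

The cascade encodes the family-based prioritization strategy for a dominantly
inherited locus: a candidate variant must (1) fall inside the linked,
capture-enriched interval, be supported by adequate evidence — (2) read depth
>= 5, (3) quality score >= 20, (4) a heterozygous call with alt-allele read
fraction in [0.4, 0.7] — and show the expected population/pedigree pattern:
(5) absent from unrelated unaffected controls, (6) carried by every affected
and no unaffected family member, and (7) rare or novel (MAF <= 0.05, novel =
no rsID in the frequency resource).

All thresholds are boundary-inclusive. Criteria 2-4 are evaluated per sample
over the carriers among the affected NGS-cohort members (strict mode,
default): one failing carrier kills the variant. The survivor set equals the
conjunction of the seven predicates, so it is independent of the order in
which criteria are applied; the per-criterion drop attribution follows the
printed order 1..7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .errors import ConfigurationError
from .variant_model import (
    CallSet,
    FrequencyTable,
    Genotype,
    IntervalSet,
    Pedigree,
    SampleCall,
    Variant,
    VariantKey,
)

CRITERION_NAMES = {
    1: "within enriched interval",
    2: "read depth >= min_depth",
    3: "quality score >= min_quality",
    4: "heterozygous with allele fraction in band",
    5: "absent from unrelated unaffected controls",
    6: "segregates with affection status",
    7: "rare or novel (MAF <= max_maf)",
}


@dataclass
class CascadeConfig:
    """Thresholds and strictness modes of the filter cascade."""

    min_depth: int = 5
    min_quality: float = 20.0
    het_band: tuple[float, float] = (0.4, 0.7)
    max_maf: float = 0.05
    #: "strict": every affected-carrier call must pass criteria 2-4;
    #: "any": one passing affected-carrier call suffices.
    sample_mode: str = "strict"
    #: "fail": an affected member with a missing genotype fails segregation;
    #: "ignore": missing affected genotypes are skipped.
    missing_affected: str = "fail"
    #: "fraction": criterion 4 requires the read fraction in the band;
    #: "genotype": genotype-only mode (no fraction evidence required).
    af_mode: str = "fraction"

    def __post_init__(self) -> None:
        if self.sample_mode not in ("strict", "any"):
            raise ConfigurationError(f"sample_mode {self.sample_mode!r}")
        if self.missing_affected not in ("fail", "ignore"):
            raise ConfigurationError(
                f"missing_affected {self.missing_affected!r}"
            )
        if self.af_mode not in ("fraction", "genotype"):
            raise ConfigurationError(f"af_mode {self.af_mode!r}")


@dataclass
class StageResult:
    criterion_id: int
    name: str
    n_in: int
    n_out: int
    dropped: list[VariantKey]


@dataclass
class FilterReport:
    stages: list[StageResult] = field(default_factory=list)
    survivors: set[VariantKey] = field(default_factory=set)

    def dropped_at(self, criterion_id: int) -> set[VariantKey]:
        for stage in self.stages:
            if stage.criterion_id == criterion_id:
                return set(stage.dropped)
        raise KeyError(criterion_id)

    def counts(self) -> list[tuple[int, int, int]]:
        return [(s.criterion_id, s.n_in, s.n_out) for s in self.stages]

    def to_records(self) -> list[dict]:
        return [
            {
                "criterion": s.criterion_id,
                "name": s.name,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "n_dropped": len(s.dropped),
                "dropped": ["{}:{}:{}>{}".format(*k) for k in s.dropped],
            }
            for s in self.stages
        ]


# ---------------------------------------------------------------------------
# Individual criteria
# ---------------------------------------------------------------------------

def criterion_interval(v: Variant, intervals: IntervalSet) -> bool:
    """Criterion 1: the variant's anchor position lies inside the locus.

    Boundaries are inclusive; a chromosome absent from the interval set is a
    fail, not an error.
    """
    return intervals.contains(v.chrom, v.pos)


def criterion_depth(call: SampleCall, config: CascadeConfig) -> bool:
    """Criterion 2: read depth >= threshold (default 5)."""
    return call.depth >= config.min_depth


def criterion_quality(call: SampleCall, config: CascadeConfig) -> bool:
    """Criterion 3: quality score >= threshold (default 20)."""
    return call.quality is not None and call.quality >= config.min_quality


def criterion_het_fraction(call: SampleCall, config: CascadeConfig) -> bool:
    """Criterion 4: heterozygous with allele fraction inside the closed band.

    In genotype-only mode the fraction requirement is waived; in fraction
    mode an undefined fraction fails (no fraction evidence).
    """
    if call.genotype is not Genotype.HET:
        return False
    if config.af_mode == "genotype":
        return True
    if call.allele_fraction is None:
        return False
    lo, hi = config.het_band
    return lo <= call.allele_fraction <= hi


def _evidence_pass(
    key: VariantKey,
    call_set: CallSet,
    affected: Sequence[str],
    predicate: Callable[[SampleCall, CascadeConfig], bool],
    config: CascadeConfig,
) -> bool:
    """Evaluate a per-sample criterion over affected-cohort carriers."""
    carrier_calls = [
        c
        for s in affected
        if (c := call_set.call(key, s)) is not None and c.genotype.is_carrier
    ]
    if not carrier_calls:
        return True  # vacuous; segregation handles absent carriers
    if config.sample_mode == "strict":
        return all(predicate(c, config) for c in carrier_calls)
    return any(predicate(c, config) for c in carrier_calls)


def criterion_controls(
    key: VariantKey, call_set: CallSet, controls: Sequence[str]
) -> bool:
    """Criterion 5: no unrelated unaffected control carries the alt allele.

    A missing or absent control genotype counts as a non-carrier.
    """
    return not any(
        call_set.genotype(key, s).is_carrier for s in controls
    )


def criterion_segregation(
    key: VariantKey,
    call_set: CallSet,
    ped: Pedigree,
    cohort: str = "ngs",
    missing_affected: str = "fail",
) -> bool:
    """Criterion 6: carried by every affected and no unaffected member.

    Carrier = het or hom_alt. Missing genotypes in affected members fail in
    strict mode (``missing_affected="fail"``) and are skipped in
    ``"ignore"`` mode; missing unaffected genotypes count as non-carriers.
    """
    affected = ped.affected(cohort)
    unaffected = ped.unaffected(cohort)
    if not affected or not unaffected:
        raise ConfigurationError(
            f"cohort {cohort!r} needs >= 1 affected and >= 1 unaffected member"
        )
    for s in affected:
        gt = call_set.genotype(key, s)
        if gt is Genotype.MISSING:
            if missing_affected == "fail":
                return False
            continue
        if not gt.is_carrier:
            return False
    return not any(
        call_set.genotype(key, s).is_carrier for s in unaffected
    )


def criterion_rarity(
    v: Variant, frequencies: FrequencyTable, max_maf: float = 0.05
) -> bool:
    """Criterion 7: novel (absent from the resource) or MAF <= cutoff.

    An entry listed without a frequency is treated as rare.
    """
    entry = frequencies.get(v.key)
    if entry is None or entry.maf is None:
        return True
    return entry.maf <= max_maf


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def build_predicates(
    call_set: CallSet,
    ped: Pedigree,
    intervals: IntervalSet,
    frequencies: FrequencyTable,
    config: CascadeConfig,
) -> list[tuple[int, Callable[[VariantKey], bool]]]:
    """The seven predicates over variant keys, in printed order."""
    affected = ped.affected("ngs")
    controls = ped.samples("control")

    return [
        (1, lambda k: criterion_interval(call_set.variants[k], intervals)),
        (2, lambda k: _evidence_pass(k, call_set, affected, criterion_depth, config)),
        (3, lambda k: _evidence_pass(k, call_set, affected, criterion_quality, config)),
        (4, lambda k: _evidence_pass(k, call_set, affected, criterion_het_fraction, config)),
        (5, lambda k: criterion_controls(k, call_set, controls)),
        (
            6,
            lambda k: criterion_segregation(
                k, call_set, ped, "ngs", config.missing_affected
            ),
        ),
        (
            7,
            lambda k: criterion_rarity(
                call_set.variants[k], frequencies, config.max_maf
            ),
        ),
    ]


def run_cascade(
    call_set: CallSet,
    ped: Pedigree,
    intervals: IntervalSet,
    frequencies: FrequencyTable,
    config: Optional[CascadeConfig] = None,
) -> FilterReport:
    """Apply the seven criteria in order, recording per-criterion drops.

    The survivor set equals the conjunction of all predicates and is
    deterministic given the inputs. Raises :class:`ConfigurationError` when
    the NGS cohort lacks an affected or unaffected member.
    """
    config = config or CascadeConfig()
    if not ped.affected("ngs") or not ped.unaffected("ngs"):
        raise ConfigurationError(
            "NGS cohort must contain at least one affected and one "
            "unaffected member"
        )
    predicates = build_predicates(call_set, ped, intervals, frequencies, config)
    current = call_set.sorted_keys()
    report = FilterReport()
    for cid, pred in predicates:
        survivors, dropped = [], []
        for key in current:
            (survivors if pred(key) else dropped).append(key)
        report.stages.append(
            StageResult(cid, CRITERION_NAMES[cid], len(current), len(survivors), dropped)
        )
        current = survivors
    report.survivors = set(current)
    return report


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordancePartition:
    """Exact partition of two callers' (normalized) variant key sets."""

    label_a: str
    label_b: str
    concordant: set[VariantKey]
    only_a: set[VariantKey]
    only_b: set[VariantKey]

    def counts(self) -> dict[str, int]:
        return {
            "concordant": len(self.concordant),
            f"only_{self.label_a}": len(self.only_a),
            f"only_{self.label_b}": len(self.only_b),
        }


def concordance(
    set_a: set[VariantKey],
    set_b: set[VariantKey],
    label_a: str = "a",
    label_b: str = "b",
) -> ConcordancePartition:
    """Partition two key sets into concordant / A-only / B-only.

    Keys must already be normalized so that identical events compare equal
    across callers.
    """
    return ConcordancePartition(
        label_a=label_a,
        label_b=label_b,
        concordant=set_a & set_b,
        only_a=set_a - set_b,
        only_b=set_b - set_a,
    )
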