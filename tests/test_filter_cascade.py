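"""The seven-criterion cascade: boundary behavior, drop attribution,
conjunction-oracle equivalence, order independence and concordance logic."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from conftest import make_callset
from locusprio.errors import ConfigurationError
from locusprio.filter_cascade import (
    CascadeConfig,
    build_predicates,
    concordance,
    criterion_controls,
    criterion_depth,
    criterion_het_fraction,
    criterion_interval,
    criterion_quality,
    criterion_rarity,
    criterion_segregation,
    run_cascade,
)
from locusprio.variant_model import (
    FrequencyEntry,
    FrequencyTable,
    Genotype,
    IntervalSet,
    Pedigree,
    PedigreeMember,
    SampleCall,
    Variant,
)

HET = Genotype.HET
HOM_REF = Genotype.HOM_REF
HOM_ALT = Genotype.HOM_ALT
MISSING = Genotype.MISSING

LOCUS = IntervalSet(
    [("chr20", 17_316_434, 26_319_280), ("chr20", 29_420_138, 31_826_081)]
)


def small_pedigree(n_controls=2) -> Pedigree:
    members = (
        [PedigreeMember(f"A{i}", True, "ngs") for i in range(1, 5)]
        + [PedigreeMember(f"U{i}", False, "ngs") for i in range(1, 5)]
        + [PedigreeMember(f"C{i}", False, "control") for i in range(1, n_controls + 1)]
    )
    return Pedigree(members)


def segregating_calls(affected_extra=None):
    calls = {f"A{i}": HET for i in range(1, 5)}
    calls.update({f"U{i}": HOM_REF for i in range(1, 5)})
    calls.update({"C1": HOM_REF, "C2": HOM_REF})
    if affected_extra:
        calls.update(affected_extra)
    return calls


# ---------------------------------------------------------------------------
# Individual criteria
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pos,expected",
    [
        (18_022_362, True),  # first candidate position, inside interval 1
        (28_000_000, False),  # centromeric gap between the intervals
        (17_316_434, True),  # exact lower boundary is inclusive
        (26_319_280, True),  # exact upper boundary
        (26_319_281, False),
    ],
)
def test_interval_criterion_boundaries(pos, expected):
    v = Variant("chr20", pos, "C", "A")
    assert criterion_interval(v, LOCUS) is expected


def test_interval_criterion_unknown_chromosome_fails_not_errors():
    assert criterion_interval(Variant("chr21", 100, "C", "A"), LOCUS) is False


def _call(gt=HET, depth=40, qual=50.0, af=0.5):
    return SampleCall("S", ("chr20", 1, "C", "A"), gt, depth, qual, af)


@pytest.mark.parametrize(
    "depth,qual,af,d_pass,q_pass,h_pass",
    [
        (5, 20.0, 0.4, True, True, True),  # all boundaries inclusive
        (4, 20.0, 0.5, False, True, True),
        (5, 19.9, 0.5, True, False, True),
        (40, 50.0, 0.7, True, True, True),
        (40, 50.0, 0.75, True, True, False),
        (40, 50.0, 0.39, True, True, False),
    ],
)
def test_evidence_criteria_boundaries(depth, qual, af, d_pass, q_pass, h_pass):
    cfg = CascadeConfig()
    c = _call(depth=depth, qual=qual, af=af)
    assert criterion_depth(c, cfg) is d_pass
    assert criterion_quality(c, cfg) is q_pass
    assert criterion_het_fraction(c, cfg) is h_pass


def test_het_criterion_requires_het_genotype_and_fraction_evidence():
    cfg = CascadeConfig()
    assert not criterion_het_fraction(_call(gt=HOM_ALT, af=0.5), cfg)
    # undefined fraction fails in strict (fraction) mode ...
    assert not criterion_het_fraction(_call(af=None), cfg)
    # ... but passes in genotype-only mode
    cfg_gt = CascadeConfig(af_mode="genotype")
    assert criterion_het_fraction(_call(af=None), cfg_gt)


def test_controls_criterion():
    ped = small_pedigree()
    v = Variant("chr20", 18_000_000, "C", "A")
    cs = make_callset([(v, None, segregating_calls())])
    assert criterion_controls(v.key, cs, ped.samples("control"))
    cs2 = make_callset([(v, None, segregating_calls({"C1": HET}))])
    assert not criterion_controls(v.key, cs2, ped.samples("control"))
    # missing control genotype counts as non-carrier
    cs3 = make_callset([(v, None, segregating_calls({"C2": MISSING}))])
    assert criterion_controls(v.key, cs3, ped.samples("control"))


def test_segregation_criterion_patterns():
    ped = small_pedigree()
    v = Variant("chr20", 18_000_000, "C", "A")
    # 4/4 affected het, 0/4 unaffected carriers -> pass
    cs = make_callset([(v, None, segregating_calls())])
    assert criterion_segregation(v.key, cs, ped)
    # one unaffected carrier -> fail
    cs = make_callset([(v, None, segregating_calls({"U2": HET}))])
    assert not criterion_segregation(v.key, cs, ped)
    # 3/4 affected carriers -> fail
    cs = make_callset([(v, None, segregating_calls({"A3": HOM_REF}))])
    assert not criterion_segregation(v.key, cs, ped)
    # missing affected genotype: fail strict, pass when ignored
    cs = make_callset([(v, None, segregating_calls({"A3": MISSING}))])
    assert not criterion_segregation(v.key, cs, ped, missing_affected="fail")
    assert criterion_segregation(v.key, cs, ped, missing_affected="ignore")


def test_segregation_requires_both_cohort_sides():
    ped = Pedigree([PedigreeMember("A1", True, "ngs")])
    v = Variant("chr20", 18_000_000, "C", "A")
    cs = make_callset([(v, None, {"A1": HET})])
    with pytest.raises(ConfigurationError):
        criterion_segregation(v.key, cs, ped)


def test_rarity_criterion():
    ft = FrequencyTable(
        {
            ("chr20", 18022362, "C", "A"): FrequencyEntry("rs6111803", 0.0403),
            ("chr20", 2, "C", "A"): FrequencyEntry("rs2", 0.06),
            ("chr20", 3, "C", "A"): FrequencyEntry("rs3", 0.05),
            ("chr20", 4, "C", "A"): FrequencyEntry("rs4", None),
        }
    )
    assert criterion_rarity(Variant("chr20", 18022362, "C", "A"), ft)
    assert not criterion_rarity(Variant("chr20", 2, "C", "A"), ft)
    assert criterion_rarity(Variant("chr20", 3, "C", "A"), ft)  # inclusive
    assert criterion_rarity(Variant("chr20", 4, "C", "A"), ft)  # no MAF listed
    # absent from the resource entirely -> novel -> pass
    assert criterion_rarity(Variant("chr20", 5, "C", "A"), ft)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def _decoy_entries():
    """One planted passer plus one decoy violating exactly one criterion."""
    ok = segregating_calls()
    entries = {
        "planted": (Variant("chr20", 18_000_100, "C", "A"), 50.0, ok),
        1: (Variant("chr20", 28_000_000, "C", "A"), 50.0, ok),
        2: (
            Variant("chr20", 18_000_200, "C", "A"),
            50.0,
            {**ok, "A2": (HET, 4, 0.5)},
        ),
        3: (Variant("chr20", 18_000_300, "C", "A"), 10.0, ok),
        4: (
            Variant("chr20", 18_000_400, "C", "A"),
            50.0,
            {**ok, "A1": (HET, 40, 0.75)},
        ),
        5: (
            Variant("chr20", 18_000_500, "C", "A"),
            50.0,
            segregating_calls({"C1": HET}),
        ),
        6: (
            Variant("chr20", 18_000_600, "C", "A"),
            50.0,
            segregating_calls({"U1": HET}),
        ),
        7: (Variant("chr20", 18_000_700, "C", "A"), 50.0, ok),
    }
    freq = FrequencyTable(
        {entries[7][0].key: FrequencyEntry("rs7", 0.2)}
    )
    return entries, freq


def test_cascade_attributes_each_decoy_to_its_criterion():
    entries, freq = _decoy_entries()
    cs = make_callset(list(entries.values()))
    report = run_cascade(cs, small_pedigree(), LOCUS, freq)
    assert report.survivors == {entries["planted"][0].key}
    for cid in range(1, 8):
        assert report.dropped_at(cid) == {entries[cid][0].key}, cid
    # bookkeeping: n_in of stage k equals n_out of stage k-1
    for prev, nxt in itertools.pairwise(report.stages):
        assert nxt.n_in == prev.n_out


def test_cascade_strict_mode_kills_variant_on_one_thin_sample():
    v = Variant("chr20", 18_000_100, "C", "A")
    calls = segregating_calls({"A4": (HET, 4, 0.5)})
    cs = make_callset([(v, 50.0, calls)])
    report = run_cascade(cs, small_pedigree(), LOCUS, FrequencyTable({}))
    assert report.survivors == set()
    assert report.dropped_at(2) == {v.key}
    # any-sample mode lets the remaining well-covered carriers vouch for it
    relaxed = CascadeConfig(sample_mode="any")
    report2 = run_cascade(cs, small_pedigree(), LOCUS, FrequencyTable({}), relaxed)
    assert report2.survivors == {v.key}


def test_cascade_empty_callset_reports_zero_counts():
    cs = make_callset([])
    report = run_cascade(cs, small_pedigree(), LOCUS, FrequencyTable({}))
    assert report.survivors == set()
    assert all(s.n_in == s.n_out == 0 for s in report.stages)


def test_cascade_requires_affected_and_unaffected():
    ped = Pedigree(
        [PedigreeMember("A1", True, "ngs"), PedigreeMember("A2", True, "ngs")]
    )
    with pytest.raises(ConfigurationError):
        run_cascade(make_callset([]), ped, LOCUS, FrequencyTable({}))


def _random_callset(seed, n=1000):
    """Random variants with random evidence/genotype/frequency structure."""
    rng = np.random.default_rng(seed)
    ped = small_pedigree()
    samples = ped.samples()
    entries = []
    freq = {}
    for i in range(n):
        pos = int(rng.integers(17_000_000, 32_200_000))
        v = Variant("chr20", pos, "C", "A")
        qual = float(rng.uniform(0, 60))
        calls = {}
        gts = [HOM_REF, HET, HOM_ALT, MISSING]
        for s in samples:
            gt = gts[int(rng.choice(4, p=[0.45, 0.35, 0.1, 0.1]))]
            depth = int(rng.integers(0, 60))
            af = float(rng.uniform(0, 1)) if depth > 0 else None
            calls[s] = (gt, depth, af)
        entries.append((v, qual, calls))
        if rng.random() < 0.5:
            freq[v.key] = FrequencyEntry(f"rs{i}", float(rng.uniform(0, 0.5)))
    return make_callset(entries), ped, FrequencyTable(freq)


def test_cascade_survivors_equal_conjunction_oracle_on_random_variants():
    """Plainly-written AND of the seven predicates, re-derived in the test,
    must agree with the staged cascade on 1,000 random variants."""
    cs, ped, freq = _random_callset(seed=42)
    cfg = CascadeConfig()
    report = run_cascade(cs, ped, LOCUS, freq, cfg)

    affected = ped.affected("ngs")
    unaffected = ped.unaffected("ngs")
    controls = ped.samples("control")
    expected = set()
    for key, v in cs.variants.items():
        if not LOCUS.contains(v.chrom, v.pos):
            continue
        carriers = [
            cs.calls[key][s]
            for s in affected
            if cs.calls[key][s].genotype in (HET, HOM_ALT)
        ]
        if any(c.depth < 5 for c in carriers):
            continue
        if any(c.quality is None or c.quality < 20 for c in carriers):
            continue
        ok4 = all(
            c.genotype is HET
            and c.allele_fraction is not None
            and 0.4 <= c.allele_fraction <= 0.7
            for c in carriers
        )
        if not ok4:
            continue
        if any(cs.calls[key][s].genotype in (HET, HOM_ALT) for s in controls):
            continue
        if not all(cs.calls[key][s].genotype is HET or cs.calls[key][s].genotype is HOM_ALT for s in affected):
            continue
        if any(cs.calls[key][s].genotype in (HET, HOM_ALT) for s in unaffected):
            continue
        entry = freq.get(key)
        if entry is not None and entry.maf is not None and entry.maf > 0.05:
            continue
        expected.add(key)
    assert report.survivors == expected


def test_cascade_order_independence_and_monotonicity():
    cs, ped, freq = _random_callset(seed=7, n=300)
    cfg = CascadeConfig()
    predicates = build_predicates(cs, ped, LOCUS, freq, cfg)
    baseline = run_cascade(cs, ped, LOCUS, freq, cfg).survivors
    rng = random.Random(0)
    for _ in range(5):
        order = predicates[:]
        rng.shuffle(order)
        current = set(cs.variants)
        sizes = [len(current)]
        for _cid, pred in order:
            current = {k for k in current if pred(k)}
            sizes.append(len(current))
        assert current == baseline
        # appending criteria never increases the survivor count
        assert all(b <= a for a, b in itertools.pairwise(sizes))


def test_segregation_symmetry_under_affection_relabel():
    """Relabeling affected/unaffected passes exactly the variants carried by
    all (former) unaffected and no (former) affected members."""
    cs, ped, _ = _random_callset(seed=11, n=200)
    flipped = Pedigree(
        [
            PedigreeMember(m.sample_id, not m.affected, m.cohort)
            if m.cohort == "ngs"
            else m
            for m in ped.members
        ]
    )
    for key in cs.variants:
        got = criterion_segregation(key, cs, flipped, missing_affected="ignore")
        carriers = {
            s: cs.calls[key][s].genotype in (HET, HOM_ALT)
            for s in ped.samples("ngs")
        }
        missing = {
            s: cs.calls[key][s].genotype is MISSING for s in ped.samples("ngs")
        }
        want = all(
            carriers[s] or missing[s] for s in ped.unaffected("ngs")
        ) and not any(carriers[s] for s in ped.affected("ngs"))
        assert got == want


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def test_concordance_simple_partition():
    x, y, z, w = [("chr20", p, "C", "A") for p in (1, 2, 3, 4)]
    part = concordance({x, y, z}, {y, z, w}, "bt2sam", "bwagatk")
    assert part.concordant == {y, z}
    assert part.only_a == {x}
    assert part.only_b == {w}
    assert part.counts() == {
        "concordant": 2,
        "only_bt2sam": 1,
        "only_bwagatk": 1,
    }


def test_concordance_identical_sets_has_empty_differences():
    keys = {("chr20", p, "C", "A") for p in range(50)}
    part = concordance(keys, set(keys))
    assert part.concordant == keys and not part.only_a and not part.only_b


def test_concordance_matches_brute_force_on_random_sets():
    rng = random.Random(3)
    universe = [("chr20", p, "C", "A") for p in range(400)]
    a = {k for k in universe if rng.random() < 0.5}
    b = {k for k in universe if rng.random() < 0.5}
    part = concordance(a, b)
    # brute-force membership arithmetic, element by element
    conc = {k for k in universe if k in a and k in b}
    only_a = {k for k in universe if k in a and k not in b}
    only_b = {k for k in universe if k in b and k not in a}
    assert (part.concordant, part.only_a, part.only_b) == (conc, only_a, only_b)
    # the three parts are disjoint and reconstruct the inputs
    assert part.concordant | part.only_a == a
    assert part.concordant | part.only_b == b
    assert not (part.only_a & part.only_b)
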