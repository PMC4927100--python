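"""Shared fixtures: bundled tables, gene model, and an in-memory call-set
builder for cascade tests."""

from __future__ import annotations

import pytest

from locusprio import fixtures as fx
from locusprio.variant_model import (
    CallSet,
    Genotype,
    SampleCall,
    Variant,
)


@pytest.fixture(scope="session")
def gene_model():
    return fx.load_gene_model()


@pytest.fixture(scope="session")
def reference():
    return fx.load_reference()


@pytest.fixture(scope="session")
def candidate_snvs():
    return fx.load_candidate_snvs()


@pytest.fixture(scope="session")
def candidate_indels():
    return fx.load_candidate_indels()


@pytest.fixture(scope="session")
def decoys():
    return fx.load_decoys()


@pytest.fixture(scope="session")
def locus():
    return fx.load_locus()


@pytest.fixture(scope="session")
def ngs_pedigree():
    return fx.load_ngs_pedigree()


@pytest.fixture(scope="session")
def extended_pedigree():
    return fx.load_extended_pedigree()


def make_callset(
    entries,
    caller: str = "test",
    qual: float = 50.0,
) -> CallSet:
    """Build a call set from compact specs.

    ``entries``: list of (Variant, site_qual or None, {sample: genotype spec})
    where a genotype spec is either a Genotype or a tuple
    (genotype, depth, allele_fraction).
    """
    cs = CallSet(caller=caller)
    for variant, site_qual, calls in entries:
        q = qual if site_qual is None else site_qual
        cs.add_variant(variant, q)
        for sample, spec in calls.items():
            if isinstance(spec, Genotype):
                gt, depth, af = spec, 40, (0.5 if spec.is_carrier else 0.0)
            else:
                gt, depth, af = spec
            cs.add_call(
                SampleCall(
                    sample_id=sample,
                    variant_key=variant.key,
                    genotype=gt,
                    depth=depth,
                    quality=q,
                    allele_fraction=af,
                )
            )
    return cs


@pytest.fixture
def callset_builder():
    return make_callset
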