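"""Bundled desk-scale fixtures: the published candidate-variant tables for
the chromosome-20 corneal dystrophy locus, a hand-built minimal gene model
that reproduces every printed functional category, decoy variants, the
extended-family carrier pattern, the CNV call table and a synthetic
promoter/motif pair for the TFBS scan demo.

The gene models are deliberately minimal synthetic transcripts (not real
exon structures): coordinates, strands and exon layouts were chosen so that
:func:`locusprio.annotation_engine.classify` yields the published category,
exon number and offset label for every candidate variant. The reference
FASTA is synthetic and covers only the two codons needed for the synonymous
calls.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path
import pandas as pd

from ..annotation_engine import GeneModel, VariantMeta, read_gene_model_tsv
from ..segregation_screen import CnvCall, read_cnvs, read_genotype_table
from ..tfbs_scan import Pwm, read_jaspar
from ..variant_model import (
    FrequencyTable,
    IntervalSet,
    Pedigree,
    ReferenceContext,
    Variant,
    VariantKey,
    read_frequencies,
    read_intervals,
    read_pedigree,
)


def _data_path(name: str) -> Path:
    return Path(resources.files(__package__) / "data" / name)


def load_gene_model() -> GeneModel:
    return read_gene_model_tsv(_data_path("gene_model.tsv"), tag="fixture")


def load_reference() -> ReferenceContext:
    return ReferenceContext.from_fasta(_data_path("reference_synthetic.fa"))


def _load_variant_table(
    name: str,
) -> tuple[list[Variant], dict[VariantKey, VariantMeta], pd.DataFrame]:
    frame = pd.read_csv(_data_path(name), sep="\t", dtype={"pos": int})
    variants: dict[VariantKey, Variant] = {}
    meta: dict[VariantKey, VariantMeta] = {}
    for _, row in frame.iterrows():
        rsid = None if pd.isna(row["rsid"]) or row["rsid"] in ("-", ".") else row["rsid"]
        v = Variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"], rsid)
        variants[v.key] = v
        maf = None if pd.isna(row.get("maf")) else float(row["maf"])
        meta[v.key] = VariantMeta(rsid=rsid, maf=maf)
    return list(variants.values()), meta, frame


def load_candidate_snvs() -> tuple[list[Variant], dict[VariantKey, VariantMeta]]:
    """The 12 candidate SNVs (variant inputs + rsid/MAF metadata)."""
    variants, meta, _ = _load_variant_table("candidate_snvs.tsv")
    return variants, meta


def load_expected_snv_table() -> pd.DataFrame:
    """The candidate SNV table with its published annotation columns."""
    return pd.read_csv(_data_path("candidate_snvs.tsv"), sep="\t")


def load_candidate_indels() -> tuple[list[Variant], dict[VariantKey, VariantMeta]]:
    """The 9 candidate indels (deduplicated from the multi-annotation rows)."""
    variants, meta, _ = _load_variant_table("candidate_indels.tsv")
    return variants, meta


def load_expected_indel_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("candidate_indels.tsv"), sep="\t")


def load_decoys() -> list[Variant]:
    """36 purely intronic / ncRNA / intergenic decoy SNVs."""
    variants, _, _ = _load_variant_table("decoy_snvs.tsv")
    return variants


def load_frequencies() -> FrequencyTable:
    return read_frequencies(_data_path("frequencies.tsv"))


def load_locus() -> IntervalSet:
    return read_intervals(_data_path("locus.bed"))


def load_ngs_pedigree() -> Pedigree:
    return read_pedigree(_data_path("ngs_family.ped"))


def load_extended_pedigree() -> Pedigree:
    return read_pedigree(_data_path("extended_family.ped"))


def load_extended_genotypes():
    return read_genotype_table(_data_path("extended_genotypes.tsv"))


def load_cnvs() -> list[CnvCall]:
    return read_cnvs(_data_path("cnv_calls.tsv"))


def load_tfbs_fixture() -> tuple[list[Pwm], str, str]:
    """(motifs, ref promoter sequence, alt promoter sequence) for the
    promoter-variant gain demo; all synthetic."""
    pwms = read_jaspar(_data_path("motif_synthetic.pfm"))
    from Bio import SeqIO

    seqs = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(_data_path("promoter_synthetic.fa")), "fasta")
    }
    return pwms, seqs["promoter_ref"], seqs["promoter_alt"]


def emit(outdir: str | Path) -> list[Path]:
    """Copy every bundled fixture file into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = []
    data_dir = resources.files(__package__) / "data"
    for entry in sorted(data_dir.iterdir(), key=lambda p: p.name):
        target = outdir / entry.name
        shutil.copyfile(str(entry), target)
        out.append(target)
    return out
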