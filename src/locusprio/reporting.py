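"""End-to-end orchestration: read inputs, run the cascade per caller, take
caller concordance, annotate survivors, write candidate tables, summaries
and an audit manifest.

Outputs are deterministic functions of the inputs: no timestamps are
embedded, so re-running on identical inputs yields identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .annotation_engine import (
    CandidateTable,
    GeneModel,
    INDEL_EXCLUDED_CATEGORIES,
    VariantMeta,
    annotate_all,
    exclude_noncandidate,
    read_gene_model_tsv,
    read_gtf,
    summarize,
)
from .errors import ConfigurationError, LocusPrioError
from .filter_cascade import (
    CascadeConfig,
    FilterReport,
    concordance,
    run_cascade,
)
from .variant_model import (
    CallSet,
    ReferenceContext,
    VariantClass,
    merge_callsets,
    normalize_callset,
    read_frequencies,
    read_intervals,
    read_pedigree,
    read_vcf,
)

logger = logging.getLogger(__name__)

SNV_TABLE_COLUMNS = [
    "pos",
    "ref",
    "alt",
    "gene_symbol",
    "rsid",
    "maf",
    "category",
    "exon",
    "label",
    "refseq_id",
    "transcript_id",
    "biotype",
]

INDEL_TABLE_COLUMNS = [
    "pos",
    "indel_type",
    "gene_symbol",
    "ref",
    "alt",
    "category",
    "rsid",
    "maf",
    "refseq_id",
    "transcript_id",
]


@dataclass
class RunConfig:
    """Paths and options for a full analysis run."""

    vcfs: list[str]
    callers: list[str]
    pedigree: str
    intervals: str
    frequencies: str
    gene_model: str
    reference: Optional[str] = None
    merge_mode: str = "union"  # forward the union of callers by default
    cascade: CascadeConfig = field(default_factory=CascadeConfig)

    def __post_init__(self) -> None:
        if len(self.vcfs) not in (1, 2):
            raise ConfigurationError("expected one or two caller VCFs")
        if len(self.callers) != len(self.vcfs):
            raise ConfigurationError("callers must match vcfs one-to-one")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown config keys: {sorted(unknown)}"
            )
        cascade = doc.pop("cascade", None)
        cfg = cls(**doc)
        if cascade:
            known_c = {f.name for f in dataclasses.fields(CascadeConfig)}
            unknown_c = set(cascade) - known_c
            if unknown_c:
                raise ConfigurationError(
                    f"{path}: unknown cascade keys: {sorted(unknown_c)}"
                )
            het_band = cascade.get("het_band")
            if het_band is not None:
                cascade["het_band"] = tuple(het_band)
            cfg.cascade = CascadeConfig(**cascade)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_gene_model(path: str) -> GeneModel:
    if path.endswith((".gtf", ".gff", ".gff3")):
        return read_gtf(path)
    return read_gene_model_tsv(path)


def export_table(table: CandidateTable, style: str, path: str | Path) -> None:
    """Write a candidate table TSV mirroring the published layouts.

    ``style="snv"``: Position/Ref/Alt/Gene/RS number/MAF/annotation/exon/
    label/transcript IDs/biotype. ``style="indel"``: Position/Indel type/
    Gene/Ref/Alt/annotation/RS number/MAF/transcript IDs. Machine output:
    no thousands separators.
    """
    if style not in ("snv", "indel"):
        raise ValueError(f"unknown table style {style!r}")
    frame = table.to_frame()
    if frame.empty:
        import pandas as pd

        cols = SNV_TABLE_COLUMNS if style == "snv" else INDEL_TABLE_COLUMNS
        pd.DataFrame(columns=cols).to_csv(path, sep="\t", index=False)
        return
    if style == "indel":
        kinds = {
            k: table.variants[k].vclass.value.capitalize()
            for k in table.variants
        }
        frame["indel_type"] = [
            kinds.get((r.chrom, r.pos, r.ref, r.alt), "")
            for r in frame.itertuples()
        ]
        cols = INDEL_TABLE_COLUMNS
    else:
        cols = SNV_TABLE_COLUMNS
    for col in ("exon", "intron"):
        if col in frame:
            frame[col] = frame[col].astype("Int64")
    frame = frame.sort_values(["pos", "transcript_id"]).reset_index(drop=True)
    frame[cols].to_csv(path, sep="\t", index=False)


@dataclass
class RunResult:
    outdir: Path
    reports: dict[str, FilterReport]
    snv_table: CandidateTable
    indel_table: CandidateTable
    snv_summary: dict
    indel_summary: dict
    manifest: dict


def run_all(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute the full prioritization analysis and write all outputs.

    Stages: read + normalize caller VCFs, run the seven-criterion cascade per
    caller, partition survivors by caller concordance, merge (union by
    default; indels restricted to the first caller, emulating an
    indel-capable primary pipeline), annotate, exclude non-candidates and
    summarize. Raises on missing inputs; outputs land in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path in [
        *config.vcfs,
        config.pedigree,
        config.intervals,
        config.frequencies,
        config.gene_model,
        *( [config.reference] if config.reference else [] ),
    ]:
        if not Path(path).exists():
            raise LocusPrioError(f"missing input file: {path}")

    reference = (
        ReferenceContext.from_fasta(config.reference)
        if config.reference
        else None
    )
    ped = read_pedigree(config.pedigree)
    intervals = read_intervals(config.intervals)
    frequencies = read_frequencies(config.frequencies)
    gene_model = _load_gene_model(config.gene_model)

    callsets: list[CallSet] = []
    for vcf, label in zip(config.vcfs, config.callers):
        cs = read_vcf(vcf, label, reference=reference)
        callsets.append(normalize_callset(cs))

    reports: dict[str, FilterReport] = {}
    for cs in callsets:
        reports[cs.caller] = run_cascade(
            cs, ped, intervals, frequencies, config.cascade
        )

    if len(callsets) == 2:
        part = concordance(
            reports[callsets[0].caller].survivors,
            reports[callsets[1].caller].survivors,
            callsets[0].caller,
            callsets[1].caller,
        )
        merged = merge_callsets(callsets[0], callsets[1], config.merge_mode)
    else:
        part = None
        merged = callsets[0]

    survivor_keys = set().union(*(r.survivors for r in reports.values()))
    if config.merge_mode == "intersection" and part is not None:
        survivor_keys = part.concordant
    survivors = [merged.variants[k] for k in sorted(survivor_keys) if k in merged.variants]
    # indels forwarded only from the first caller (the indel-capable pipeline)
    first = callsets[0]
    survivors = [
        v
        for v in survivors
        if v.vclass is VariantClass.SNV or v.key in first.variants
    ]
    meta = {}
    for v in survivors:
        entry = frequencies.get(v.key)
        meta[v.key] = VariantMeta(
            rsid=v.rsid or (entry.rsid if entry else None),
            maf=entry.maf if entry else None,
            sources=merged.sources.get(v.key, ()),
        )

    snvs = [v for v in survivors if v.vclass is VariantClass.SNV]
    indels = [v for v in survivors if v.vclass is not VariantClass.SNV]
    snv_table = exclude_noncandidate(
        annotate_all(snvs, gene_model, reference, meta)
    )
    indel_table = exclude_noncandidate(
        annotate_all(indels, gene_model, reference, meta),
        excluded=INDEL_EXCLUDED_CATEGORIES,
    )
    snv_summary = summarize(snv_table).as_dict()
    indel_summary = summarize(indel_table).as_dict()

    export_table(snv_table, "snv", outdir / "candidate_snvs.tsv")
    export_table(indel_table, "indel", outdir / "candidate_indels.tsv")
    with open(outdir / "filter_report.json", "w") as fh:
        json.dump(
            {caller: r.to_records() for caller, r in reports.items()},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(
            {
                "snv": snv_summary,
                "indel": indel_summary,
                "concordance": part.counts() if part else None,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")

    manifest = {
        "version": __version__,
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [
                *config.vcfs,
                config.pedigree,
                config.intervals,
                config.frequencies,
                config.gene_model,
            ]
        },
        "config": {
            "callers": config.callers,
            "merge_mode": config.merge_mode,
            "cascade": dataclasses.asdict(config.cascade),
        },
        "stage_counts": {
            caller: report.counts() for caller, report in reports.items()
        },
        "n_candidate_snvs": len(snv_table.keys()),
        "n_candidate_indels": len(indel_table.keys()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return RunResult(
        outdir=outdir,
        reports=reports,
        snv_table=snv_table,
        indel_table=indel_table,
        snv_summary=snv_summary,
        indel_summary=indel_summary,
        manifest=manifest,
    )
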