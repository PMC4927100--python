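"""Transcript-aware classification: category assignment, offset labels,
multi-transcript rows, exclusion and summary counts."""

from __future__ import annotations

import pytest

from locusprio.annotation_engine import (
    Category,
    GeneModel,
    INDEL_EXCLUDED_CATEGORIES,
    TranscriptModel,
    annotate_all,
    annotation_concordance,
    classify,
    exclude_noncandidate,
    intergenic_row,
    protein_coding_candidates,
    read_gtf,
    summarize,
)
from locusprio.errors import AnnotationError, GeneModelError
from locusprio.variant_model import ReferenceContext, Variant


def by_transcript(rows, tid):
    return next(r for r in rows if r.transcript_id == tid)


# ---------------------------------------------------------------------------
# classify on the bundled worked examples
# ---------------------------------------------------------------------------


def test_synonymous_snv_in_reverse_strand_gene(gene_model, reference):
    """chr20:18,022,362 C>A against the OVOL2 coding transcript is a
    synonymous exon-3 change labelled c.327C>A."""
    t = by_transcript(gene_model.transcripts, "ENST00000278780")
    row = classify(Variant("chr20", 18_022_362, "C", "A"), t, reference)
    assert row.category is Category.SYNONYMOUS
    assert row.exon_number == 3
    assert row.offset_label == "c.327C>A"


def test_promoter_snv_upstream_of_coding_transcript(gene_model):
    t = by_transcript(gene_model.transcripts, "ENST00000278780")
    row = classify(Variant("chr20", 18_038_585, "T", "C"), t)
    assert row.category is Category.PROMOTER
    assert row.offset_label == "c.-307T>C"


def test_utr3_snv_with_starred_offset(gene_model):
    t = by_transcript(gene_model.transcripts, "ENST00000377103")
    row = classify(Variant("chr20", 23_028_063, "A", "G"), t)
    assert row.category is Category.UTR3
    assert row.offset_label == "c.*351A>G"


def test_synonymous_snv_in_forward_strand_gene(gene_model, reference):
    t = by_transcript(gene_model.transcripts, "ENST00000262659")
    row = classify(Variant("chr20", 30_616_835, "G", "A"), t, reference)
    assert row.category is Category.SYNONYMOUS
    assert row.exon_number == 7
    assert row.offset_label == "c.1107G>A"


def test_codon_classification_requires_reference_context(gene_model):
    t = by_transcript(gene_model.transcripts, "ENST00000262659")
    with pytest.raises(AnnotationError):
        classify(Variant("chr20", 30_616_835, "G", "A"), t, None)


def test_missense_and_nonsense_classification():
    # forward-strand single-exon gene; CDS starts at 201
    t = TranscriptModel(
        gene_symbol="G1",
        transcript_id="T1",
        biotype="protein-coding",
        strand="+",
        exons=[(101, 700)],
        cds_start=201,
        cds_end=500,
    )
    #               codon 1 at 201: TGG (Trp)
    ref = ReferenceContext([("chr20", 101, "A" * 100 + "TGGC" + "A" * 496)])
    missense = classify(Variant("chr20", 202, "G", "C"), t, ref)  # TCG = Ser
    assert missense.category is Category.MISSENSE
    nonsense = classify(Variant("chr20", 203, "G", "A"), t, ref)  # TGA = stop
    assert nonsense.category is Category.NONSENSE


def test_splice_window_and_intron_assignment():
    t = TranscriptModel(
        gene_symbol="G1",
        transcript_id="T1",
        biotype="protein-coding",
        strand="+",
        exons=[(101, 200), (301, 400)],
        cds_start=110,
        cds_end=390,
    )
    donor = classify(Variant("chr20", 201, "G", "A"), t)
    acceptor = classify(Variant("chr20", 299, "G", "A"), t)
    deep = classify(Variant("chr20", 250, "G", "A"), t)
    assert donor.category is Category.SPLICE5
    assert acceptor.category is Category.SPLICE3
    assert deep.category is Category.INTRONIC and deep.intron_number == 1
    # reverse strand: donor side flips to the genomic-low exon edge
    t2 = TranscriptModel(
        gene_symbol="G1",
        transcript_id="T2",
        biotype="protein-coding",
        strand="-",
        exons=[(101, 200), (301, 400)],
        cds_start=110,
        cds_end=390,
    )
    assert classify(Variant("chr20", 299, "G", "A"), t2).category is Category.SPLICE5
    assert classify(Variant("chr20", 201, "G", "A"), t2).category is Category.SPLICE3


def test_ncrna_exon_and_downstream_returns_none(gene_model):
    t = by_transcript(gene_model.transcripts, "ENST00000441136")  # KIZ
    row = classify(Variant("chr20", 21_206_900, "A", "G"), t)
    assert row.category is Category.NCRNA
    # downstream of a plus-strand transcript: no annotation from it
    assert classify(Variant("chr20", 21_208_000, "A", "G"), t) is None


def test_classification_is_deterministic(gene_model, reference):
    v = Variant("chr20", 18_022_362, "C", "A")
    t = by_transcript(gene_model.transcripts, "ENST00000278780")
    assert classify(v, t, reference) == classify(v, t, reference)


def test_strand_reflection_preserves_category():
    """Mirroring a transcript and its variant across a coordinate axis (and
    flipping the strand) must preserve the category: the promoter stays
    upstream, introns stay introns."""
    axis = 1_000_000
    t = TranscriptModel(
        gene_symbol="G1",
        transcript_id="T1",
        biotype="processed transcript",
        strand="+",
        exons=[(10_000, 10_400), (10_800, 11_200)],
    )
    mirrored = TranscriptModel(
        gene_symbol="G1",
        transcript_id="T1m",
        biotype="processed transcript",
        strand="-",
        exons=sorted((axis - e, axis - s) for s, e in t.exons),
    )
    for pos in [9_700, 10_100, 10_600, 10_401, 11_199, 10_799]:
        row = classify(Variant("chr20", pos, "A", "G"), t)
        mrow = classify(Variant("chr20", axis - pos, "A", "G"), mirrored)
        assert (row is None) == (mrow is None)
        if row is not None:
            assert row.category is mrow.category
            assert row.exon_number == mrow.exon_number


# ---------------------------------------------------------------------------
# annotate_all / multi-transcript rows
# ---------------------------------------------------------------------------


def test_indel_annotated_to_intron_and_neighbour_promoter(gene_model, reference):
    v = Variant("chr20", 20_034_644, "G", "GTT")
    table = annotate_all([v], gene_model, reference)
    cats = {(r.gene_symbol, r.category) for r in table.rows_for(v.key)}
    assert cats == {
        ("CRNKL1", Category.INTRONIC),
        ("C20orf26", Category.PROMOTER),
    }


def test_deletion_intronic_in_coding_and_exonic_in_noncoding(gene_model, reference):
    v = Variant("chr20", 30_660_366, "TTAAAAAAAA", "T")
    table = annotate_all([v], gene_model, reference)
    rows = table.rows_for(v.key)
    coding = by_transcript(rows, "ENST00000520553")
    noncoding = by_transcript(rows, "ENST00000470092")
    assert coding.category is Category.INTRONIC and coding.intron_number == 2
    assert noncoding.category is Category.NCRNA and noncoding.exon_number == 2


def test_every_variant_gets_at_least_one_row(gene_model, reference):
    lonely = Variant("chr20", 19_500_000, "A", "G")
    table = annotate_all([lonely], gene_model, reference)
    rows = table.rows_for(lonely.key)
    assert len(rows) == 1 and rows[0].category is Category.INTERGENIC


def test_dual_gene_model_annotation_concordance(gene_model, reference):
    reduced = GeneModel(
        [t for t in gene_model.transcripts if t.gene_symbol != "KIZ"],
        tag="reduced",
    )
    v_kiz = Variant("chr20", 21_206_234, "A", "G")
    v_both = Variant("chr20", 18_038_585, "T", "C")
    v_neither = Variant("chr20", 19_500_000, "A", "G")
    table = annotate_all([v_kiz, v_both, v_neither], [gene_model, reduced], reference)
    part = annotation_concordance(table, "fixture", "reduced")
    assert part.concordant == {v_both.key}
    assert part.only_a == {v_kiz.key}
    assert part.only_b == set()


# ---------------------------------------------------------------------------
# exclusion and summaries
# ---------------------------------------------------------------------------


def test_exclude_noncandidate_drops_pure_noncoding_variants(
    gene_model, reference, candidate_snvs, decoys
):
    variants, meta = candidate_snvs
    table = annotate_all(variants + decoys, gene_model, reference, meta)
    kept = exclude_noncandidate(table)
    assert len(kept.keys()) == 12
    assert {k for k in table.keys()} - {k for k in kept.keys()} == {
        d.key for d in decoys
    }


def test_variant_with_mixed_rows_is_retained(gene_model, reference):
    # intronic for one gene, promoter of another: retained with both rows
    v = Variant("chr20", 20_035_056, "T", "TACACACAC")
    kept = exclude_noncandidate(
        annotate_all([v], gene_model, reference),
        excluded=INDEL_EXCLUDED_CATEGORIES,
    )
    assert v.key in kept.keys()
    assert {r.category for r in kept.rows_for(v.key)} == {
        Category.INTRONIC,
        Category.PROMOTER,
    }


def test_exclude_and_summarize_empty_table():
    table = annotate_all([], GeneModel([]))
    kept = exclude_noncandidate(table)
    s = summarize(kept)
    assert s.n_variants == s.n_genes == s.n_protein_coding_genes == 0
    assert s.per_category == {}


def test_summary_gene_dedup_matches_brute_force(gene_model, reference, candidate_snvs):
    variants, meta = candidate_snvs
    table = annotate_all(variants, gene_model, reference, meta)
    s = summarize(table)
    genes = {r.gene_symbol for r in table.rows if r.gene_symbol}
    assert s.n_genes == len(genes)
    assert s.n_variants == len({r.variant_key for r in table.rows})
    # distinct-gene count can never exceed the number of annotation rows
    assert s.n_genes <= len(table.rows)


def test_worst_consequence_precedence(gene_model, reference):
    v = Variant("chr20", 20_034_644, "G", "GTT")
    table = annotate_all([v], gene_model, reference)
    # promoter outranks intronic in the severity-derived single view
    assert table.worst_consequence(v.key) is Category.PROMOTER


def test_protein_coding_candidate_selection(gene_model, reference, candidate_snvs):
    """Only variants with a candidate-category row on a protein-coding
    transcript go forward to the extended screen — the OVOL2 variant that is
    only a promoter of a processed transcript does not qualify."""
    variants, meta = candidate_snvs
    table = exclude_noncandidate(annotate_all(variants, gene_model, reference, meta))
    keys = protein_coding_candidates(table)
    assert keys == [
        ("chr20", 18_022_362, "C", "A"),
        ("chr20", 18_038_585, "T", "C"),
        ("chr20", 23_028_063, "A", "G"),
        ("chr20", 30_616_835, "G", "A"),
    ]


# ---------------------------------------------------------------------------
# model validation and GTF reading
# ---------------------------------------------------------------------------


def test_transcript_model_validation():
    with pytest.raises(GeneModelError):
        TranscriptModel("G", "T", "lincRNA", "*", exons=[(1, 10)])
    with pytest.raises(GeneModelError):
        TranscriptModel("G", "T", "lincRNA", "+", exons=[(1, 10), (5, 20)])
    with pytest.raises(GeneModelError):
        TranscriptModel(
            "G", "T", "protein-coding", "+", exons=[(10, 20)], cds_start=1, cds_end=15
        )


def test_read_gtf_minimal(tmp_path):
    gtf = tmp_path / "m.gtf"
    gtf.write_text(
        'chr20\tx\texon\t101\t200\t.\t+\t.\tgene_name "G1"; transcript_id "T1";\n'
        'chr20\tx\texon\t301\t400\t.\t+\t.\tgene_name "G1"; transcript_id "T1";\n'
        'chr20\tx\tCDS\t150\t350\t.\t+\t.\tgene_name "G1"; transcript_id "T1";\n'
    )
    model = read_gtf(gtf)
    t = model.transcripts[0]
    assert t.gene_symbol == "G1" and t.exons == [(101, 200), (301, 400)]
    assert t.cds_start == 150 and t.cds_end == 350
    assert t.biotype == "protein-coding"
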