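# Methods

This note records the models, conventions and design choices behind
`locusprio`, in the order the pipeline applies them.

## Coordinates, keys and normalization

All internal coordinates are 1-based inclusive (VCF convention); BED input
is converted at the boundary (`start+1`, `end`). A variant's identity is the
key `(chrom, pos, ref, alt)` *after* normalization: shared suffix/prefix
bases are trimmed and indels are shifted left while the trailing base of the
longer allele equals the reference base preceding the current position. The
result is the parsimonious, left-aligned encoding (shortest alleles,
smallest position among equivalents); the operation is idempotent and is
verified in the tests against a brute-force enumeration of all equivalent
encodings over the local reference segment. Normalization needs only local
reference context, so the package carries short reference *segments*
(`ReferenceContext`) rather than a genome; an indel whose context is missing
passes through un-normalized with a warning.

Multiallelic records are split into biallelic variants before anything else;
per-alternate allelic depths are preserved so the original AD vector remains
recoverable. Caller concordance is plain set arithmetic on normalized keys
and deliberately ignores rsIDs and annotations, which callers disagree on.

## The filter cascade

The seven criteria encode the family-based argument for a dominant,
fully penetrant, rare disorder mapped to a known locus: the causal variant
must lie in the linked interval, be a well-supported heterozygous call,
be absent from unrelated unaffected controls, co-segregate perfectly with
affection status, and be rare or absent in the population. Defaults:
depth ≥ 5, quality ≥ 20, heterozygous fraction in [0.4, 0.7], MAF ≤ 0.05,
all boundary-inclusive (the fraction band is taken closed by symmetry with
the printed ≥/≤ operators of the other criteria).

Decisions a user can override, with their defaults:

* **Quality source** — the site-level QUAL, not per-sample GQ
  (`quality_field="GQ"` at read time switches); the criterion as published
  does not specify, so the site score is the default.
* **Per-sample scope** — criteria 2–4 must hold for *every* carrier among
  the affected sequenced samples (`sample_mode="strict"`); `"any"` lets one
  well-supported carrier vouch for the variant.
* **Allele-fraction source** — the read fraction AD_alt/(AD_ref+AD_alt);
  with no AD, a per-sample AF tag; with neither, the call set runs
  genotype-only and criterion 4 reduces to the heterozygous genotype
  (logged as a degraded mode).
* **Missing genotypes** — a missing genotype in an affected member fails
  segregation (`missing_affected="fail"`); missing unaffected or control
  genotypes count as non-carriers. This is the conservative reading of
  "present in affected and absent in unaffected".
* **Caller merging** — the candidate set forwarded to annotation is the
  union of callers with per-variant source labels; indels are forwarded
  only from the first (indel-capable) caller. `merge_mode="intersection"`
  restricts to concordant keys.

The survivor set equals the conjunction of the seven predicates, so the
report's drop attribution (first failing criterion in printed order) never
changes which variants survive. This equivalence, and its order
independence, are property-tested on 1,000 randomized synthetic variants.

## Functional classification

Classification is per (variant, transcript) pair; the multi-row output is
native, because one event can be, e.g., intronic in one gene and a promoter
variant of its neighbour. Category assignment, in precedence of position:

* upstream of the transcript start within the promoter window → `promoter`.
  The window defaults to 1,000 bp: the candidate tables label variants at
  −9 to −666 bp as promoter variants, so 1 kb covers all printed offsets
  with margin. It is a per-transcript field.
* inside the CDS → translate the reference codon against the substituted
  codon (`synonymous` / `nonsense` / `missense`). Reverse-strand
  transcripts are translated in cDNA sense. A CDS-overlapping indel is
  reported as `missense` — the category set has no frameshift class and
  the distinction is out of scope here.
* exonic, outside the CDS of a coding transcript → `utr5`/`utr3` by
  transcript side; exonic in a non-coding biotype → `ncRNA`.
* intronic within ±2 bp of an exon boundary → `splice5` (donor side) /
  `splice3` (acceptor side); deeper → `intronic` with the intron number.
* otherwise `intergenic` (a variant always receives at least one row).

Indels are anchored at their first reference base for all positional tests.

**Labels.** Offset labels are simplified HGVS-like strings: `c.<pos>` in
CDS coordinates, `c.-<d>` for upstream of a coding transcript (distance to
the transcript start), `c.*<d>` past the stop, `n.` forms for non-coding
transcripts. The ref/alt alleles are printed exactly as supplied with the
call — no strand complementing — which is the dialect of caller-centric
candidate tables (a reverse-strand synonymous change prints as `c.327C>A`
with the supplied C/A alleles). Full HGVS normalization (3′ rule for
indels, protein notation) is out of scope.

**Exclusion.** A variant is excluded when every row falls in the excluded
set: `{intronic, ncRNA, intergenic}` for SNVs; for indels only
`{intronic, intergenic}`, so an event whose sole non-intronic context is the
exon of a non-coding transcript (an intron-retaining isoform, say) is
retained. A retained variant keeps all rows, intronic ones included, which
is what the distinct-gene counts in the summaries operate on. A gene counts
as protein-coding if any of its annotated transcripts has a protein-coding
biotype; the single-"worst consequence" view uses the precedence
nonsense > missense > splice > synonymous > UTR > promoter > ncRNA >
intronic > intergenic.

Candidates carried into the extended-family screen are those with at least
one candidate-category row on a *protein-coding transcript* — a promoter
variant of a processed transcript does not qualify even when the gene also
has a coding isoform, matching how such tables count "variants in
protein-coding genes".

## Extended screen and shared CNVs

The extended screen re-applies the segregation predicate to the follow-up
cohort and names the discordant members (affected non-carriers, then
unaffected carriers). In strict mode a cohort member absent from the
genotype table is an error rather than silently a non-carrier.

Shared CNV regions are computed by an elementary-segment sweep over the
breakpoints of all same-chromosome, same-kind calls: a maximal run of
segments where every affected sample's calls cover the segment and no
unaffected sample's do. "Same event" means ≥ 1 bp overlap of same-kind
calls; exact-interval matching is available for identical-probe array
designs. Every output region carries
`requires_orthogonal_validation=True`: high-density array designs can
produce *shared* false positives through competitive hybridization, so an
array-only shared CNV is a hypothesis, not a finding.

## PWM scanning

A matrix column is normalized to frequencies `f` and regularized toward the
uniform background: `p = (f + α·0.25) / (1 + α)` with `α = 0.1`. A window
scores `Σᵢ log₂(pᵢ(bᵢ)/0.25)` and its relative score rescales that between
the matrix's minimum and maximum attainable scores, giving a value in
[0, 1] that is exactly invariant to rescaling the count matrix (the reason
for regularizing frequencies rather than adding a per-cell count
pseudocount). The scores are cross-checked in the tests against Biopython's
PSSM with the equivalent pseudocount.

Scanning is restricted by default to windows overlapping the variant, on
both strands: the question asked is what the *variant* changes, not an
inventory of the promoter (`full=True` scans everything). A site is gained
at threshold t when the alt window reaches t and the matching ref window
does not; lost in the converse case. Note that the count of gained+lost
windows is not monotone in the threshold — a window is gained exactly when
t lies in the interval (ref score, alt score] — the tests assert this exact
characterization. The published FOXO3 gain (77.8 % relative score) depends
on the matrix version and exact promoter sequence of the original analysis;
the bundled motif and promoter pair are synthetic and demonstrate the
mechanism (one gained forkhead-like site at 88.8 %), not the number.

## The simulator

The generator's defaults are the emulated study design: four
affected and four unaffected sequenced family members, seven affected and
twelve unaffected extended members, 100 unrelated unaffected controls, a
two-interval chromosome-20 locus (17,316,434–26,319,280 and
29,420,138–31,826,081), and 300 background variants of which 10 % fall
outside the enriched intervals and 10 % are small indels.

* **Pedigree** — one founder couple (an affected carrier and an unaffected
  non-carrier) and their children; carrier status of each child is set by
  the affection label (dominant, fully penetrant, no phenocopies).
* **Background genotypes** — population MAFs from `0.5·Beta(0.8, 3)`
  (mostly rare, some common); founders and controls drawn under
  Hardy–Weinberg; children inherit one random allele per parent,
  independently per variant (free recombination — only the planted variant
  is linked to affection status). 10 % of background variants are omitted
  from the frequency table, making them novel.
* **Read evidence** — depth ~ NegativeBinomial(size 10, mean 150),
  reflecting deep targeted capture of a small locus; het alt-read
  probability ~ Beta with concentration 400 around 0.5; alt reads binomial
  given depth; site quality ~ Normal(60, 12) clipped at 0. Setting a noise
  parameter to 0 switches that source off deterministically
  (`noiseless_config()` switches them all off).
* **Callers** — two pseudo-callers observe the same truth; each drops a
  true variant record with probability 0.02 and injects private
  false-positive SNVs at 2 per Mb with low (exponential, mean 8) quality,
  so the concordance partition and the effectiveness of the quality
  criterion are predictable from the configuration.

Identical configurations (including the seed) produce byte-identical
emitted files; all randomness flows from one `numpy` generator.

What the simulator deliberately does **not** model: read-level artifacts
(mapping error, strand bias), capture-efficiency variation along the locus,
linkage disequilibrium among background variants, genotyping error in the
extended cohort, and phenocopies or incomplete penetrance. Passing tests
therefore demonstrate the correctness of the filtering logic under the
stated statistical model, not robustness to real-data artifacts.

Under the default noise model the planted variant is recovered in roughly
80–90 % of replicates, and essentially every loss is criterion 4: requiring
*every* affected carrier's read fraction inside [0.4, 0.7] is the lossiest
part of the published design, which is an honest property of the method
rather than a defect of the implementation. Background variants essentially
never survive (the controls plus perfect-segregation criteria remove them),
so the false-candidate count per replicate is ~0 at these cohort sizes.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on bundled fixtures
and simulation. The property suites use 1,000 random variants for the
cascade conjunction oracle, exhaustive 4-mer enumeration for PWM ranking,
and 100 simulated replicates (60 background variants, 10 controls per
replicate) for the recovery-vs-oracle comparison; the headline recovery
rate in `scripts/acceptance.py` uses 100 replicates at the full default
design. These sizes were chosen as the smallest that make the binomial
expectations in the statistical checks meaningfully tight.

## Known limitations

* The annotation engine classifies against minimal transcript models; it
  is not a VEP replacement (no consequence prediction beyond codon
  translation, no full HGVS).
* Splice-site effect *prediction* (MutPred Splice, NetGene2 class tools) is
  out of scope; the ±2 bp window flags canonical-site overlap only.
* CDS indels are reported as protein-altering without frameshift/in-frame
  distinction.
* The cascade performs no statistical association or linkage computation;
  it presumes the locus is already established.
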