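# Methods

## Timing model and CCF estimation

A mutation observed at variant allele frequency VAF in a tumour of purity ρ,
at a locus with allele-specific copy number (major, minor) and total
CN_t = major + minor, has mutation copy number

    n_mut = VAF · (1/ρ) · (ρ·CN_t + 2·(1 − ρ))          (autosomes, CN_n = 2)

This quantity is multiplicity × CCF. We estimate the multiplicity as
m = clamp(round_half_up(n_mut), 1, major) — a mutation cannot occupy more
copies than the major allele carries — and report CCF = n_mut / m, capped at
1.5 to bound purity-error artefacts. Rounding the multiplicity before the
early/late decision (rather than thresholding raw n_mut > 1) keeps
read-sampling noise from calling n_mut = 1.02 "early". Half-up rounding is
used everywhere ties can occur, for determinism.

Clonality: when read counts are available we put an exact (Clopper–Pearson)
two-sided 95% binomial interval on the VAF, push both ends through the
formula above and divide by m; the mutation is subclonal iff the upper CCF
bound is below 1. Without read counts a hard threshold (CCF < 0.9) is used.
Both the interval level (`alpha`) and the fallback threshold are
configuration keys, since published work rarely states its subclonality
test; the CI route is preferred because it adapts to depth.

Timing: only loci with major ≥ 2 are timeable. Subclonal ⇒ late,
regardless of segment — this check runs first, so subclonal mutations are
never reported untimed. Clonal with m ≥ 2 ⇒ early; clonal with m = 1 ⇒
late; clonal with major < 2, no overlapping segment, or missing VAF ⇒
untimed. Mutations with no overlapping segment still get a CCF under a
diploid assumption (CN_t = 2, m = 1) so clonality remains callable.
Cohort summaries partition mutations four ways (early / clonal-late /
subclonal / untimed) to keep the subclonal class visible.

## Driver rules

Census genes (role TSG, oncogene or both in the gene resource) are tested
in fixed order: frameshift indel in a TSG and non-frameshift indel in an
oncogene (both additionally requiring recurrence ≥ 3 in the variant
recurrence table — the recurrence clause is read as binding both indel
classes, switchable with `indel_requires_recurrence`); deleterious TSG
variants (SIFT "deleterious", PolyPhen "probably damaging" — *not*
"possibly damaging" — or any stop-gain/splice variant); and exact variants
recurring > 10 times. Genes outside the census take the wide rule (SIFT
deleterious, PolyPhen probably damaging, stop-gain or frameshift indel, or
recurrence > 10). A mutation can satisfy several rules; the first match is
recorded and the mutation is counted once. SCNA drivers: TSG with total
CN 0 (single-copy losses are deliberately excluded — they belong to the LOH
analysis), oncogene with total CN ≥ 2 × sample ploidy (a GISTIC-like
convention; the threshold multiplier is configurable).

The bundled gene/pathway resources are a compact curated subset: ~47
well-known cancer genes with roles and approximate hg19 loci, and the ten
canonical oncogenic signalling pathways (cell cycle, Hippo, Myc, Notch,
NRF2, PI3K, RTK/RAS, TGF-β, p53, Wnt). The bundled recurrence table is a
small synthetic stand-in with plausible hotspot counts (full recurrence
exports are licence-restricted); production use should supply a real
export via `RunConfig.recurrence`.

## Instability metrics

Ploidy is the length-weighted mean total copy number of the segmentation.
wGII is the unweighted mean over chromosomes of the fraction of segmented
length whose total copy number differs from round(ploidy); a `diploid`
baseline (compare against 2) is available, since the aberration baseline is
a known point of divergence between implementations. LOH fraction is the
length fraction with minor = 0 and major ≥ 1 (homozygous loss is not LOH).
Genome doubling: at least half the segmented length with major ≥ 2,
boundary inclusive. All denominators use segmented length, not genome
length, so sparse segmentations are not penalised; `covered_bp` is reported
for transparency.

## Cohort statistics

All enrichment tests are two-sided Fisher's exact tests on patient counts
(altered vs not, primary vs metastatic) or mutation counts (early vs late in
a unit vs elsewhere; subclonal recoded late to gain power), with
Benjamini–Hochberg FDR within each analysis × stratification run — the FDR
family is a documented choice, since it is rarely printed. Odds ratios are
sample ORs with a Haldane 0.5 correction when any cell is zero, which keeps
log-OR concordance (Pearson correlation of matched log2 ORs across cohorts)
well defined. Hotspot variants are tested per cancer type after a
min-3-patients filter to avoid testing singletons. Per-gene CCF outliers
require ≥ 5 driver mutations per (cohort, cancer type), a z-score against
the distribution of per-gene means, |z| > 2, and at least 3 qualifying genes
(the SD is unstable below that). The gene-length confound check reports the
mean midrank length percentile of an enriched gene set and a two-sided
rank-sum p against the background, because loose driver definitions enrich
long genes by target size alone.

## Synthetic cohort

The generator emulates a primary (WES) vs metastatic (WGS) two-cohort
study on a toy genome (4 chromosomes × 10 Mb, fully tiled by ~120 gene
loci; 32 census genes at fixed positions, with TP53–MAP2K4–NCOR1 adjacent
to mimic a 17p-like tumour-suppressor cluster). Defaults — chosen once as
the study conditions for the test suite — are 50 samples per (cohort ×
cancer type) over BRCA and LUNG (200 total), purity ~ U(0.3, 0.9), 60
mutations per sample, depth 100×, 30% early / 20% subclonal target
fractions, per-segment gain probability 0.4 and LOH probability 0.25, and
genome-doubling probability 0.2 (primary) vs 0.4 (metastatic), reflecting
the higher instability of metastatic disease. Driver injections give
recurrent cancer genes per-cohort prevalence with timing biases (p53 and
RTK/RAS pathway genes early, Notch/Hippo/TGF-β late, CYLD
subclonal-skewed and metastatic-biased); early-biased drivers co-occur with
a gain of their segment with probability 0.9 — the mutation-then-gain
sequence that relative timing detects. Hotspot injections add exact
variants with cohort-restricted prevalence (EGFR and ESR1
metastatic-only "resistance" variants, a BRAF variant depleted in
metastatic samples).

Read counts follow total ~ Poisson(depth), alt ~ Binomial(total, E[VAF])
with E[VAF] = ρ·m·CCF / (ρ·CN_t + 2(1 − ρ)) — the exact inverse of the
estimator, so the noise-free mode is recovered to machine precision. Truth
tables live in a separate `truth/` directory and are read only by tests.

What the generator does **not** model: trinucleotide mutational signatures,
subclonal copy number, multi-region or multi-sample phylogenies, purity
estimation error, and mapping/sequencing artefacts. Passing tests therefore
demonstrate correctness of the estimators under the stated generative model,
not robustness to real-data artefacts such as mis-segmented copy number or
biased purity calls.

## Numerical and design choices

- External coordinates are 1-based inclusive (MAF/SEG convention);
  chromosome labels are normalised by stripping an optional "chr" prefix,
  and anything outside 1–22/X/Y/MT (e.g. "23") is an explicit error.
- Hypermutator cutoffs (counts strictly above 1000 for WES, 60,000 for WGS)
  are applied to raw per-sample mutation counts before any consequence
  filtering; boundary counts are retained.
- Duplicate (sample, chrom, pos, alt) rows are collapsed with a warning;
  invalid rows are rejected with row-numbered diagnostics rather than
  failing the load.
- Degenerate Fisher tables (a zero margin) return p = 1 with an undefined
  OR and are excluded from concordance; empty strata are skipped with
  warnings, never fabricated.
- The pipeline is deterministic given inputs and configuration; the manifest
  records a SHA-256 of all thresholds, so reruns are verifiable.
- Problem sizes in tests (200-sample cohort, 10 kb oracle genomes, 200 null
  replicates, exhaustive Fisher enumeration to margins of 30) were chosen as
  the smallest scales at which each property is convincingly exercised.

## Known limitations

Timing is single-sample and relative to gains only: it cannot order
mutations within unamplified regions, and roughly a quarter to a third of
mutations in realistic configurations are untimeable. CCF capping at 1.5
hides gross purity errors rather than correcting them. The SCNA driver
rules are deliberately coarse (no focality test). The wide driver rule is
known to enrich long genes — that is the point of the confound check, not a
defect to be corrected away.
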