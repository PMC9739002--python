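# mutclock

Tumour life-history analysis from single-sample sequencing data: `mutclock`
times somatic mutations as **early** or **late** relative to copy-number
gains, estimates cancer cell fractions (CCF), annotates driver events by
rule, quantifies chromosomal instability, and runs the cohort-level
statistics needed to compare primary against metastatic tumours — gene,
pathway and hotspot enrichment, per-gene clonality outliers, and pairs of
driver mutations on regions of loss of heterozygosity (LOH).

It is aimed at cancer-genomics analysts who have per-sample somatic mutation
tables (MAF-like), allele-specific segmented copy number (SEG-like) and
sample metadata with tumour purity, and who want a tested, reproducible
implementation of the timing/CCF/driver/enrichment tool-chain. Because the
cohorts this kind of study draws on are access-controlled, the package ships
a synthetic-cohort generator that emulates their structure with full ground
truth, so every stage is testable end to end.

## The model

For a mutation at a locus with total tumour copy number CN_t (major + minor
allele copy number), tumour purity ρ, and normal copy number CN_n = 2
(autosomes only), the **mutation copy number** is

```
n_mut = VAF · (1/ρ) · (ρ·CN_t + CN_n·(1 − ρ))
```

i.e. the number of mutated copies per cancer cell times the fraction of
cancer cells carrying the mutation. Dividing by the **multiplicity**
m = clamp(round(n_mut), 1, major_cn) gives the **CCF** = n_mut / m, which is
1 for a clonal mutation at any purity and multiplicity.

Timing relative to gains: only loci with major allele copy number ≥ 2 are
timeable. A clonal mutation with m ≥ 2 was present before the gain
(**early**); m = 1 means it arrived after (**late**); subclonal mutations
(binomial confidence interval of the CCF entirely below 1) are late by
definition. Everything else is untimed.

Around this core: driver mutations are called by a fixed rule set over gene
roles (tumour suppressor / oncogene), COSMIC-style recurrence counts and
SIFT/PolyPhen labels, with a wide rule for genes outside the census; SCNA
drivers are homozygous TSG deletions and oncogene amplifications (total CN ≥
2 × ploidy); per-sample instability is summarised as wGII, LOH fraction and
genome-doubling status; and all cohort comparisons use two-sided Fisher's
exact tests with Benjamini–Hochberg FDR control.

## Worked example

```
python analysis/01_simulate.py          # synthetic 200-sample cohort
python analysis/02_run_pipeline.py      # full pipeline + summary
python analysis/03_cohort_comparison.py
python analysis/04_timing_and_hotspots.py
python analysis/05_loh_pairs.py
```

`02_run_pipeline.py` ends with (seed 1):

```
metastatic: 6000 mutations — 32% early, 32% late, 19% subclonal, 17% untimed
primary: 6000 mutations — 30% early, 25% late, 19% subclonal, 25% untimed
metastatic: mean 4.02 driver mutations/sample; 6.98 per 100 exonic SNVs
primary: mean 3.43 driver mutations/sample; 5.97 per 100 exonic SNVs
metastatic: mean wGII 0.507, mean LOH fraction 0.284, genome doubled 64%
primary: mean wGII 0.458, mean LOH fraction 0.247, genome doubled 43%
```

The synthetic metastatic cohort is generated with more genome doubling and
slightly higher driver prevalence, and the pipeline recovers exactly that:
higher driver burden, more instability, and fewer untimeable mutations
(more gains ⇒ more timeable loci). `04_timing_and_hotspots.py` then shows
the injected timing structure coming back out — the p53 pathway
early-enriched in *both* cohorts (OR ≈ 14.5, q < 1e-4), late-skewed Wnt /
Notch / Hippo, pathway odds ratios correlated across cohorts (Pearson
r = 0.90) — and the injected treatment-resistance hotspots (EGFR and ESR1,
metastatic-only) flagged at q < 0.05 while the targetable BRAF variant comes
back primary-enriched. `05_loh_pairs.py` finds TP53 + MAP2K4 / NCOR1 as the
dominant driver pairs on LOH segments, the expected signature of a
17p-like single-copy loss priming several tumour suppressors at once.

The same machinery is available as a CLI for your own data:

```
mutclock simulate --seed 1 --out cohort/
mutclock run --config run.yaml --out results/
mutclock summarize results/
```

Input dialects are documented in `mutclock.io` (tab-separated `mutations.tsv`,
`segments.tsv`, `samples.tsv`; 1-based inclusive coordinates).

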