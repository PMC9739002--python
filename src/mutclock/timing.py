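"""Mutation copy number, cancer cell fraction (CCF), clonality and timing.

The mutation copy number at a locus is

    mut_cn = VAF * (1 / purity) * (purity * CN_t + CN_n * (1 - purity))

with CN_t the total tumour copy number of the containing segment and CN_n = 2
on autosomes. Dividing by the estimated multiplicity (the number of mutated
chromosomal copies per cell) gives the CCF: the fraction of cancer cells
carrying the mutation, 1 for a clonal event.

Timing relative to copy-number gains: only loci with major-allele copy number
>= 2 are timeable. A clonal mutation with multiplicity >= 2 predates the gain
(early); multiplicity 1 postdates it (late). Subclonal mutations are late by
definition, regardless of segment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MutclockError
from .io import Cohort, attach_segments

#: Default cap applied to reported CCF to bound purity-error artefacts.
DEFAULT_CCF_CAP = 1.5
#: CCF threshold for calling subclonality when read counts are unavailable.
DEFAULT_CCF_FALLBACK = 0.9
#: Two-sided significance level of the binomial VAF confidence interval.
DEFAULT_ALPHA = 0.05

NORMAL_CN_AUTOSOME = 2


def mutation_copy_number(vaf, purity, total_cn, normal_cn=NORMAL_CN_AUTOSOME):
    """Copy number of the mutated allele per cancer cell (multiplicity x CCF).

    Vectorised over numpy-compatible inputs. purity must be in (0, 1].
    """
    purity = np.asarray(purity, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise MutclockError("purity must lie in (0, 1]")
    vaf = np.asarray(vaf, dtype=float)
    total_cn = np.asarray(total_cn, dtype=float)
    return vaf / purity * (purity * total_cn + normal_cn * (1.0 - purity))


def round_half_up(x):
    """Deterministic half-up rounding (2.5 -> 3), unlike banker's rounding."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def estimate_multiplicity(mut_cn, major_cn):
    """Nearest integer multiplicity, clamped to [1, major_cn].

    A mutation cannot sit on more copies than the major allele provides.
    major_cn = 0 with positive mut_cn is inconsistent input: warn, return 1.
    """
    mut_cn = np.asarray(mut_cn, dtype=float)
    major = np.asarray(major_cn, dtype=float)
    inconsistent = (major < 1) & (mut_cn > 0)
    if np.any(inconsistent):
        warnings.warn("mutation with positive copy number on a segment with "
                      "major_cn = 0; multiplicity forced to 1")
    mult = np.clip(round_half_up(mut_cn), 1, np.maximum(major, 1))
    return mult.astype(np.int64) if mult.ndim else int(mult)


def ccf(mut_cn, multiplicity, cap: float = DEFAULT_CCF_CAP):
    """Cancer cell fraction = mut_cn / multiplicity, capped (default 1.5)."""
    out = np.asarray(mut_cn, dtype=float) / np.asarray(multiplicity, dtype=float)
    return np.minimum(out, cap)


def clopper_pearson(k, n, alpha: float = DEFAULT_ALPHA):
    """Exact (Clopper–Pearson) two-sided binomial CI for a proportion."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    lo = np.where(k > 0, stats.beta.ppf(alpha / 2, k, n - k + 1), 0.0)
    hi = np.where(k < n, stats.beta.ppf(1 - alpha / 2, k + 1, n - k), 1.0)
    return lo, hi


def time_cohort(
    cohort: Cohort,
    alpha: float = DEFAULT_ALPHA,
    ccf_fallback: float = DEFAULT_CCF_FALLBACK,
    ccf_cap: float = DEFAULT_CCF_CAP,
) -> pd.DataFrame:
    """Attach segments and compute mut_cn, multiplicity, CCF, clonality and
    timing for every mutation in the cohort.

    Clonality: with read counts, the (1 - alpha) exact binomial CI on VAF is
    propagated to a CCF interval; subclonal iff its upper bound is < 1.
    Without reads, subclonal iff ccf < ccf_fallback. Mutations with no
    overlapping segment are evaluated under a diploid assumption (CN_t = 2,
    multiplicity 1) for clonality only, and are untimed unless subclonal.
    """
    df = attach_segments(cohort)
    purity = df["sample_id"].map(
        cohort.meta.set_index("sample_id")["purity"]).to_numpy(float)

    has_seg = df["major_cn"].notna().to_numpy()
    major = df["major_cn"].to_numpy(float)
    minor = df["minor_cn"].to_numpy(float)
    total_cn = np.where(has_seg, major + minor, float(NORMAL_CN_AUTOSOME))
    eff_major = np.where(has_seg, major, 1.0)

    vaf = pd.to_numeric(df["vaf"], errors="coerce").astype(float).to_numpy()
    alt0 = df["alt_reads"].to_numpy(dtype=float, na_value=np.nan)
    tot0 = df["total_reads"].to_numpy(dtype=float, na_value=np.nan)
    fill = ~np.isfinite(vaf) & np.isfinite(alt0) & np.isfinite(tot0) & (tot0 > 0)
    vaf = np.where(fill, alt0 / np.where(tot0 > 0, tot0, 1.0), vaf)
    has_vaf = np.isfinite(vaf)
    safe_vaf = np.where(has_vaf, vaf, 0.0)

    mut_cn = mutation_copy_number(safe_vaf, purity, total_cn)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mult = np.asarray(estimate_multiplicity(mut_cn, eff_major))
    ccf_val = ccf(mut_cn, mult, cap=ccf_cap)

    alt = df["alt_reads"].to_numpy(dtype=float, na_value=np.nan)
    tot = df["total_reads"].to_numpy(dtype=float, na_value=np.nan)
    has_reads = np.isfinite(alt) & np.isfinite(tot) & (tot > 0)
    vlo, vhi = clopper_pearson(np.where(has_reads, alt, 0),
                               np.where(has_reads, tot, 1), alpha=alpha)
    ccf_lo = mutation_copy_number(vlo, purity, total_cn) / mult
    ccf_hi = mutation_copy_number(vhi, purity, total_cn) / mult

    clonality = np.full(len(df), "unknown", dtype=object)
    with_reads = has_vaf & has_reads
    clonality[with_reads & (ccf_hi < 1.0)] = "subclonal"
    clonality[with_reads & (ccf_hi >= 1.0)] = "clonal"
    no_reads = has_vaf & ~has_reads
    clonality[no_reads & (ccf_val < ccf_fallback)] = "subclonal"
    clonality[no_reads & (ccf_val >= ccf_fallback)] = "clonal"

    timing = np.full(len(df), "untimed", dtype=object)
    timing[clonality == "subclonal"] = "late"
    timeable = (clonality == "clonal") & has_seg & (major >= 2)
    timing[timeable & (mult >= 2)] = "early"
    timing[timeable & (mult == 1)] = "late"

    out = df.copy()
    out["mut_cn"] = np.where(has_vaf, mut_cn, np.nan)
    out["multiplicity"] = pd.array(np.where(has_vaf, mult, np.nan), dtype="Int64")
    out["ccf"] = np.where(has_vaf, ccf_val, np.nan)
    out["ccf_low"] = np.where(with_reads, ccf_lo, np.nan)
    out["ccf_high"] = np.where(with_reads, ccf_hi, np.nan)
    out["clonality"] = clonality
    out["timing"] = timing
    return out


def timing_class(timed: pd.DataFrame) -> pd.Series:
    """Four-way partition used for cohort summaries: subclonal mutations are
    reported as their own class; 'late' means clonal-late."""
    cls = timed["timing"].copy()
    cls[timed["clonality"] == "subclonal"] = "subclonal"
    return cls


CLASS_ORDER = ["early", "late", "subclonal", "untimed"]


def timing_summary(
    timed: pd.DataFrame,
    meta: pd.DataFrame,
    by_cancer_type: bool = False,
) -> pd.DataFrame:
    """Fractions of early / (clonal) late / subclonal / untimed mutations per
    cohort (optionally per cancer type). Fractions sum to 1 per stratum;
    empty strata are omitted with a warning."""
    df = timed.merge(meta[["sample_id", "cohort", "cancer_type"]], on="sample_id")
    df["class"] = timing_class(df)
    keys = ["cohort", "cancer_type"] if by_cancer_type else ["cohort"]
    rows = []
    for grp_keys, grp in df.groupby(keys):
        if grp.empty:  # pragma: no cover - groupby yields non-empty groups
            continue
        frac = grp["class"].value_counts(normalize=True)
        row = dict(zip(keys, grp_keys if isinstance(grp_keys, tuple) else (grp_keys,)))
        row["n_mutations"] = len(grp)
        for cls in CLASS_ORDER:
            row[f"frac_{cls}"] = float(frac.get(cls, 0.0))
        rows.append(row)
    if not rows:
        warnings.warn("timing summary: no mutations in any stratum")
    return pd.DataFrame(rows)
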