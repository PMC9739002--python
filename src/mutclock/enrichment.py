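"""Cohort-level statistics: Fisher 2x2 tests with BH-FDR correction for gene,
pathway, timing and hotspot enrichment; per-gene mean-CCF outliers; the
gene-length confound check; and cross-cohort odds-ratio concordance.

Contingency convention for primary-vs-metastatic comparisons:

    a = altered metastatic    b = unaltered metastatic
    c = altered primary       d = unaltered primary

so OR > 1 means metastatic-enriched. For early-vs-late timing comparisons,
a/b are early/late hits in the unit and c/d the hits elsewhere, so OR > 1
means early-enriched. The sample odds ratio uses the Haldane 0.5 correction
whenever any cell is zero; p-values are two-sided exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .drivers import GeneResource
from .errors import MutclockError
from .timing import timing_class

FDR_Q = 0.05
HOTSPOT_MIN_PATIENTS = 3
MIN_DRIVERS_PER_GENE = 5
OUTLIER_SD = 2.0


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Returns (odds_ratio, p). The p-value sums all tables with the observed
    margins whose hypergeometric probability does not exceed the observed
    table's. A degenerate table (a zero row or column margin) has p = 1 and
    an undefined (NaN) odds ratio.
    """
    if min(a, b, c, d) < 0:
        raise MutclockError("contingency counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1), in the
    input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _fisher_table(rows: list[dict]) -> pd.DataFrame:
    """Shared finishing step: compute OR/p per row, FDR across the family."""
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["unit", "stratum", "a", "b", "c", "d",
                                     "odds_ratio", "p", "q", "direction"])
    ors, ps = zip(*(fisher_2x2(r.a, r.b, r.c, r.d) for r in df.itertuples()))
    df["odds_ratio"] = ors
    df["p"] = ps
    df["q"] = fdr_adjust(df["p"])
    return df


def _binarize(calls: pd.DataFrame, meta: pd.DataFrame, unit_col: str) -> pd.DataFrame:
    """Patient x unit alteration indicator (one sample per patient)."""
    altered = calls[["sample_id", unit_col]].drop_duplicates()
    return altered.merge(meta[["sample_id", "cohort", "cancer_type"]],
                         on="sample_id")


def gene_enrichment(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    unit_col: str = "gene",
    stratify: str = "pan",
) -> pd.DataFrame:
    """Primary-vs-metastatic enrichment of altered units (genes or pathways).

    One two-sided Fisher test per unit per stratum ('pan' or per cancer
    type), on patients with vs without >= 1 driver call in the unit; BH-FDR
    across all tests of the run. Units altered in no patient are skipped.
    """
    if stratify not in {"pan", "per_type"}:
        raise MutclockError(f"unknown stratification {stratify!r}")
    altered = _binarize(calls, meta, unit_col) if len(calls) else \
        pd.DataFrame(columns=["sample_id", unit_col, "cohort", "cancer_type"])
    strata = [("pan", meta)] if stratify == "pan" else \
        [(ct, grp) for ct, grp in meta.groupby("cancer_type")]
    rows = []
    for stratum, smeta in strata:
        n_met = int((smeta["cohort"] == "metastatic").sum())
        n_pri = int((smeta["cohort"] == "primary").sum())
        sub = altered[altered["sample_id"].isin(set(smeta["sample_id"]))]
        for unit, grp in sub.groupby(unit_col):
            a = int((grp["cohort"] == "metastatic").sum())
            c = int((grp["cohort"] == "primary").sum())
            rows.append({"unit": unit, "stratum": stratum,
                         "a": a, "b": n_met - a, "c": c, "d": n_pri - c})
    df = _fisher_table(rows)
    if not df.empty:
        df["direction"] = np.where(df["odds_ratio"] > 1, "metastatic", "primary")
    return df.reset_index(drop=True)


def timing_enrichment(
    timed_calls: pd.DataFrame,
    unit_col: str = "gene",
    stratum_col: str | None = None,
    min_timed: int = 2,
) -> pd.DataFrame:
    """Early-vs-late enrichment per unit within one cohort's timed driver
    mutations. Subclonal mutations count as late. Contingency: early/late
    hits in the unit vs in all other units; OR > 1 = early-enriched. Units
    with fewer than `min_timed` timed hits are skipped.
    """
    df = timed_calls[timed_calls["timing"].isin(["early", "late"])].copy()
    df = df.dropna(subset=[unit_col])
    strata = [("pan", df)] if stratum_col is None else list(df.groupby(stratum_col))
    rows = []
    for stratum, grp in strata:
        early_tot = int((grp["timing"] == "early").sum())
        late_tot = int((grp["timing"] == "late").sum())
        for unit, ug in grp.groupby(unit_col):
            if len(ug) < min_timed:
                continue
            a = int((ug["timing"] == "early").sum())
            b = int((ug["timing"] == "late").sum())
            rows.append({"unit": unit, "stratum": stratum, "a": a, "b": b,
                         "c": early_tot - a, "d": late_tot - b})
    df = _fisher_table(rows)
    if not df.empty:
        df["direction"] = np.where(df["odds_ratio"] > 1, "early", "late")
    return df.reset_index(drop=True)


def or_concordance(primary: pd.DataFrame, metastatic: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of log2 odds ratios over (unit, stratum) pairs
    present in both cohorts' enrichment tables. Units with an undefined or
    non-positive odds ratio in either cohort are excluded; fewer than 3
    matched units is an error."""
    m = primary.merge(metastatic, on=["unit", "stratum"], suffixes=("_p", "_m"))
    ok = np.isfinite(m["odds_ratio_p"]) & np.isfinite(m["odds_ratio_m"]) & \
        (m["odds_ratio_p"] > 0) & (m["odds_ratio_m"] > 0)
    m = m[ok]
    if len(m) < 3:
        raise MutclockError("odds-ratio concordance needs >= 3 matched units")
    r, p = stats.pearsonr(np.log2(m["odds_ratio_p"]), np.log2(m["odds_ratio_m"]))
    return float(r), float(p)


def hotspot_scan(
    mutations: pd.DataFrame,
    meta: pd.DataFrame,
    min_patients: int = HOTSPOT_MIN_PATIENTS,
) -> pd.DataFrame:
    """Variant-level primary-vs-metastatic enrichment per cancer type.

    A variant is keyed (chrom, pos, ref, alt) and a patient either carries it
    or not. Variants observed in fewer than `min_patients` patients overall
    are not tested; BH-FDR across all tested (variant, cancer type) pairs.
    """
    keys = ["chrom", "pos", "ref", "alt"]
    carriers = mutations[keys + ["gene", "sample_id"]].drop_duplicates()
    n_total = carriers.groupby(keys)["sample_id"].nunique()
    tested = n_total[n_total >= min_patients].index
    carriers = carriers.set_index(keys).loc[tested].reset_index()
    carriers = carriers.merge(meta[["sample_id", "cohort", "cancer_type"]],
                              on="sample_id")
    rows = []
    genes = {}
    cohort_sizes = meta.groupby(["cancer_type", "cohort"]).size()
    for (ct, chrom, pos, ref, alt), grp in carriers.groupby(
            ["cancer_type"] + keys):
        n_met = int(cohort_sizes.get((ct, "metastatic"), 0))
        n_pri = int(cohort_sizes.get((ct, "primary"), 0))
        a = int((grp["cohort"] == "metastatic").sum())
        c = int((grp["cohort"] == "primary").sum())
        unit = f"{chrom}:{pos}:{ref}>{alt}"
        genes[unit] = grp["gene"].iloc[0]
        rows.append({"unit": unit, "stratum": ct,
                     "a": a, "b": n_met - a, "c": c, "d": n_pri - c})
    df = _fisher_table(rows)
    if not df.empty:
        df["gene"] = df["unit"].map(genes)
        df["direction"] = np.where(df["odds_ratio"] > 1, "metastatic", "primary")
    return df.reset_index(drop=True)


def gene_ccf_outliers(
    timed_calls: pd.DataFrame,
    meta: pd.DataFrame,
    min_drivers: int = MIN_DRIVERS_PER_GENE,
    sd_threshold: float = OUTLIER_SD,
) -> pd.DataFrame:
    """Genes whose mean driver-mutation CCF deviates > sd_threshold standard
    deviations from the per-(cohort, cancer type) mean of per-gene means.

    Only genes with >= min_drivers driver mutations in the stratum enter;
    strata with < 3 qualifying genes or zero SD yield no calls.
    """
    df = timed_calls.dropna(subset=["ccf"])
    df = df.drop(columns=[c for c in ("cohort", "cancer_type") if c in df], errors="ignore")
    df = df.merge(meta[["sample_id", "cohort", "cancer_type"]], on="sample_id")
    rows = []
    for (cohort, ct), grp in df.groupby(["cohort", "cancer_type"]):
        per_gene = grp.groupby("gene")["ccf"].agg(["mean", "size"])
        per_gene = per_gene[per_gene["size"] >= min_drivers]
        if len(per_gene) < 3:
            continue
        mu = per_gene["mean"].mean()
        sd = per_gene["mean"].std(ddof=1)
        for gene, r in per_gene.iterrows():
            z = (r["mean"] - mu) / sd if sd > 0 else 0.0
            rows.append({
                "gene": gene, "cohort": cohort, "cancer_type": ct,
                "n_drivers": int(r["size"]), "mean_ccf": float(r["mean"]),
                "zscore": float(z),
                "outlier": bool(sd > 0 and abs(z) > sd_threshold),
            })
    return pd.DataFrame(rows, columns=["gene", "cohort", "cancer_type",
                                       "n_drivers", "mean_ccf", "zscore",
                                       "outlier"])


def gene_length_confound(
    enriched_genes,
    resource: GeneResource,
) -> tuple[float, float]:
    """Do enriched genes skew long? Returns (mean length percentile of the
    enriched set within all resource genes, two-sided rank-sum p of enriched
    vs background lengths). Percentiles use the midrank convention."""
    lengths = resource.roles.set_index("gene")["length_bp"]
    enriched = [g for g in enriched_genes if g in lengths.index]
    if not enriched:
        raise MutclockError("enriched gene set is empty or has no lengths")
    ranks = stats.rankdata(lengths.to_numpy())  # midranks
    pct = pd.Series(ranks / len(lengths), index=lengths.index)
    mean_pct = float(pct.loc[enriched].mean())
    background = lengths.drop(index=enriched)
    _, p = stats.mannwhitneyu(lengths.loc[enriched], background,
                              alternative="two-sided")
    return mean_pct, float(p)


def recode_subclonal_late(timed: pd.DataFrame) -> pd.DataFrame:
    """Ensure subclonal mutations carry timing 'late' (the timing caller
    already does this; kept as an explicit, idempotent recode for inputs
    assembled elsewhere)."""
    out = timed.copy()
    out.loc[timing_class(out) == "subclonal", "timing"] = "late"
    return out
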