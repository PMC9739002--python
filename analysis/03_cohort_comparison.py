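#!/usr/bin/env python
"""Compare primary vs metastatic cohorts: driver burden (raw and per 100
exonic SNVs), chromosomal instability (wGII, LOH fraction, genome doubling),
clonality (mean CCF, per-gene CCF outliers) and gene/pathway enrichment.
Reads results/pipeline/, writes results/cohort_comparison/."""

import argparse
from pathlib import Path

import pandas as pd
from scipy import stats

ROOT = Path(__file__).resolve().parents[1]


def by_cohort(df, meta, col):
    merged = df.merge(meta[["sample_id", "cohort"]], on="sample_id")
    groups = {c: g[col].dropna() for c, g in merged.groupby("cohort")}
    u, p = stats.mannwhitneyu(groups["primary"], groups["metastatic"])
    return groups, p


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pipeline", type=Path, default=ROOT / "results" / "pipeline")
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "cohort_comparison")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    read = lambda name, base=args.pipeline: pd.read_csv(
        base / f"{name}.tsv", sep="\t")
    meta = pd.read_csv(args.cohort / "samples.tsv", sep="\t")

    print("== driver burden ==")
    dps = read("drivers_per_sample")
    rows = []
    for col in ("n_driver_mutations", "drivers_per_100_exonic_snv"):
        groups, p = by_cohort(dps, meta, col)
        rows.append({"metric": col,
                     "mean_primary": groups["primary"].mean(),
                     "mean_metastatic": groups["metastatic"].mean(),
                     "wilcoxon_p": p})
        print(f"  {col}: primary {groups['primary'].mean():.2f} vs "
              f"metastatic {groups['metastatic'].mean():.2f} (p={p:.2g})")

    print("== chromosomal instability ==")
    gm = read("genome_metrics")
    for col in ("wgii", "loh_fraction", "ploidy"):
        groups, p = by_cohort(gm, meta, col)
        rows.append({"metric": col,
                     "mean_primary": groups["primary"].mean(),
                     "mean_metastatic": groups["metastatic"].mean(),
                     "wilcoxon_p": p})
        print(f"  {col}: primary {groups['primary'].mean():.3f} vs "
              f"metastatic {groups['metastatic'].mean():.3f} (p={p:.2g})")
    gd = gm.merge(meta[["sample_id", "cohort"]], on="sample_id") \
        .groupby("cohort")["genome_doubled"].mean()
    print(f"  genome doubled: primary {gd['primary']:.0%} vs "
          f"metastatic {gd['metastatic']:.0%}")

    print("== clonality ==")
    timed = read("timed_mutations")
    mean_ccf = timed.groupby("sample_id")["ccf"].mean().rename("mean_ccf") \
        .reset_index()
    groups, p = by_cohort(mean_ccf, meta, "mean_ccf")
    rows.append({"metric": "mean_ccf_per_sample",
                 "mean_primary": groups["primary"].mean(),
                 "mean_metastatic": groups["metastatic"].mean(),
                 "wilcoxon_p": p})
    print(f"  mean CCF/sample: primary {groups['primary'].mean():.3f} vs "
          f"metastatic {groups['metastatic'].mean():.3f} (p={p:.2g})")
    outliers = read("ccf_outliers")
    flagged = outliers[outliers["outlier"]]
    print(f"  per-gene CCF outliers (|z| > 2, >=5 drivers): {len(flagged)}")
    for r in flagged.itertuples():
        kind = "subclonal-skewed" if r.zscore < 0 else "clonal-skewed"
        print(f"    {r.gene} ({r.cohort} {r.cancer_type}): mean CCF "
              f"{r.mean_ccf:.2f}, z={r.zscore:.1f} -> {kind}")

    print("== enrichment (q < 0.05) ==")
    for name in ("gene_enrichment", "pathway_enrichment"):
        enr = read(name)
        sig = enr[enr["q"] < 0.05]
        print(f"  {name}: {len(sig)} significant of {len(enr)} tests")
        for r in sig.itertuples():
            print(f"    {r.unit} [{r.stratum}]: OR={r.odds_ratio:.2f} "
                  f"({r.direction}-enriched, q={r.q:.3g})")
        sig.to_csv(args.out / f"significant_{name}.tsv", sep="\t", index=False)

    pd.DataFrame(rows).to_csv(args.out / "cohort_metrics.tsv", sep="\t",
                              index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
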