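#!/usr/bin/env python
"""Driver-mutation pairs on LOH segments: which genes co-occur on regions
primed by single-copy loss, per cohort. Reads results/pipeline/, writes
results/loh_pairs/."""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pipeline", type=Path, default=ROOT / "results" / "pipeline")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "loh_pairs")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pairs = pd.read_csv(args.pipeline / "loh_pairs.tsv", sep="\t")
    counts = pd.read_csv(args.pipeline / "loh_pair_counts.tsv", sep="\t")
    partners = pd.read_csv(args.pipeline / "loh_pair_partners.tsv", sep="\t")

    print(f"== {len(pairs)} LOH driver pairs across "
          f"{pairs['sample_id'].nunique() if len(pairs) else 0} samples ==")
    top = counts.groupby(["gene_a", "gene_b"])["count"].sum() \
        .sort_values(ascending=False).head(8)
    for (a, b), n in top.items():
        print(f"  {a} + {b}: {n} samples")

    if len(pairs):
        participation = pd.concat([pairs["gene_a"], pairs["gene_b"]]) \
            .value_counts()
        print("most frequent pair members and their partners:")
        for gene in participation.head(3).index:
            part = partners[partners["gene"] == gene]
            desc = ", ".join(f"{r.partner} ({r.count_})" for r in
                             part.rename(columns={"count": "count_"})
                             .itertuples())
            print(f"  {gene}: {desc}")
        by_cohort = pairs.groupby("cohort").size()
        for cohort, n in by_cohort.items():
            print(f"  {cohort}: {n} pairs")

    counts.to_csv(args.out / "pair_counts.tsv", sep="\t", index=False)
    partners.to_csv(args.out / "pair_partners.tsv", sep="\t", index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
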