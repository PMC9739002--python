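"""Pairs of driver-mutated genes co-located on LOH segments.

Single-copy loss can deliver a "first hit" to every tumour suppressor on the
lost region at once; a region of LOH carrying one driver mutation is
therefore primed for additional inactivating mutations. This module
enumerates, per sample and LOH segment (minor_cn = 0, major_cn >= 1), all
unordered pairs of distinct genes whose driver mutations fall inside the
segment. A pair is counted once per sample even if a gene has several driver
mutations there. Adjacent LOH segments are not merged by default.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd


def merge_adjacent_loh(segments: pd.DataFrame) -> pd.DataFrame:
    """Optional preprocessing: merge touching LOH segments with identical
    copy-number state into one. Non-LOH segments pass through unchanged."""
    out = []
    for (sample, chrom), grp in segments.sort_values(
            ["sample_id", "chrom", "start"]).groupby(["sample_id", "chrom"]):
        prev = None
        for row in grp.to_dict("records"):
            if (prev is not None and prev["minor_cn"] == 0 and row["minor_cn"] == 0
                    and prev["major_cn"] == row["major_cn"]
                    and row["start"] == prev["end"] + 1):
                prev["end"] = row["end"]
            else:
                if prev is not None:
                    out.append(prev)
                prev = dict(row)
        if prev is not None:
            out.append(prev)
    return pd.DataFrame(out, columns=segments.columns)


def find_loh_pairs(
    driver_mutations: pd.DataFrame,
    segments: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Enumerate per-sample LOH gene pairs.

    driver_mutations needs sample_id, chrom, pos, gene. Returns one row per
    (sample, LOH segment, gene pair) with gene_a < gene_b lexicographically,
    annotated with cohort/cancer_type when metadata is given.
    """
    loh = segments[(segments["minor_cn"] == 0) & (segments["major_cn"] >= 1)]
    rows = []
    muts_by_sample = dict(tuple(driver_mutations.groupby("sample_id")))
    for seg in loh.itertuples():
        muts = muts_by_sample.get(seg.sample_id)
        if muts is None:
            continue
        inside = muts[(muts["chrom"] == seg.chrom) &
                      (muts["pos"] >= seg.start) & (muts["pos"] <= seg.end)]
        genes = sorted(inside["gene"].unique())
        for gene_a, gene_b in combinations(genes, 2):
            rows.append({
                "sample_id": seg.sample_id, "chrom": seg.chrom,
                "seg_start": seg.start, "seg_end": seg.end,
                "major_cn": seg.major_cn, "minor_cn": seg.minor_cn,
                "gene_a": gene_a, "gene_b": gene_b,
            })
    cols = ["sample_id", "chrom", "seg_start", "seg_end", "major_cn",
            "minor_cn", "gene_a", "gene_b"]
    out = pd.DataFrame(rows, columns=cols)
    if meta is not None:
        out = out.merge(meta[["sample_id", "cohort", "cancer_type"]],
                        on="sample_id", how="left")
    return out.sort_values(cols[:3] + ["gene_a", "gene_b"]).reset_index(drop=True)


def pair_summary(pairs: pd.DataFrame, top_k: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate pair counts and partner tables.

    Returns (pair_counts, partners): pair_counts per (gene_a, gene_b, cohort,
    cancer_type) sorted by count desc then lexicographically; partners lists,
    for the top_k genes by overall pair participation, the counts of each
    partner gene. Both orderings are deterministic.
    """
    group_cols = ["gene_a", "gene_b"]
    for col in ("cohort", "cancer_type"):
        if col in pairs.columns:
            group_cols.append(col)
    if pairs.empty:
        return (pd.DataFrame(columns=group_cols + ["count"]),
                pd.DataFrame(columns=["gene", "partner", "count"]))
    counts = (pairs.groupby(group_cols).size().rename("count").reset_index()
              .sort_values(["count"] + group_cols, ascending=[False] + [True] * len(group_cols))
              .reset_index(drop=True))

    long = pd.concat([
        pairs.rename(columns={"gene_a": "gene", "gene_b": "partner"}),
        pairs.rename(columns={"gene_b": "gene", "gene_a": "partner"}),
    ])[["gene", "partner"]]
    participation = long.groupby("gene").size().sort_values(ascending=False)
    top = sorted(participation.head(top_k).index,
                 key=lambda g: (-participation[g], g))
    partners = (long[long["gene"].isin(top)]
                .groupby(["gene", "partner"]).size().rename("count").reset_index()
                .sort_values(["gene", "count", "partner"],
                             ascending=[True, False, True])
                .reset_index(drop=True))
    return counts, partners
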