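"""Cohort I/O: MAF-like mutation tables, SEG-like allele-specific copy number,
and sample metadata, plus cohort-level QC (hypermutator removal, autosome
restriction) and mutation/segment overlap.

External files use 1-based inclusive coordinates (MAF/SEG convention). Rows
violating record invariants are rejected with row-numbered diagnostics rather
than failing the whole load; structural problems (missing columns, unknown
sample ids) raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortFormatError, DataIntegrityError, LinkageError

MUTATION_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "alt_reads", "total_reads", "vaf", "sift", "polyphen",
]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "major_cn", "minor_cn"]
META_COLUMNS = ["sample_id", "cohort", "cancer_type", "platform", "purity"]

CONSEQUENCE_CLASSES = {
    "nonsyn_snv", "frameshift_indel", "nonframeshift_indel", "stopgain",
    "splice", "synonymous", "other",
}
SIFT_LABELS = {"deleterious", "tolerated", "NA"}
POLYPHEN_LABELS = {"probably_damaging", "possibly_damaging", "benign", "NA"}
COHORTS = {"primary", "metastatic"}
PLATFORMS = {"WES", "WGS"}

AUTOSOMES = [str(i) for i in range(1, 23)]
_VALID_CHROMS = set(AUTOSOMES) | {"X", "Y", "MT"}

#: Default hypermutator cutoffs (strict inequality: counts above are removed).
WES_HYPERMUTATOR_CUTOFF = 1000
WGS_HYPERMUTATOR_CUTOFF = 60000


@dataclass
class Cohort:
    """A joined somatic-mutation dataset: mutations, allele-specific segments
    and per-sample metadata. Every mutation/segment sample_id must have a
    metadata row."""

    mutations: pd.DataFrame
    segments: pd.DataFrame
    meta: pd.DataFrame
    diagnostics: list[str] = field(default_factory=list)

    def copy(self) -> "Cohort":
        return Cohort(self.mutations.copy(), self.segments.copy(),
                      self.meta.copy(), list(self.diagnostics))


def normalize_chrom(label: object) -> str:
    """Strip an optional 'chr' prefix (case-insensitive) and validate against
    1–22, X, Y, MT. Anything else (including '23') is an explicit error."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "M":
        s = "MT"
    if s not in _VALID_CHROMS:
        raise CohortFormatError(f"unparseable chromosome label: {label!r}")
    return s


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{what}: missing required column(s) {missing}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _numeric(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series.mask(series == "", np.nan), errors="coerce")


def read_mutations(path) -> tuple[pd.DataFrame, list[str]]:
    raw = _read_tsv(path)
    _require_columns(raw, MUTATION_COLUMNS, "mutations table")
    df = raw[MUTATION_COLUMNS].copy()
    df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
    df["pos"] = _numeric(df["pos"])
    for col in ("alt_reads", "total_reads", "vaf"):
        df[col] = _numeric(df[col])
    df["sift"] = df["sift"].replace("", "NA")
    df["polyphen"] = df["polyphen"].replace("", "NA")

    diagnostics: list[str] = []
    bad = pd.Series(False, index=df.index)

    def reject(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        mask = mask & ~bad
        for i in df.index[mask]:
            diagnostics.append(f"mutations row {i + 2}: {reason}")
        bad |= mask

    reject(df["pos"].isna() | (df["pos"] < 1), "pos must be a 1-based integer")
    reject(df["ref"] == df["alt"], "ref equals alt")
    reject(~df["consequence"].isin(CONSEQUENCE_CLASSES), "unknown consequence class")
    reject(~df["sift"].isin(SIFT_LABELS), "unknown SIFT label")
    reject(~df["polyphen"].isin(POLYPHEN_LABELS), "unknown PolyPhen label")
    has_reads = df["alt_reads"].notna() & df["total_reads"].notna()
    reject(has_reads & (df["alt_reads"] > df["total_reads"]),
           "alt_reads > total_reads")
    reject(has_reads & (df["total_reads"] <= 0), "total_reads must be positive")
    reject(~has_reads & df["vaf"].isna(), "vaf required when read counts absent")
    reject(df["vaf"].notna() & ((df["vaf"] < 0) | (df["vaf"] > 1)),
           "vaf outside [0, 1]")
    # vaf must equal alt/total when both are present (tolerance 1e-9);
    # fill vaf from reads when missing.
    has_reads = has_reads & ~bad
    implied = df.loc[has_reads, "alt_reads"] / df.loc[has_reads, "total_reads"]
    stated = df.loc[has_reads, "vaf"]
    mism = has_reads.copy()
    mism.loc[has_reads] = stated.notna() & ((stated - implied).abs() > 1e-9)
    reject(mism, "vaf inconsistent with alt_reads/total_reads")
    fill = has_reads & df["vaf"].isna() & ~bad
    df.loc[fill, "vaf"] = df.loc[fill, "alt_reads"] / df.loc[fill, "total_reads"]

    df = df[~bad].copy()
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("alt_reads", "total_reads"):
        df[col] = df[col].astype("Int64")

    dup = df.duplicated(subset=["sample_id", "chrom", "pos", "alt"], keep="first")
    if dup.any():
        warnings.warn(f"collapsed {int(dup.sum())} duplicate mutation row(s) "
                      "at identical (sample, chrom, pos, alt)")
        df = df[~dup]
    return df.reset_index(drop=True), diagnostics


def read_segments(path) -> tuple[pd.DataFrame, list[str]]:
    raw = _read_tsv(path)
    _require_columns(raw, SEGMENT_COLUMNS, "segments table")
    df = raw[SEGMENT_COLUMNS].copy()
    df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
    for col in ("start", "end", "major_cn", "minor_cn"):
        df[col] = _numeric(df[col])

    diagnostics: list[str] = []
    bad = pd.Series(False, index=df.index)

    def reject(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        mask = mask & ~bad
        for i in df.index[mask]:
            diagnostics.append(f"segments row {i + 2}: {reason}")
        bad |= mask

    for col in ("start", "end", "major_cn", "minor_cn"):
        reject(df[col].isna(), f"{col} must be an integer")
    reject((df["start"] < 1) | (df["end"] < df["start"]),
           "require 1 <= start <= end")
    reject((df["minor_cn"] < 0) | (df["major_cn"] < df["minor_cn"]),
           "require major_cn >= minor_cn >= 0")

    df = df[~bad].copy()
    for col in ("start", "end", "major_cn", "minor_cn"):
        df[col] = df[col].astype(np.int64)

    # Within one sample/chromosome, segments must not overlap; reject the
    # later-starting row of each offending pair.
    df = df.sort_values(["sample_id", "chrom", "start"], kind="mergesort")
    same = (df["sample_id"] == df["sample_id"].shift()) & \
           (df["chrom"] == df["chrom"].shift())
    overlap = same & (df["start"] <= df["end"].shift())
    for i in df.index[overlap]:
        diagnostics.append(f"segments row {i + 2}: overlaps previous segment "
                           "on the same sample/chromosome")
    df = df[~overlap]
    return df.reset_index(drop=True), diagnostics


def read_meta(path) -> tuple[pd.DataFrame, list[str]]:
    raw = _read_tsv(path)
    _require_columns(raw, META_COLUMNS, "samples table")
    df = raw[META_COLUMNS].copy()
    df["purity"] = _numeric(df["purity"])

    diagnostics: list[str] = []
    bad = pd.Series(False, index=df.index)

    def reject(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        mask = mask & ~bad
        for i in df.index[mask]:
            diagnostics.append(f"samples row {i + 2}: {reason}")
        bad |= mask

    reject(~df["cohort"].isin(COHORTS), "cohort must be primary|metastatic")
    reject(~df["platform"].isin(PLATFORMS), "platform must be WES|WGS")
    reject(df["purity"].isna() | (df["purity"] <= 0) | (df["purity"] > 1),
           "purity must lie in (0, 1]")
    reject(df["sample_id"].duplicated(keep="first"), "duplicate sample_id")
    return df[~bad].reset_index(drop=True), diagnostics


def read_cohort(mutation_path, segment_path, meta_path) -> Cohort:
    """Load and validate the three cohort tables and check sample linkage."""
    mutations, d1 = read_mutations(mutation_path)
    segments, d2 = read_segments(segment_path)
    meta, d3 = read_meta(meta_path)
    known = set(meta["sample_id"])
    for what, df in (("mutations", mutations), ("segments", segments)):
        unknown = sorted(set(df["sample_id"]) - known)
        if unknown:
            raise LinkageError(f"{what} reference unknown sample_id(s): "
                               f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}")
    diags = d1 + d2 + d3
    for msg in diags:
        warnings.warn(msg)
    return Cohort(mutations, segments, meta, diags)


def write_cohort(cohort: Cohort, mutation_path, segment_path, meta_path) -> None:
    """Write the three tables in the documented dialects (NA -> empty)."""
    mut = cohort.mutations.copy()
    mut["sift"] = mut["sift"].replace("NA", "")
    mut["polyphen"] = mut["polyphen"].replace("NA", "")
    mut.to_csv(mutation_path, sep="\t", index=False, na_rep="")
    cohort.segments.to_csv(segment_path, sep="\t", index=False)
    cohort.meta.to_csv(meta_path, sep="\t", index=False, float_format="%.6g")


def filter_hypermutators(
    cohort: Cohort,
    wes_cutoff: int = WES_HYPERMUTATOR_CUTOFF,
    wgs_cutoff: int = WGS_HYPERMUTATOR_CUTOFF,
) -> tuple[Cohort, list[str]]:
    """Remove hypermutated samples: per-sample mutation count strictly above
    the platform cutoff (WES: 1000, WGS: 60,000). Counts use all loaded
    mutation rows, before any consequence filtering. Boundary counts are
    retained. Idempotent."""
    meta = cohort.meta
    if meta["platform"].isna().any() or (~meta["platform"].isin(PLATFORMS)).any():
        from .errors import ConfigError
        raise ConfigError("every sample needs platform WES|WGS for the "
                          "hypermutator filter")
    counts = cohort.mutations.groupby("sample_id").size()
    cutoffs = meta.set_index("sample_id")["platform"].map(
        {"WES": wes_cutoff, "WGS": wgs_cutoff})
    n = counts.reindex(cutoffs.index, fill_value=0)
    removed = sorted(n.index[n > cutoffs])
    keep = set(cutoffs.index) - set(removed)
    out = Cohort(
        cohort.mutations[cohort.mutations["sample_id"].isin(keep)].reset_index(drop=True),
        cohort.segments[cohort.segments["sample_id"].isin(keep)].reset_index(drop=True),
        meta[meta["sample_id"].isin(keep)].reset_index(drop=True),
        list(cohort.diagnostics),
    )
    return out, removed


def restrict_autosomes(cohort: Cohort) -> Cohort:
    """Drop mutations and segments on X, Y and MT; keep autosomes 1–22."""
    return Cohort(
        cohort.mutations[cohort.mutations["chrom"].isin(AUTOSOMES)].reset_index(drop=True),
        cohort.segments[cohort.segments["chrom"].isin(AUTOSOMES)].reset_index(drop=True),
        cohort.meta,
        list(cohort.diagnostics),
    )


def overlap_segment(mut: pd.Series, segments: pd.DataFrame):
    """Return the unique segment (row) of the mutation's sample containing its
    position (start <= pos <= end, same chromosome), or None. Two containing
    segments is a data-integrity error."""
    hit = segments[(segments["chrom"] == mut["chrom"]) &
                   (segments["start"] <= mut["pos"]) &
                   (segments["end"] >= mut["pos"])]
    if len(hit) > 1:
        raise DataIntegrityError(
            f"position {mut['chrom']}:{mut['pos']} contained in "
            f"{len(hit)} overlapping segments")
    if hit.empty:
        return None
    return hit.iloc[0]


def attach_segments(cohort: Cohort) -> pd.DataFrame:
    """Join each mutation onto the segment containing it (same sample and
    chromosome). Returns the mutation table with seg_start, seg_end, major_cn,
    minor_cn columns; mutations outside any segment get NA there."""
    seg = cohort.segments.rename(columns={"start": "seg_start", "end": "seg_end"})
    merged = cohort.mutations.reset_index(names="_mut_idx").merge(
        seg, on=["sample_id", "chrom"], how="left")
    inside = (merged["seg_start"] <= merged["pos"]) & (merged["pos"] <= merged["seg_end"])
    merged.loc[~inside.fillna(False), ["seg_start", "seg_end", "major_cn", "minor_cn"]] = np.nan
    hits = merged[inside.fillna(False)]
    multi = hits["_mut_idx"].duplicated(keep=False)
    if multi.any():
        row = hits[multi].iloc[0]
        raise DataIntegrityError(
            f"position {row['chrom']}:{row['pos']} of sample "
            f"{row['sample_id']} contained in overlapping segments")
    # one output row per mutation: the containing-segment row when it exists
    merged = merged.sort_values(["_mut_idx", "seg_start"], na_position="last")
    merged["_has"] = merged["seg_start"].notna()
    merged = merged.sort_values(["_mut_idx", "_has"], ascending=[True, False],
                                kind="mergesort")
    out = merged.drop_duplicates("_mut_idx", keep="first")
    out = out.sort_values("_mut_idx").drop(columns=["_mut_idx", "_has"])
    for col in ("major_cn", "minor_cn"):
        out[col] = out[col].astype("Float64")
    return out.reset_index(drop=True)
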