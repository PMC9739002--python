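"""Per-sample chromosomal-instability metrics from allele-specific segments:
ploidy, weighted genome integrity index (wGII), LOH fraction and
genome-doubling status.

Definitions (autosomes only; lengths are 1-based inclusive interval lengths):

* ploidy — length-weighted mean total copy number over all segments.
* wGII — for each chromosome, the fraction of its segmented length whose
  total copy number differs from the rounded sample ploidy; wGII is the
  unweighted mean of these per-chromosome fractions (chromosomes without
  segments are excluded). A config switch compares against 2 instead.
* LOH fraction — segmented length with minor_cn = 0 and major_cn >= 1,
  divided by the total segmented length.
* genome doubled — at least half of the segmented length has major_cn >= 2.

Denominators use segmented length rather than genome-build length so sparse
segmentations are not penalised; covered_bp is reported for transparency.
"""

from __future__ import annotations

from importlib import resources as _ires

import numpy as np
import pandas as pd

from .errors import MutclockError
from .timing import round_half_up


def load_build(path=None) -> pd.DataFrame:
    """Chromosome lengths (chrom, length_bp). Defaults to bundled hg19
    autosomes; synthetic builds may be supplied for tests."""
    if path is None:
        path = _ires.files("mutclock.resources") / "build_hg19.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length_bp": np.int64})
    if (df["length_bp"] <= 0).any():
        raise MutclockError("build lengths must be positive")
    return df


def _lengths(segments: pd.DataFrame) -> np.ndarray:
    return (segments["end"] - segments["start"] + 1).to_numpy(float)


def sample_ploidy(segments: pd.DataFrame) -> float:
    """Length-weighted mean total copy number across segments."""
    if segments.empty:
        raise MutclockError("cannot compute ploidy of an empty segmentation")
    w = _lengths(segments)
    total = (segments["major_cn"] + segments["minor_cn"]).to_numpy(float)
    return float(np.average(total, weights=w))


def wgii(segments: pd.DataFrame, baseline: str = "ploidy") -> float:
    """Weighted genome integrity index.

    baseline='ploidy' (default) marks a base as aberrant when its total copy
    number differs from round(sample ploidy); baseline='diploid' compares
    against 2.
    """
    if segments.empty:
        raise MutclockError("cannot compute wGII of an empty segmentation")
    if baseline == "ploidy":
        ref = round_half_up(sample_ploidy(segments))
    elif baseline == "diploid":
        ref = 2.0
    else:
        raise MutclockError(f"unknown wGII baseline {baseline!r}")
    df = segments.assign(
        _len=_lengths(segments),
        _aberrant=(segments["major_cn"] + segments["minor_cn"] != ref),
    )
    per_chrom = df.groupby("chrom").apply(
        lambda g: g.loc[g["_aberrant"], "_len"].sum() / g["_len"].sum(),
        include_groups=False,
    )
    return float(per_chrom.mean())


def loh_fraction(segments: pd.DataFrame) -> float:
    """Fraction of segmented length under LOH (minor_cn = 0, major_cn >= 1)."""
    if segments.empty:
        raise MutclockError("cannot compute LOH fraction of an empty segmentation")
    w = _lengths(segments)
    loh = (segments["minor_cn"] == 0) & (segments["major_cn"] >= 1)
    return float(w[loh.to_numpy()].sum() / w.sum())


def genome_doubled(segments: pd.DataFrame) -> bool:
    """True iff >= half the segmented length has major_cn >= 2 (boundary
    inclusive)."""
    if segments.empty:
        raise MutclockError("cannot assess genome doubling of an empty segmentation")
    w = _lengths(segments)
    hit = (segments["major_cn"] >= 2).to_numpy()
    return bool(w[hit].sum() >= 0.5 * w.sum())


def genome_metrics(segments: pd.DataFrame, baseline: str = "ploidy") -> pd.DataFrame:
    """Per-sample GenomeMetrics table: wgii, loh_fraction, ploidy,
    genome_doubled, covered_bp."""
    rows = []
    for sample_id, seg in segments.groupby("sample_id"):
        rows.append({
            "sample_id": sample_id,
            "wgii": wgii(seg, baseline=baseline),
            "loh_fraction": loh_fraction(seg),
            "ploidy": sample_ploidy(seg),
            "genome_doubled": genome_doubled(seg),
            "covered_bp": int(_lengths(seg).sum()),
        })
    return pd.DataFrame(rows, columns=["sample_id", "wgii", "loh_fraction",
                                       "ploidy", "genome_doubled", "covered_bp"])
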