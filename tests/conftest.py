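"""Shared fixtures: hand-built micro-cohorts and one session-scoped default
synthetic cohort with its pipeline outputs."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mutclock.io import Cohort
from mutclock.pipeline import RunConfig, run_pipeline
from mutclock.simulate import SimConfig, write_simulation


def make_mutations(rows: list[dict]) -> pd.DataFrame:
    defaults = dict(ref="A", alt="T", gene="PSG001", consequence="nonsyn_snv",
                    alt_reads=pd.NA, total_reads=pd.NA, vaf=0.5,
                    sift="tolerated", polyphen="benign")
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    out["alt_reads"] = out["alt_reads"].astype("Int64")
    out["total_reads"] = out["total_reads"].astype("Int64")
    out["chrom"] = out["chrom"].astype(str)
    return out


def make_segments(rows: list[dict]) -> pd.DataFrame:
    out = pd.DataFrame(rows)
    out["chrom"] = out["chrom"].astype(str)
    return out


def make_meta(rows: list[dict]) -> pd.DataFrame:
    defaults = dict(cohort="primary", cancer_type="BRCA", platform="WES",
                    purity=1.0)
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_cohort(mutations, segments, meta) -> Cohort:
    return Cohort(make_mutations(mutations), make_segments(segments),
                  make_meta(meta))


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default study conditions (200 samples, depth 100x, seed 1), written
    to disk once per session."""
    outdir = tmp_path_factory.mktemp("sim") / "bundle"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = write_simulation(SimConfig(seed=1), outdir)
    return outdir, result


@pytest.fixture(scope="session")
def pipeline_run(sim_bundle, tmp_path_factory):
    """Full pipeline over the default synthetic cohort."""
    outdir, result = sim_bundle
    run_dir = tmp_path_factory.mktemp("run") / "out"
    cfg = RunConfig(
        mutations=str(outdir / "mutations.tsv"),
        segments=str(outdir / "segments.tsv"),
        samples=str(outdir / "samples.tsv"),
        gene_roles=str(outdir / "gene_roles.tsv"),
        pathways=str(outdir / "pathways.tsv"),
        recurrence=str(outdir / "recurrence.tsv"),
        out_dir=str(run_dir),
        seed=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = run_pipeline(cfg)
    return {"config": cfg, "tables": tables, "dir": run_dir,
            "bundle": outdir, "sim": result}
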