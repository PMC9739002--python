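#!/usr/bin/env python
"""Run the full analysis pipeline (QC, timing, drivers, instability metrics,
enrichment, hotspots, LOH pairs) on the cohort from 01_simulate.py.
Writes results/pipeline/ and prints the run summary."""

import argparse
from pathlib import Path

from mutclock.pipeline import RunConfig, run_pipeline, summarize

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "pipeline")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = RunConfig(
        mutations=str(args.cohort / "mutations.tsv"),
        segments=str(args.cohort / "segments.tsv"),
        samples=str(args.cohort / "samples.tsv"),
        gene_roles=str(args.cohort / "gene_roles.tsv"),
        pathways=str(args.cohort / "pathways.tsv"),
        recurrence=str(args.cohort / "recurrence.tsv"),
        out_dir=str(args.out),
        seed=args.seed,
    )
    tables = run_pipeline(cfg)
    print(f"wrote {len(tables)} tables to {args.out}:")
    for name, df in tables.items():
        print(f"  {name}: {len(df)} rows")
    print()
    print(summarize(args.out))


if __name__ == "__main__":
    main()
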