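#!/usr/bin/env python
"""Generate the study cohort: a synthetic primary (WES) vs metastatic (WGS)
two-cancer-type bundle with ground truth, under the default study conditions
(200 samples, depth 100x). Writes results/cohort/."""

import argparse
from pathlib import Path

from mutclock.simulate import SimConfig, write_simulation

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    res = write_simulation(cfg, args.out, overwrite=True)
    meta = res.cohort.meta
    print(f"wrote {args.out}")
    print(f"  samples: {len(meta)} "
          f"({(meta.cohort == 'primary').sum()} primary WES, "
          f"{(meta.cohort == 'metastatic').sum()} metastatic WGS), "
          f"cancer types: {', '.join(sorted(meta.cancer_type.unique()))}")
    print(f"  mutations: {len(res.cohort.mutations)}, "
          f"segments: {len(res.cohort.segments)}")
    print(f"  ground truth drivers injected: "
          f"{int(res.truth_mutations.is_driver.sum())} mutations; "
          f"genome-doubled samples: {int(res.truth_samples.true_gd.sum())}")


if __name__ == "__main__":
    main()
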