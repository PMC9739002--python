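"""End-to-end orchestration: QC -> timing -> drivers -> genome metrics ->
enrichment -> hotspots -> LOH pairs, with a reproducible run manifest.

The pipeline itself is deterministic; the seed is recorded in the manifest
for provenance of any upstream simulation. Each stage writes its TSVs as it
completes, so an aborted run preserves partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .drivers import (call_driver_scna, call_drivers, drivers_per_sample,
                      load_gene_resource, load_recurrence, map_to_pathways)
from .enrichment import (gene_ccf_outliers, gene_enrichment, hotspot_scan,
                         or_concordance, timing_enrichment)
from .errors import MutclockError
from .instability import genome_metrics, sample_ploidy
from .io import (filter_hypermutators, read_cohort, restrict_autosomes,
                 WES_HYPERMUTATOR_CUTOFF, WGS_HYPERMUTATOR_CUTOFF)
from .lohpairs import find_loh_pairs, pair_summary
from .timing import (DEFAULT_ALPHA, DEFAULT_CCF_CAP, DEFAULT_CCF_FALLBACK,
                     time_cohort, timing_summary)

STAGES = ["qc", "timing", "drivers", "metrics", "enrichment", "hotspots", "pairs"]


@dataclass
class RunConfig:
    """Inputs, resources, stage toggles and thresholds for one run.

    Threshold defaults are the published rule values: hypermutator cutoffs
    1000 (WES) / 60,000 (WGS), indel recurrence >= 3, recurrent variant > 10,
    FDR q < 0.05, >= 5 driver mutations per gene for CCF outliers, 2 SD
    outlier bound.
    """

    mutations: str = ""
    segments: str = ""
    samples: str = ""
    gene_roles: str | None = None
    pathways: str | None = None
    recurrence: str | None = None
    out_dir: str = "results/run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    wes_hypermutator: int = WES_HYPERMUTATOR_CUTOFF
    wgs_hypermutator: int = WGS_HYPERMUTATOR_CUTOFF
    alpha: float = DEFAULT_ALPHA
    ccf_fallback: float = DEFAULT_CCF_FALLBACK
    ccf_cap: float = DEFAULT_CCF_CAP
    fdr_q: float = 0.05
    min_drivers_per_gene: int = 5
    hotspot_min_patients: int = 3
    scna_amp_ploidy_mult: float = 2.0
    outlier_sd: float = 2.0
    wgii_baseline: str = "ploidy"
    indel_requires_recurrence: bool = True
    seed: int = 0

    def __post_init__(self):
        self.stages = {s: bool(self.stages.get(s, True)) for s in STAGES}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the report bundle.

    Returns the in-memory tables keyed by output name. A stage failure
    raises with the stage name; previously written outputs are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "row_counts": {},
        "skipped": [],
        "removed_hypermutators": [],
    }
    tables: dict[str, pd.DataFrame] = {}
    stage = "read"
    try:
        cohort = read_cohort(config.mutations, config.segments, config.samples)
        resource = load_gene_resource(config.gene_roles, config.pathways)
        recurrence = load_recurrence(config.recurrence)

        if config.stages["qc"]:
            stage = "qc"
            cohort, removed = filter_hypermutators(
                cohort, config.wes_hypermutator, config.wgs_hypermutator)
            manifest["removed_hypermutators"] = removed
            cohort = restrict_autosomes(cohort)
        else:
            manifest["skipped"].append("qc")

        timed = None
        if config.stages["timing"]:
            stage = "timing"
            timed = time_cohort(cohort, alpha=config.alpha,
                                ccf_fallback=config.ccf_fallback,
                                ccf_cap=config.ccf_cap)
            tables["timed_mutations"] = timed
            tables["timing_summary"] = timing_summary(timed, cohort.meta)
            tables["timing_summary_by_type"] = timing_summary(
                timed, cohort.meta, by_cancer_type=True)
        else:
            manifest["skipped"].append("timing")

        calls = None
        if config.stages["drivers"]:
            stage = "drivers"
            basis = timed if timed is not None else cohort.mutations
            mut_calls = call_drivers(
                basis, resource, recurrence,
                indel_requires_recurrence=config.indel_requires_recurrence)
            ploidy = cohort.segments.groupby("sample_id").apply(
                sample_ploidy, include_groups=False)
            scna_calls = call_driver_scna(
                cohort.segments, resource, ploidy,
                amp_ploidy_mult=config.scna_amp_ploidy_mult)
            calls = pd.concat([mut_calls, scna_calls], ignore_index=True)
            tables["driver_calls"] = calls
            tables["drivers_per_sample"] = drivers_per_sample(
                calls, cohort.mutations, cohort.meta)
            tables["pathways_per_sample"] = map_to_pathways(calls, resource)
        else:
            manifest["skipped"].append("drivers")

        if config.stages["metrics"]:
            stage = "metrics"
            tables["genome_metrics"] = genome_metrics(
                cohort.segments, baseline=config.wgii_baseline)
        else:
            manifest["skipped"].append("metrics")

        if config.stages["enrichment"] and calls is not None:
            stage = "enrichment"
            meta = cohort.meta
            tables["gene_enrichment"] = pd.concat([
                gene_enrichment(calls, meta, stratify="pan"),
                gene_enrichment(calls, meta, stratify="per_type"),
            ], ignore_index=True)
            pw_calls = calls.merge(resource.pathways, on="gene")
            tables["pathway_enrichment"] = pd.concat([
                gene_enrichment(pw_calls, meta, unit_col="pathway", stratify="pan"),
                gene_enrichment(pw_calls, meta, unit_col="pathway",
                                stratify="per_type"),
            ], ignore_index=True)

            if timed is not None:
                mut_calls = calls[calls["source"] == "mutation"].merge(
                    meta[["sample_id", "cohort", "cancer_type"]], on="sample_id")
                timing_tabs, conc = [], {}
                for unit_col, units in (("gene", mut_calls),
                                        ("pathway", mut_calls.merge(
                                            resource.pathways, on="gene"))):
                    per_cohort = {}
                    for cohort_name, grp in units.groupby("cohort"):
                        for strat, scol in (("pan", None),
                                            ("per_type", "cancer_type")):
                            res = timing_enrichment(grp, unit_col=unit_col,
                                                    stratum_col=scol)
                            res.insert(0, "cohort", cohort_name)
                            res.insert(1, "unit_type", unit_col)
                            timing_tabs.append(res)
                            per_cohort.setdefault(cohort_name, []).append(res)
                    try:
                        merged = {c: pd.concat(v, ignore_index=True)
                                  for c, v in per_cohort.items()}
                        r, p = or_concordance(merged.get("primary", pd.DataFrame()),
                                              merged.get("metastatic", pd.DataFrame()))
                        conc[unit_col] = {"pearson_r": r, "p": p}
                    except (MutclockError, KeyError):
                        conc[unit_col] = None
                tables["timing_enrichment"] = pd.concat(timing_tabs,
                                                        ignore_index=True)
                manifest["or_concordance"] = conc
                with open(out / "or_concordance.json", "w") as fh:
                    json.dump(conc, fh, indent=2)
                tables["ccf_outliers"] = gene_ccf_outliers(
                    mut_calls.dropna(subset=["ccf"]), meta,
                    min_drivers=config.min_drivers_per_gene,
                    sd_threshold=config.outlier_sd)
        elif config.stages["enrichment"]:
            manifest["skipped"].append("enrichment (needs drivers)")
        else:
            manifest["skipped"].append("enrichment")

        if config.stages["hotspots"]:
            stage = "hotspots"
            tables["hotspots"] = hotspot_scan(
                cohort.mutations, cohort.meta,
                min_patients=config.hotspot_min_patients)
        else:
            manifest["skipped"].append("hotspots")

        if config.stages["pairs"] and calls is not None:
            stage = "pairs"
            mut_calls = calls[calls["source"] == "mutation"]
            pairs = find_loh_pairs(mut_calls, cohort.segments, cohort.meta)
            tables["loh_pairs"] = pairs
            counts, partners = pair_summary(pairs)
            tables["loh_pair_counts"] = counts
            tables["loh_pair_partners"] = partners
        elif config.stages["pairs"]:
            manifest["skipped"].append("pairs (needs drivers)")
        else:
            manifest["skipped"].append("pairs")

        stage = "write"
        for name, df in tables.items():
            manifest["row_counts"][name] = _write(df, out / f"{name}.tsv")
    except MutclockError as exc:
        raise MutclockError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return tables


def summarize(out_dir) -> str:
    """Human-readable per-cohort summary of a completed run, re-derived from
    the stage TSVs: timing fractions, mean driver burden, mean wGII/LOH and
    genome-doubling rate."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = [f"mutclock run summary ({out})",
             f"config hash: {manifest['config_hash']}"]

    def table(name):
        path = out / f"{name}.tsv"
        return pd.read_csv(path, sep="\t") if path.exists() else None

    ts = table("timing_summary")
    meta = None
    dps, gm = table("drivers_per_sample"), table("genome_metrics")
    samples_path = Path(manifest["config"]["samples"])
    if samples_path.exists():
        meta = pd.read_csv(samples_path, sep="\t")
    if ts is None or ts.empty:
        lines.append("timing: no mutations summarised (zero rows)")
    else:
        for row in ts.itertuples():
            lines.append(
                f"{row.cohort}: {row.n_mutations} mutations — "
                f"{row.frac_early:.0%} early, {row.frac_late:.0%} late, "
                f"{row.frac_subclonal:.0%} subclonal, "
                f"{row.frac_untimed:.0%} untimed")
    if dps is not None and meta is not None and not dps.empty:
        merged = dps.merge(meta[["sample_id", "cohort"]], on="sample_id")
        for cohort_name, grp in merged.groupby("cohort"):
            lines.append(
                f"{cohort_name}: mean {grp['n_driver_mutations'].mean():.2f} "
                f"driver mutations/sample; "
                f"{grp['drivers_per_100_exonic_snv'].mean():.2f} per 100 exonic SNVs")
    if gm is not None and meta is not None and not gm.empty:
        merged = gm.merge(meta[["sample_id", "cohort"]], on="sample_id")
        for cohort_name, grp in merged.groupby("cohort"):
            lines.append(
                f"{cohort_name}: mean wGII {grp['wgii'].mean():.3f}, "
                f"mean LOH fraction {grp['loh_fraction'].mean():.3f}, "
                f"genome doubled {grp['genome_doubled'].mean():.0%}")
    if manifest.get("skipped"):
        lines.append("skipped stages: " + ", ".join(manifest["skipped"]))
    return "\n".join(lines)
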