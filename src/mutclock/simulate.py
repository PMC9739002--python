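"""Synthetic two-cohort tumour generator with full ground truth.

Emulates the structure of a primary (WES) versus metastatic (WGS) pan-cancer
comparison on a toy genome: per-sample purity, allele-specific copy-number
segments with gains, LOH and whole-genome doubling, and mutations placed
before or after gains with known multiplicity, CCF and clonality. Read
counts follow the forward model

    E[VAF] = purity * multiplicity * CCF / (purity * CN_t + 2 * (1 - purity))
    total_reads ~ Poisson(depth),  alt_reads ~ Binomial(total_reads, E[VAF])

which is the exact inverse of the CCF estimator, so noise-free output is
recovered to machine precision by the pipeline. Outputs are written in the
cohort I/O dialects; truth tables live in a separate truth/ directory and
are read only by tests, never by the pipeline.

Driver injections model recurrent cancer genes: per-cohort prevalence, an
optional timing bias, and an optional subclonality bias. Early-biased driver
mutations co-occur with a gain of their segment (the mutation-then-gain
sequence that relative timing detects) with probability ensure_gain_prob.
Hotspot injections add one exact variant with cohort-specific prevalence,
modelling e.g. treatment-resistance mutations private to metastases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources as _ires
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .drivers import GeneResource
from .errors import ConfigError
from .io import Cohort

DEFAULT_GENOME = {"1": 10_000_000, "2": 10_000_000,
                  "3": 10_000_000, "4": 10_000_000}

# census genes placed on the toy genome; roles mirror the bundled pathway table
_TOY_CENSUS = [
    ("TP53", "TSG"), ("MAP2K4", "TSG"), ("NCOR1", "TSG"), ("MDM2", "oncogene"),
    ("ATM", "TSG"), ("CHEK2", "TSG"), ("KRAS", "oncogene"), ("EGFR", "oncogene"),
    ("BRAF", "oncogene"), ("NF1", "TSG"), ("ERBB2", "oncogene"),
    ("PIK3CA", "oncogene"), ("PTEN", "TSG"), ("AKT1", "oncogene"),
    ("STK11", "TSG"), ("TSC2", "TSG"), ("APC", "TSG"), ("CTNNB1", "oncogene"),
    ("RB1", "TSG"), ("CDKN2A", "TSG"), ("CCND1", "oncogene"), ("MYC", "oncogene"),
    ("NFE2L2", "oncogene"), ("KEAP1", "TSG"), ("NOTCH1", "both"),
    ("FBXW7", "TSG"), ("NF2", "TSG"), ("FAT1", "TSG"), ("SMAD4", "TSG"),
    ("TGFBR2", "TSG"), ("CYLD", "TSG"), ("ESR1", "oncogene"),
]
_LOCUS_PATTERN = [250_000, 400_000, 150_000, 600_000, 300_000, 500_000,
                  200_000, 350_000]


@dataclass
class DriverInjection:
    """A recurrently mutated gene with per-cohort prevalence and biases."""

    gene: str
    prevalence_primary: float
    prevalence_metastatic: float
    timing_bias: str | None = None       # 'early' | 'late' | None
    clonality_bias: str | None = None    # 'subclonal' | None

    def prevalence(self, cohort: str) -> float:
        return self.prevalence_primary if cohort == "primary" \
            else self.prevalence_metastatic


@dataclass
class HotspotInjection:
    """One exact variant with cohort-specific prevalence, optionally
    restricted to some cancer types."""

    gene: str
    prevalence_primary: float
    prevalence_metastatic: float
    cancer_types: tuple[str, ...] | None = None

    def prevalence(self, cohort: str) -> float:
        return self.prevalence_primary if cohort == "primary" \
            else self.prevalence_metastatic


def default_driver_injections() -> list[DriverInjection]:
    return [
        DriverInjection("TP53", 0.45, 0.50, timing_bias="early"),
        DriverInjection("MDM2", 0.10, 0.12, timing_bias="early"),
        DriverInjection("KRAS", 0.25, 0.30, timing_bias="early"),
        DriverInjection("EGFR", 0.10, 0.15, timing_bias="early"),
        DriverInjection("CDKN2A", 0.15, 0.18, timing_bias="early"),
        DriverInjection("NOTCH1", 0.12, 0.12, timing_bias="late"),
        DriverInjection("FAT1", 0.10, 0.10, timing_bias="late"),
        DriverInjection("SMAD4", 0.08, 0.08, timing_bias="late"),
        DriverInjection("APC", 0.20, 0.20),
        DriverInjection("PTEN", 0.15, 0.12),
        DriverInjection("MAP2K4", 0.08, 0.12),
        DriverInjection("NCOR1", 0.08, 0.12),
        DriverInjection("CYLD", 0.05, 0.15, clonality_bias="subclonal"),
    ]


def default_hotspot_injections() -> list[HotspotInjection]:
    return [
        HotspotInjection("EGFR", 0.0, 0.25, cancer_types=("LUNG",)),
        HotspotInjection("ESR1", 0.0, 0.20, cancer_types=("BRCA",)),
        HotspotInjection("BRAF", 0.12, 0.01, cancer_types=("LUNG",)),
    ]


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort (defaults = the conditions
    exercised by the test suite: 2 cohorts x 2 cancer types x 50 samples,
    depth 100x)."""

    seed: int = 1
    cancer_types: tuple[str, ...] = ("BRCA", "LUNG")
    n_samples: int = 50                       # per (cohort, cancer type)
    genome: dict = field(default_factory=lambda: dict(DEFAULT_GENOME))
    purity_range: tuple[float, float] = (0.3, 0.9)
    gd_prob: dict = field(default_factory=lambda: {"primary": 0.2,
                                                   "metastatic": 0.4})
    gain_prob: float = 0.4
    loh_prob: float = 0.25
    n_mutations: int = 60                     # per sample, before injections
    frac_early: float = 0.3
    frac_subclonal: float = 0.2
    depth: float = 100.0
    noise_free: bool = False
    ensure_gain_prob: float = 0.9
    driver_injections: list = field(default_factory=default_driver_injections)
    hotspot_injections: list = field(default_factory=default_hotspot_injections)

    def __post_init__(self):
        for name in ("gain_prob", "loh_prob", "frac_early", "frac_subclonal",
                     "ensure_gain_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_early + self.frac_subclonal > 1:
            raise ConfigError("frac_early + frac_subclonal must be <= 1")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, typ in (("driver_injections", DriverInjection),
                         ("hotspot_injections", HotspotInjection)):
            if key in raw:
                raw[key] = [typ(**d) for d in raw[key]]
        for key in ("cancer_types", "purity_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def toy_gene_table(genome: dict | None = None) -> pd.DataFrame:
    """Deterministic gene loci tiling the toy genome.

    Census genes occupy fixed loci (TP53, MAP2K4 and NCOR1 adjacent on
    chromosome 1, mimicking a 17p-like tumour-suppressor cluster); the rest
    are filler genes with role 'other'.
    """
    genome = dict(genome or DEFAULT_GENOME)
    loci = []
    for chrom, length in genome.items():
        pos, i = 1, 0
        while pos <= length:
            size = _LOCUS_PATTERN[i % len(_LOCUS_PATTERN)]
            end = min(pos + size - 1, length)
            loci.append((chrom, pos, end))
            pos = end + 1
            i += 1
    census_slots = {3: 0, 4: 1, 5: 2}  # TP53/MAP2K4/NCOR1 adjacency
    next_slot, j = 8, 3
    while j < len(_TOY_CENSUS) and next_slot < len(loci):
        census_slots[next_slot] = j
        next_slot += 3
        j += 1
    if j < len(_TOY_CENSUS):
        raise ConfigError("toy genome too small to place the census gene set")
    rows, filler = [], 1
    for idx, (chrom, start, end) in enumerate(loci):
        if idx in census_slots:
            gene, role = _TOY_CENSUS[census_slots[idx]]
        else:
            gene, role = f"PSG{filler:03d}", "other"
            filler += 1
        rows.append({"gene": gene, "role": role, "chrom": chrom,
                     "start": start, "end": end,
                     "length_bp": end - start + 1})
    return pd.DataFrame(rows)


def toy_resource(genome: dict | None = None) -> GeneResource:
    pathways = pd.read_csv(_ires.files("mutclock.resources") / "pathways.tsv",
                           sep="\t")
    return GeneResource(roles=toy_gene_table(genome), pathways=pathways)


def _hotspot_pos(locus, which: int) -> int:
    """Deterministic in-gene positions for canonical (0) and injected (1)
    hotspot variants."""
    span = locus["end"] - locus["start"]
    return int(locus["start"] + span // 2) if which == 0 \
        else int(locus["start"] + span // 3)


def toy_recurrence(resource: GeneResource,
                   hotspots: list[HotspotInjection]) -> pd.DataFrame:
    """Recurrence counts for the toy gene set: every oncogene gets one
    canonical hotspot (count 20), every injected hotspot variant count 25."""
    loci = resource.roles.set_index("gene")
    rows = []
    for gene, locus in loci.iterrows():
        if locus["role"] in ("oncogene", "both"):
            rows.append({"chrom": locus["chrom"], "pos": _hotspot_pos(locus, 0),
                         "ref": "C", "alt": "T", "gene": gene,
                         "protein_change": f"{gene}_canonical", "count": 20})
    for h in hotspots:
        locus = loci.loc[h.gene]
        rows.append({"chrom": locus["chrom"], "pos": _hotspot_pos(locus, 1),
                     "ref": "G", "alt": "A", "gene": h.gene,
                     "protein_change": f"{h.gene}_injected", "count": 25})
    df = pd.DataFrame(rows).drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def expected_vaf(purity, multiplicity, ccf_true, total_cn) -> float:
    """Forward VAF model; exact inverse of the CCF estimator."""
    return (purity * multiplicity * ccf_true) / \
        (purity * total_cn + 2.0 * (1.0 - purity))


def simulate_segments(config: SimConfig, rng: np.random.Generator,
                      sample_id: str, cohort: str) -> tuple[list[dict], bool]:
    """Allele-specific segmentation of the toy genome for one sample:
    optional whole-genome doubling, then per-segment gains (+1 major) and
    single-copy losses creating LOH (minor -> 0). Fully tiles the genome."""
    gd = bool(rng.random() < config.gd_prob[cohort])
    base = (2, 2) if gd else (1, 1)
    segments = []
    for chrom, length in config.genome.items():
        n_seg = int(rng.integers(3, 7))
        cuts = set()
        while len(cuts) < n_seg - 1:  # distinct breakpoints in [2, length]
            cuts.add(int(rng.integers(2, length + 1)))
        cuts = np.sort(np.fromiter(cuts, dtype=np.int64))
        bounds = np.concatenate([[1], cuts, [length + 1]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            major, minor = base
            if rng.random() < config.gain_prob:
                major += 1
            if rng.random() < config.loh_prob:
                minor = 0
            segments.append({"sample_id": sample_id, "chrom": chrom,
                             "start": int(lo), "end": int(hi - 1),
                             "major_cn": major, "minor_cn": minor})
    return segments, gd


class _GeneIndex:
    """Fast locus lookups over the gene table (built once per cohort)."""

    def __init__(self, roles: pd.DataFrame):
        self._by_gene = {r["gene"]: r for r in roles.to_dict("records")}
        self._by_chrom = {}
        for chrom, grp in roles.sort_values("start").groupby("chrom"):
            self._by_chrom[chrom] = (grp["start"].to_numpy(),
                                     grp["end"].to_numpy(),
                                     grp["gene"].to_numpy())

    def locus(self, gene: str) -> dict:
        return self._by_gene[gene]

    def gene_at(self, chrom: str, pos: int) -> str:
        starts, ends, genes = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        assert i >= 0 and pos <= ends[i], "toy genome loci tile every chromosome"
        return str(genes[i])


_PASSENGER_CONSEQUENCES = np.array(
    ["nonsyn_snv", "synonymous", "stopgain", "frameshift_indel",
     "nonframeshift_indel", "splice", "other"])
_PASSENGER_WEIGHTS = np.array([0.70, 0.24, 0.02, 0.01, 0.01, 0.01, 0.01])
_BASES = np.array(["A", "C", "G", "T"])


class _SampleSim:
    """Generation state for one sample; mutable because early-biased drivers
    may add a gain to their segment."""

    def __init__(self, config, rng, resource, recurrence, sample_id, cohort,
                 cancer_type, purity, gene_index=None):
        self.config, self.rng = config, rng
        self.resource, self.recurrence = resource, recurrence
        self.sample_id, self.cohort = sample_id, cohort
        self.cancer_type, self.purity = cancer_type, purity
        self.segments, self.gd = simulate_segments(config, rng, sample_id, cohort)
        self._index = gene_index if gene_index is not None \
            else _GeneIndex(resource.roles)
        self.mutations: list[dict] = []
        self.truth: list[dict] = []

    def _segment_at(self, chrom: str, pos: int) -> dict:
        for seg in self.segments:
            if seg["chrom"] == chrom and seg["start"] <= pos <= seg["end"]:
                return seg
        raise AssertionError("toy genome is fully tiled")  # pragma: no cover

    def _gene_at(self, chrom: str, pos: int) -> str:
        return self._index.gene_at(chrom, pos)

    def _locus(self, gene: str):
        return self._index.locus(gene)

    def _emit(self, *, chrom, pos, ref, alt, gene, consequence, sift, polyphen,
              mult, ccf_true, seg, is_driver):
        total_cn = seg["major_cn"] + seg["minor_cn"]
        vaf = expected_vaf(self.purity, mult, ccf_true, total_cn)
        rec = {"sample_id": self.sample_id, "chrom": chrom, "pos": int(pos),
               "ref": ref, "alt": alt, "gene": gene, "consequence": consequence,
               "sift": sift, "polyphen": polyphen}
        if self.config.noise_free:
            rec.update(alt_reads="", total_reads="", vaf=f"{vaf:.12g}")
        else:
            total = max(int(self.rng.poisson(self.config.depth)), 1)
            altr = int(self.rng.binomial(total, vaf))
            rec.update(alt_reads=altr, total_reads=total, vaf="")
        self.mutations.append(rec)
        timeable = seg["major_cn"] >= 2 and ccf_true >= 1.0
        self.truth.append({
            "mutation_id": f"{self.sample_id}:{chrom}:{int(pos)}:{alt}",
            "sample_id": self.sample_id,
            "true_ccf": ccf_true, "true_multiplicity": mult,
            "true_timing": ("early" if mult >= 2 else "late"),
            "timeable": bool(timeable),
            "true_clonality": "clonal" if ccf_true >= 1.0 else "subclonal",
            "is_driver": bool(is_driver),
        })

    def _timing_state(self, seg: dict, bias: str | None,
                      clonality_bias: str | None):
        """Choose (multiplicity, true ccf), possibly forcing a gain for
        early-biased events. Returns after any segment mutation."""
        rng, cfg = self.rng, self.config
        if clonality_bias == "subclonal":
            return 1, float(rng.uniform(0.1, 0.6))
        if bias == "early":
            if seg["major_cn"] < 2 and rng.random() < cfg.ensure_gain_prob:
                seg["major_cn"] += 1
            if seg["major_cn"] >= 2:
                return int(seg["major_cn"]), 1.0
            return 1, 1.0
        if bias == "late":
            return 1, 1.0
        u = rng.random()
        if u < cfg.frac_subclonal:
            return 1, float(rng.uniform(0.1, 0.6))
        if u < cfg.frac_subclonal + cfg.frac_early and seg["major_cn"] >= 2:
            return int(seg["major_cn"]), 1.0
        return 1, 1.0

    def inject_drivers(self):
        role = self.resource.role_of()
        for inj in self.config.driver_injections:
            if self.rng.random() >= inj.prevalence(self.cohort):
                continue
            locus = self._locus(inj.gene)
            if role.get(inj.gene) in ("oncogene", "both"):
                pos, ref, alt = _hotspot_pos(locus, 0), "C", "T"
                sift, cons = "tolerated", "nonsyn_snv"
            else:
                pos = int(self.rng.integers(locus["start"], locus["end"] + 1))
                ref, alt = (str(b) for b in self.rng.choice(_BASES, 2, replace=False))
                sift, cons = "deleterious", "nonsyn_snv"
            seg = self._segment_at(locus["chrom"], pos)
            mult, ccf_true = self._timing_state(seg, inj.timing_bias,
                                                inj.clonality_bias)
            self._emit(chrom=locus["chrom"], pos=pos, ref=ref, alt=alt,
                       gene=inj.gene, consequence=cons, sift=sift,
                       polyphen="benign", mult=mult, ccf_true=ccf_true,
                       seg=seg, is_driver=True)

    def inject_hotspots(self):
        for h in self.config.hotspot_injections:
            if h.cancer_types and self.cancer_type not in h.cancer_types:
                continue
            if self.rng.random() >= h.prevalence(self.cohort):
                continue
            locus = self._locus(h.gene)
            pos = _hotspot_pos(locus, 1)
            seg = self._segment_at(locus["chrom"], pos)
            self._emit(chrom=locus["chrom"], pos=pos, ref="G", alt="A",
                       gene=h.gene, consequence="nonsyn_snv", sift="tolerated",
                       polyphen="benign", mult=1, ccf_true=1.0, seg=seg,
                       is_driver=True)

    def passengers(self):
        rng, cfg = self.rng, self.config
        chroms = list(cfg.genome)
        lengths = np.array([cfg.genome[c] for c in chroms], float)
        n = cfg.n_mutations - len(self.mutations)
        for _ in range(max(n, 0)):
            u = rng.random()
            want_subclonal = u < cfg.frac_subclonal
            want_early = not want_subclonal and \
                u < cfg.frac_subclonal + cfg.frac_early
            if want_early:
                gained = [s for s in self.segments if s["major_cn"] >= 2]
                if gained:
                    w = np.array([s["end"] - s["start"] + 1 for s in gained], float)
                    seg = gained[rng.choice(len(gained), p=w / w.sum())]
                else:
                    want_early = False
            if not want_early:
                ci = rng.choice(len(chroms), p=lengths / lengths.sum())
                pos = int(rng.integers(1, lengths[ci] + 1))
                seg = self._segment_at(chroms[ci], pos)
            else:
                pos = int(rng.integers(seg["start"], seg["end"] + 1))
            if want_subclonal:
                mult, ccf_true = 1, float(rng.uniform(0.1, 0.6))
            elif want_early:
                mult, ccf_true = int(seg["major_cn"]), 1.0
            else:
                mult, ccf_true = 1, 1.0
            cons = str(rng.choice(_PASSENGER_CONSEQUENCES, p=_PASSENGER_WEIGHTS))
            ref, alt = (str(b) for b in rng.choice(_BASES, 2, replace=False))
            self._emit(chrom=seg["chrom"], pos=pos, ref=ref, alt=alt,
                       gene=self._gene_at(seg["chrom"], pos), consequence=cons,
                       sift="tolerated", polyphen="benign", mult=mult,
                       ccf_true=ccf_true, seg=seg, is_driver=False)

    def run(self):
        self.inject_drivers()
        self.inject_hotspots()
        self.passengers()


@dataclass
class SimResult:
    cohort: Cohort
    truth_mutations: pd.DataFrame
    truth_samples: pd.DataFrame
    resource: GeneResource
    recurrence: pd.DataFrame


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate the full two-cohort dataset with ground truth. Deterministic
    for a fixed config (one seeded generator, fixed sample order)."""
    rng = np.random.default_rng(config.seed)
    resource = toy_resource(config.genome)
    recurrence = toy_recurrence(resource, config.hotspot_injections)
    gene_index = _GeneIndex(resource.roles)

    meta_rows, mut_rows, seg_rows = [], [], []
    truth_mut, truth_samp = [], []
    for cohort in ("primary", "metastatic"):
        prefix = "P" if cohort == "primary" else "M"
        platform = "WES" if cohort == "primary" else "WGS"
        for ct in config.cancer_types:
            for i in range(config.n_samples):
                sample_id = f"{prefix}_{ct}_{i:03d}"
                purity = float(rng.uniform(*config.purity_range))
                sim = _SampleSim(config, rng, resource, recurrence,
                                 sample_id, cohort, ct, purity,
                                 gene_index=gene_index)
                sim.run()
                meta_rows.append({"sample_id": sample_id, "cohort": cohort,
                                  "cancer_type": ct, "platform": platform,
                                  "purity": purity})
                seg_rows.extend(sim.segments)
                mut_rows.extend(sim.mutations)
                truth_mut.extend(sim.truth)
                seg_df = pd.DataFrame(sim.segments)
                w = seg_df["end"] - seg_df["start"] + 1
                truth_samp.append({
                    "sample_id": sample_id, "true_gd": sim.gd,
                    "true_ploidy": float(np.average(
                        seg_df["major_cn"] + seg_df["minor_cn"], weights=w)),
                    "purity": purity,
                })

    mutations = pd.DataFrame(mut_rows, columns=[
        "sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
        "alt_reads", "total_reads", "vaf", "sift", "polyphen"])
    dup = mutations.duplicated(subset=["sample_id", "chrom", "pos", "alt"])
    truth_mutations = pd.DataFrame(truth_mut)[~dup.to_numpy()] if len(mut_rows) \
        else pd.DataFrame(truth_mut)
    mutations = mutations[~dup].reset_index(drop=True)
    truth_mutations = truth_mutations.reset_index(drop=True)

    segments = pd.DataFrame(seg_rows, columns=[
        "sample_id", "chrom", "start", "end", "major_cn", "minor_cn"])
    meta = pd.DataFrame(meta_rows, columns=META_ORDER)
    cohort = Cohort(mutations=_typed_mutations(mutations), segments=segments,
                    meta=meta)
    return SimResult(cohort, truth_mutations, pd.DataFrame(truth_samp),
                     resource, recurrence)


META_ORDER = ["sample_id", "cohort", "cancer_type", "platform", "purity"]


def _typed_mutations(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["vaf"] = pd.to_numeric(out["vaf"].mask(out["vaf"] == "", np.nan))
    for col in ("alt_reads", "total_reads"):
        out[col] = pd.to_numeric(out[col].mask(out[col] == "", np.nan)).astype("Int64")
    has_reads = out["alt_reads"].notna()
    out.loc[has_reads, "vaf"] = (out.loc[has_reads, "alt_reads"]
                                 / out.loc[has_reads, "total_reads"])
    return out


def write_simulation(config: SimConfig, outdir, overwrite: bool = False) -> SimResult:
    """Write the file bundle: cohort tables + resources at top level, truth
    tables under truth/ (read only by tests). Byte-identical under a fixed
    config."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise ConfigError(f"output directory {outdir} is not empty "
                          "(pass overwrite=True)")
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    res = simulate_cohort(config)

    fmt = dict(sep="\t", index=False, float_format="%.10g")
    mut = res.cohort.mutations.copy()
    has_reads = mut["alt_reads"].notna()
    mut["vaf"] = mut["vaf"].map(lambda v: f"{v:.12g}" if pd.notna(v) else "")
    mut.loc[has_reads, "vaf"] = ""  # reads are authoritative when present
    mut.to_csv(outdir / "mutations.tsv", **fmt, na_rep="")
    res.cohort.segments.to_csv(outdir / "segments.tsv", **fmt)
    res.cohort.meta.to_csv(outdir / "samples.tsv", **fmt)
    res.resource.roles.to_csv(outdir / "gene_roles.tsv", **fmt)
    res.resource.pathways.to_csv(outdir / "pathways.tsv", **fmt)
    res.recurrence.to_csv(outdir / "recurrence.tsv", **fmt)
    res.truth_mutations.to_csv(outdir / "truth" / "truth_mutations.tsv", **fmt)
    res.truth_samples.to_csv(outdir / "truth" / "truth_samples.tsv", **fmt)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return res
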