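"""Rule-based driver annotation for mutations and somatic copy-number
alterations (SCNAs), plus pathway mapping and per-sample driver burden.

Genes listed in the census resource with a cancer role (TSG / oncogene /
both) are evaluated against the census rule set, in fixed order:

1. fs_indel_tsg        — frameshift indel in a TSG, recurrence >= 3
2. nonfs_indel_oncogene — non-frameshift indel in an oncogene, recurrence >= 3
3. deleterious_tsg     — TSG variant predicted deleterious (SIFT), probably
                         damaging (PolyPhen), or a stop-gain / splice variant
4. recurrent_variant   — exact variant seen > 10 times in the recurrence table

Genes outside the census (absent, or role 'other') use the wide rule: SIFT
deleterious, PolyPhen probably damaging, stop-gain or frameshift indel, or
recurrence > 10. PolyPhen 'possibly_damaging' never fires a rule.

SCNA drivers: homozygous deletion (total CN 0) of a TSG; amplification
(total CN >= amp_ploidy_mult x sample ploidy) of an oncogene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources as _ires

import numpy as np
import pandas as pd

from .errors import CohortFormatError

TSG_ROLES = {"TSG", "both"}
ONCOGENE_ROLES = {"oncogene", "both"}
CENSUS_ROLES = {"TSG", "oncogene", "both"}

INDEL_RECURRENCE_MIN = 3       # inclusive: ">= 3 times"
RECURRENT_VARIANT_MIN = 10     # exclusive: "more than 10 times"

RULE_ORDER = ["fs_indel_tsg", "nonfs_indel_oncogene", "deleterious_tsg",
              "recurrent_variant"]


@dataclass
class GeneResource:
    """Gene roles/loci and pathway membership tables.

    roles: gene, role, chrom, start, end, length_bp
    pathways: pathway, gene
    """

    roles: pd.DataFrame
    pathways: pd.DataFrame

    def census_genes(self) -> set[str]:
        return set(self.roles.loc[self.roles["role"].isin(CENSUS_ROLES), "gene"])

    def role_of(self) -> pd.Series:
        return self.roles.set_index("gene")["role"]


def load_gene_resource(roles_path=None, pathways_path=None) -> GeneResource:
    """Load gene roles and pathway membership; defaults to the bundled
    compact hg19 census subset and the ten canonical oncogenic signalling
    pathways (cell cycle, Hippo, Myc, Notch, NRF2, PI3K, RTK/RAS, TGF-beta,
    p53, Wnt)."""
    if roles_path is None:
        roles_path = _ires.files("mutclock.resources") / "gene_roles_hg19.tsv"
    if pathways_path is None:
        pathways_path = _ires.files("mutclock.resources") / "pathways.tsv"
    roles = pd.read_csv(roles_path, sep="\t", dtype={"chrom": str})
    for col in ("gene", "role", "chrom", "start", "end", "length_bp"):
        if col not in roles.columns:
            raise CohortFormatError(f"gene roles table: missing column {col}")
    pathways = pd.read_csv(pathways_path, sep="\t")
    for col in ("pathway", "gene"):
        if col not in pathways.columns:
            raise CohortFormatError(f"pathway table: missing column {col}")
    return GeneResource(roles=roles, pathways=pathways)


def load_recurrence(path=None) -> pd.DataFrame:
    """Variant recurrence counts (COSMIC-style export). The bundled default
    is a small synthetic stand-in with plausible hotspot counts for the demo
    gene set; supply a real export for production use.

    Keyed on exact (chrom, pos, ref, alt); (gene, protein_change) is a
    documented fallback key.
    """
    if path is None:
        path = _ires.files("mutclock.resources") / "recurrence_synthetic.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "ref", "alt", "gene", "count"):
        if col not in df.columns:
            raise CohortFormatError(f"recurrence table: missing column {col}")
    if (df["count"] < 0).any():
        raise CohortFormatError("recurrence counts must be >= 0")
    return df


def _recurrence_counts(mutations: pd.DataFrame, recurrence: pd.DataFrame) -> np.ndarray:
    key = recurrence.set_index(["chrom", "pos", "ref", "alt"])["count"]
    key = key[~key.index.duplicated(keep="first")]
    idx = pd.MultiIndex.from_frame(mutations[["chrom", "pos", "ref", "alt"]])
    return key.reindex(idx).fillna(0).to_numpy(float)


def call_drivers(
    mutations: pd.DataFrame,
    resource: GeneResource,
    recurrence: pd.DataFrame,
    indel_requires_recurrence: bool = True,
) -> pd.DataFrame:
    """Evaluate the full rule set over a mutation table.

    Returns one row per driver mutation with the first matching rule in the
    fixed order. Deterministic: the result is a pure function of the rows,
    independent of input ordering. Columns of the input are preserved and a
    `rule` column added.
    """
    df = mutations.reset_index(drop=True)
    role = df["gene"].map(resource.role_of()).fillna("other")
    is_census = role.isin(CENSUS_ROLES).to_numpy()
    is_tsg = role.isin(TSG_ROLES).to_numpy()
    is_onc = role.isin(ONCOGENE_ROLES).to_numpy()
    rec = _recurrence_counts(df, recurrence)

    cons = df["consequence"].to_numpy(object)
    sift_del = (df["sift"] == "deleterious").to_numpy()
    pp_dam = (df["polyphen"] == "probably_damaging").to_numpy()
    fs = cons == "frameshift_indel"
    nonfs = cons == "nonframeshift_indel"
    stop_or_splice = (cons == "stopgain") | (cons == "splice")

    indel_rec_ok = rec >= INDEL_RECURRENCE_MIN if indel_requires_recurrence \
        else np.ones(len(df), bool)

    rules = {
        "fs_indel_tsg": is_census & is_tsg & fs & indel_rec_ok,
        "nonfs_indel_oncogene": is_census & is_onc & nonfs & indel_rec_ok,
        "deleterious_tsg": is_census & is_tsg & (sift_del | pp_dam | stop_or_splice),
        "recurrent_variant": is_census & (rec > RECURRENT_VARIANT_MIN),
    }
    noncensus = ~is_census & (sift_del | pp_dam | (cons == "stopgain") | fs
                              | (rec > RECURRENT_VARIANT_MIN))

    rule = np.full(len(df), "", dtype=object)
    for name in reversed(RULE_ORDER):  # earlier rules overwrite later ones
        rule[rules[name]] = name
    rule[noncensus] = "noncensus_pathogenic"

    out = df[rule != ""].copy()
    out["rule"] = rule[rule != ""]
    out["source"] = "mutation"
    return out.reset_index(drop=True)


def call_driver_mutation(mut: pd.Series, resource: GeneResource,
                         recurrence: pd.DataFrame, **kw):
    """Single-record census-path convenience wrapper; returns the rule name
    or None."""
    calls = call_drivers(pd.DataFrame([mut]), resource, recurrence, **kw)
    return None if calls.empty else calls.iloc[0]["rule"]


def call_driver_scna(
    segments: pd.DataFrame,
    resource: GeneResource,
    ploidy_by_sample: pd.Series,
    amp_ploidy_mult: float = 2.0,
) -> pd.DataFrame:
    """SCNA driver calls: TSG homozygous deletions (total CN 0) and oncogene
    amplifications (total CN >= amp_ploidy_mult x sample ploidy). A gene
    qualifies through any overlapping segment, once per sample and rule.
    Census genes without locus information are skipped with a warning.
    """
    loci = resource.roles[resource.roles["role"].isin(CENSUS_ROLES)]
    missing = loci["start"].isna() | loci["end"].isna() | loci["chrom"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} census gene(s) lack locus "
                      "coordinates and are skipped for SCNA calling")
        loci = loci[~missing]
    merged = segments.merge(loci, on="chrom", suffixes=("", "_gene"))
    overlap = (merged["start_gene"] <= merged["end"]) & \
              (merged["end_gene"] >= merged["start"])
    merged = merged[overlap]
    total = merged["major_cn"] + merged["minor_cn"]
    ploidy = merged["sample_id"].map(ploidy_by_sample)

    dele = merged[(total == 0) & merged["role"].isin(TSG_ROLES)].copy()
    dele["rule"] = "scna_del_tsg"
    amp = merged[(total >= amp_ploidy_mult * ploidy)
                 & merged["role"].isin(ONCOGENE_ROLES)].copy()
    amp["rule"] = "scna_amp_oncogene"
    out = pd.concat([dele, amp], ignore_index=True)
    out = out.drop_duplicates(subset=["sample_id", "gene", "rule"])
    out["source"] = "scna"
    cols = ["sample_id", "gene", "rule", "source", "chrom", "start", "end",
            "major_cn", "minor_cn"]
    return out[cols].sort_values(["sample_id", "gene", "rule"]).reset_index(drop=True)


def exonic_snv_counts(mutations: pd.DataFrame) -> pd.Series:
    """Exonic SNVs per sample: single-nucleotide ref/alt with an exonic
    consequence (non-synonymous, synonymous or stop-gain)."""
    snv = (mutations["ref"].str.len() == 1) & (mutations["alt"].str.len() == 1)
    exonic = mutations["consequence"].isin({"nonsyn_snv", "synonymous", "stopgain"})
    return mutations[snv & exonic].groupby("sample_id").size()


def drivers_per_sample(
    calls: pd.DataFrame,
    mutations: pd.DataFrame,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample driver burden: raw counts by source and driver mutations
    per 100 exonic SNVs (missing when a sample has no exonic SNVs)."""
    idx = meta["sample_id"]
    mut_calls = calls[calls["source"] == "mutation"] if len(calls) else calls
    scna_calls = calls[calls["source"] == "scna"] if len(calls) else calls
    n_mut = mut_calls.groupby("sample_id").size().reindex(idx, fill_value=0)
    n_scna = scna_calls.groupby("sample_id").size().reindex(idx, fill_value=0)
    snvs = exonic_snv_counts(mutations).reindex(idx, fill_value=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per100 = np.where(snvs > 0,
                          100.0 * n_mut.to_numpy() / snvs.to_numpy(), np.nan)
    return pd.DataFrame({
        "sample_id": idx.to_numpy(),
        "n_driver_mutations": n_mut.to_numpy(),
        "n_driver_scna": n_scna.to_numpy(),
        "exonic_snvs": snvs.to_numpy(),
        "drivers_per_100_exonic_snv": per100,
    })


def map_to_pathways(calls: pd.DataFrame, resource: GeneResource) -> pd.DataFrame:
    """Per-sample altered pathways: a pathway is altered iff >= 1 driver call
    hits a member gene; multi-pathway genes contribute to each. Returns
    (sample_id, pathway) rows; genes with no pathway contribute nothing."""
    if calls.empty:
        return pd.DataFrame(columns=["sample_id", "pathway"])
    hits = calls.merge(resource.pathways, on="gene")
    return (hits[["sample_id", "pathway"]]
            .drop_duplicates()
            .sort_values(["sample_id", "pathway"])
            .reset_index(drop=True))
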