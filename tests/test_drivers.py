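"""Driver rule engine: census and wide (non-census) paths, SCNA rules,
per-sample burden and pathway mapping."""

import numpy as np
import pandas as pd
import pytest

from mutclock.drivers import (GeneResource, call_driver_scna, call_drivers,
                              drivers_per_sample, exonic_snv_counts,
                              load_gene_resource, load_recurrence,
                              map_to_pathways)

from conftest import make_meta, make_mutations, make_segments

ROLES = pd.DataFrame([
    dict(gene="TP53", role="TSG", chrom="17", start=100, end=200, length_bp=101),
    dict(gene="KRAS", role="oncogene", chrom="12", start=300, end=400, length_bp=101),
    dict(gene="NOTCH1", role="both", chrom="9", start=500, end=600, length_bp=101),
    dict(gene="PSGX", role="other", chrom="1", start=700, end=800, length_bp=101),
])
PATHWAYS = pd.DataFrame([
    dict(pathway="p53", gene="TP53"),
    dict(pathway="RTK/RAS", gene="KRAS"),
    dict(pathway="Cell cycle", gene="CDKN2A"),
])
RESOURCE = GeneResource(roles=ROLES, pathways=PATHWAYS)


def recurrence(rows):
    base = dict(chrom="17", pos=1, ref="A", alt="T", gene="TP53",
                protein_change="", count=0)
    return pd.DataFrame([{**base, **r} for r in rows] or [base])


def mut(**kw):
    defaults = dict(sample_id="S1", chrom="17", pos=150, gene="TP53")
    return {**defaults, **kw}


def rules_of(mutations, rec=None, **kw):
    calls = call_drivers(make_mutations(mutations), RESOURCE,
                         rec if rec is not None else recurrence([]), **kw)
    return list(calls["rule"])


class TestCensusRules:
    def test_frameshift_tsg_needs_recurrence_three(self):
        rec3 = recurrence([dict(chrom="17", pos=150, ref="A", alt="T", count=3)])
        m = [mut(consequence="frameshift_indel")]
        assert rules_of(m, rec3) == ["fs_indel_tsg"]
        rec2 = recurrence([dict(chrom="17", pos=150, ref="A", alt="T", count=2)])
        assert rules_of(m, rec2) == []
        assert rules_of(m, rec2, indel_requires_recurrence=False) \
            == ["fs_indel_tsg"]

    def test_nonframeshift_oncogene_indel(self):
        rec = recurrence([dict(chrom="12", pos=350, ref="A", alt="T",
                               gene="KRAS", count=5)])
        m = [mut(chrom="12", pos=350, gene="KRAS",
                 consequence="nonframeshift_indel")]
        assert rules_of(m, rec) == ["nonfs_indel_oncogene"]
        # frameshift in an oncogene fires nothing
        m2 = [mut(chrom="12", pos=350, gene="KRAS",
                  consequence="frameshift_indel")]
        assert rules_of(m2, rec) == []

    @pytest.mark.parametrize("fields", [
        dict(sift="deleterious"),
        dict(polyphen="probably_damaging"),
        dict(consequence="stopgain"),
        dict(consequence="splice"),
    ])
    def test_deleterious_tsg_variants(self, fields):
        assert rules_of([mut(**fields)]) == ["deleterious_tsg"]

    def test_possibly_damaging_does_not_fire(self):
        assert rules_of([mut(polyphen="possibly_damaging")]) == []

    def test_deleterious_oncogene_snv_is_not_a_driver(self):
        assert rules_of([mut(chrom="12", pos=350, gene="KRAS",
                             sift="deleterious")]) == []

    def test_recurrent_variant_strictly_above_ten(self):
        for count, expect in ((11, ["recurrent_variant"]), (10, [])):
            rec = recurrence([dict(chrom="12", pos=350, ref="A", alt="T",
                                   gene="KRAS", count=count)])
            m = [mut(chrom="12", pos=350, gene="KRAS")]
            assert rules_of(m, rec) == expect

    def test_rule_order_first_match_recorded_once(self):
        rec = recurrence([dict(chrom="17", pos=150, ref="A", alt="T", count=50)])
        m = [mut(sift="deleterious")]  # deleterious_tsg and recurrent both fire
        calls = call_drivers(make_mutations(m), RESOURCE, rec)
        assert len(calls) == 1 and calls.iloc[0]["rule"] == "deleterious_tsg"


class TestNonCensusRules:
    @pytest.mark.parametrize("fields, expect", [
        (dict(consequence="stopgain"), True),
        (dict(polyphen="probably_damaging"), True),
        (dict(sift="deleterious"), True),
        (dict(consequence="frameshift_indel"), True),
        (dict(), False),
        (dict(polyphen="possibly_damaging"), False),
    ])
    def test_wide_rule(self, fields, expect):
        m = [mut(chrom="1", pos=750, gene="PSGX", **fields)]
        got = rules_of(m)
        assert got == (["noncensus_pathogenic"] if expect else [])

    def test_paths_are_mutually_exclusive(self):
        m = make_mutations([mut(sift="deleterious"),
                            mut(chrom="1", pos=750, gene="PSGX",
                                sift="deleterious")])
        calls = call_drivers(m, RESOURCE, recurrence([]))
        assert set(calls["rule"]) == {"deleterious_tsg", "noncensus_pathogenic"}

    def test_unlisted_gene_takes_wide_path(self):
        m = [mut(chrom="2", pos=50, gene="NOVEL1", consequence="stopgain")]
        assert rules_of(m) == ["noncensus_pathogenic"]


class TestOrderStability:
    def test_shuffling_input_never_changes_the_call_set(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(60):
            rows.append(mut(
                sample_id=f"S{i % 7}", pos=100 + i % 90,
                gene=str(rng.choice(["TP53", "KRAS", "PSGX", "NOVEL"])),
                consequence=str(rng.choice(
                    ["nonsyn_snv", "stopgain", "frameshift_indel", "synonymous"])),
                sift=str(rng.choice(["deleterious", "tolerated"])),
            ))
        df = make_mutations(rows)
        rec = recurrence([dict(chrom="17", pos=120, ref="A", alt="T", count=15)])
        key = ["sample_id", "chrom", "pos", "alt", "gene", "rule"]
        baseline = call_drivers(df, RESOURCE, rec)[key] \
            .sort_values(key).reset_index(drop=True)
        for seed in range(3):
            shuffled = df.sample(frac=1, random_state=seed)
            calls = call_drivers(shuffled, RESOURCE, rec)[key] \
                .sort_values(key).reset_index(drop=True)
            pd.testing.assert_frame_equal(calls, baseline)

    def test_calls_reverify_against_raw_records(self, pipeline_run):
        """Each emitted rule's preconditions hold on the underlying record."""
        calls = pipeline_run["tables"]["driver_calls"]
        roles = pd.read_csv(pipeline_run["bundle"] / "gene_roles.tsv", sep="\t")
        role = roles.set_index("gene")["role"]
        mut_calls = calls[calls["source"] == "mutation"]
        r = mut_calls["gene"].map(role).fillna("other")
        assert (r[mut_calls["rule"] == "fs_indel_tsg"].isin(["TSG", "both"])).all()
        assert (mut_calls.loc[mut_calls["rule"] == "fs_indel_tsg",
                              "consequence"] == "frameshift_indel").all()
        dele = mut_calls[mut_calls["rule"] == "deleterious_tsg"]
        assert r[dele.index].isin(["TSG", "both"]).all()
        ok = (dele["sift"] == "deleterious") | \
             (dele["polyphen"] == "probably_damaging") | \
             (dele["consequence"].isin(["stopgain", "splice"]))
        assert ok.all()
        noncensus = mut_calls[mut_calls["rule"] == "noncensus_pathogenic"]
        assert (~r[noncensus.index].isin(["TSG", "oncogene", "both"])).all()


class TestScnaDrivers:
    SEGS = make_segments([
        dict(sample_id="S1", chrom="17", start=1, end=1000, major_cn=0, minor_cn=0),
        dict(sample_id="S1", chrom="12", start=1, end=1000, major_cn=6, minor_cn=2),
        dict(sample_id="S2", chrom="17", start=1, end=1000, major_cn=1, minor_cn=0),
    ])

    def test_deletion_and_amplification_rules(self):
        ploidy = pd.Series({"S1": 2.0, "S2": 2.0})
        calls = call_driver_scna(self.SEGS, RESOURCE, ploidy)
        got = set(zip(calls["sample_id"], calls["gene"], calls["rule"]))
        assert ("S1", "TP53", "scna_del_tsg") in got
        assert ("S1", "KRAS", "scna_amp_oncogene") in got  # 8 >= 2*2*2
        # single-copy loss is not an SCNA driver (handled by LOH analysis)
        assert not any(s == "S2" for s, _, _ in got)

    def test_amplification_threshold_scales_with_ploidy(self):
        calls = call_driver_scna(self.SEGS, RESOURCE,
                                 pd.Series({"S1": 4.5, "S2": 2.0}))
        assert "scna_amp_oncogene" not in set(calls["rule"])  # 8 < 2*4.5


class TestBurdenAndPathways:
    def test_per_sample_normalisation(self):
        muts = make_mutations(
            [mut(pos=100 + i, alt="G") for i in range(100)] +
            [mut(sample_id="S2", pos=300, consequence="frameshift_indel")])
        calls = pd.DataFrame([
            dict(sample_id="S1", gene="TP53", rule="deleterious_tsg",
                 source="mutation") for _ in range(4)])
        meta = make_meta([dict(sample_id="S1"), dict(sample_id="S2")])
        out = drivers_per_sample(calls, muts, meta).set_index("sample_id")
        assert out.loc["S1", "drivers_per_100_exonic_snv"] == pytest.approx(4.0)
        assert out.loc["S1", "n_driver_mutations"] == 4
        # S2 has no exonic SNVs: raw count kept, normalised value missing
        assert out.loc["S2", "n_driver_mutations"] == 0
        assert np.isnan(out.loc["S2", "drivers_per_100_exonic_snv"])

    def test_indels_do_not_count_as_exonic_snvs(self):
        muts = make_mutations([
            mut(pos=1), mut(pos=2, consequence="synonymous"),
            mut(pos=3, consequence="frameshift_indel"),
            mut(pos=4, ref="AT", alt="A", consequence="nonsyn_snv"),
        ])
        assert exonic_snv_counts(muts)["S1"] == 2

    def test_pathway_mapping_union(self):
        calls = pd.DataFrame([
            dict(sample_id="S1", gene="TP53"),
            dict(sample_id="S1", gene="KRAS"),
            dict(sample_id="S1", gene="CDKN2A"),
            dict(sample_id="S2", gene="UNMAPPED"),
        ])
        out = map_to_pathways(calls, RESOURCE)
        s1 = set(out.loc[out["sample_id"] == "S1", "pathway"])
        assert s1 == {"p53", "RTK/RAS", "Cell cycle"}
        assert not (out["sample_id"] == "S2").any()


def test_bundled_resources_load():
    res = load_gene_resource()
    assert {"TSG", "oncogene", "both"} <= set(res.roles["role"])
    assert res.pathways["pathway"].nunique() == 10
    rec = load_recurrence()
    assert (rec["count"] > 0).all()
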