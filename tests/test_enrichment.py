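"""Fisher/FDR machinery against independent oracles, enrichment analyses on
constructed tables, outliers and the gene-length confound."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutclock.drivers import GeneResource
from mutclock.enrichment import (fdr_adjust, fisher_2x2, gene_ccf_outliers,
                                 gene_enrichment, gene_length_confound,
                                 hotspot_scan, or_concordance,
                                 timing_enrichment)
from mutclock.errors import MutclockError

from conftest import make_meta, make_mutations


def fisher_p_enumeration(a, b, c, d):
    """Oracle: sum hypergeometric probabilities of all tables with the
    observed margins that are no more likely than the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    obs = comb(r1, a) * comb(r2, c1 - a) / denom
    p = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        pr = comb(r1, x) * comb(r2, c1 - x) / denom
        if pr <= obs * (1 + 1e-9):
            p += pr
    return min(p, 1.0)


def bh_oracle(p):
    """Textbook Benjamini–Hochberg step-up, written from the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFisher:
    @pytest.mark.parametrize("table", [(10, 90, 30, 70), (3, 0, 2, 5),
                                       (0, 10, 10, 0), (7, 1, 1, 7)])
    def test_matches_enumeration(self, table):
        _, p = fisher_2x2(*table)
        assert p == pytest.approx(fisher_p_enumeration(*table), abs=1e-12)

    def test_balanced_table(self):
        odds, p = fisher_2x2(5, 5, 5, 5)
        assert odds == 1.0 and p == 1.0

    def test_haldane_correction_on_zero_cells(self):
        odds, p = fisher_2x2(0, 10, 10, 0)
        assert odds == pytest.approx(0.25 / 110.25)
        assert p == pytest.approx(fisher_p_enumeration(0, 10, 10, 0))

    def test_degenerate_margin(self):
        odds, p = fisher_2x2(0, 0, 5, 5)
        assert np.isnan(odds) and p == 1.0

    def test_label_swap_inverts_odds_and_preserves_p(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 30, size=4)
            o1, p1 = fisher_2x2(a, b, c, d)
            o2, p2 = fisher_2x2(c, d, a, b)
            assert o1 * o2 == pytest.approx(1.0)
            assert p1 == pytest.approx(p2, rel=1e-9)

    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25)))
    @settings(max_examples=300, deadline=None)
    def test_enumeration_equivalence_property(self, table):
        a, b, c, d = table
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        _, p = fisher_2x2(a, b, c, d)
        assert p == pytest.approx(fisher_p_enumeration(a, b, c, d), abs=1e-9)


class TestFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_single_value_unchanged(self):
        assert fdr_adjust([0.5])[0] == pytest.approx(0.5)

    def test_empty_input(self):
        assert fdr_adjust([]).size == 0

    def test_matches_definition_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p), atol=1e-12)

    def test_q_dominates_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 100)
        q = fdr_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()


def driver_calls(rows):
    return pd.DataFrame([dict(sample_id=r[0], gene=r[1], source="mutation")
                         for r in rows])


class TestGeneEnrichment:
    def _meta(self, n_pri=10, n_met=10):
        return make_meta(
            [dict(sample_id=f"P{i}", cohort="primary") for i in range(n_pri)] +
            [dict(sample_id=f"M{i}", cohort="metastatic") for i in range(n_met)])

    def test_strong_metastatic_enrichment_flagged(self):
        calls = driver_calls([(f"M{i}", "G1") for i in range(8)] +
                             [("P0", "G1")])
        res = gene_enrichment(calls, self._meta())
        row = res.iloc[0]
        assert row["unit"] == "G1" and row["direction"] == "metastatic"
        assert row["q"] < 0.05
        assert (row["a"], row["b"], row["c"], row["d"]) == (8, 2, 1, 9)

    def test_equal_proportions_not_significant(self):
        calls = driver_calls([(f"M{i}", "G1") for i in range(5)] +
                             [(f"P{i}", "G1") for i in range(5)])
        res = gene_enrichment(calls, self._meta())
        assert res.iloc[0]["p"] == 1.0

    def test_counts_partition_the_stratum(self):
        calls = driver_calls([("M0", "G1"), ("P0", "G1"), ("P1", "G2")])
        res = gene_enrichment(calls, self._meta(), stratify="per_type")
        assert ((res["a"] + res["b"] + res["c"] + res["d"]) == 20).all()

    def test_null_cohort_fdr_control(self):
        """With no true cohort differences, q < 0.05 calls are rare."""
        rng = np.random.default_rng(2024)
        meta = self._meta(25, 25)
        n_hits = 0
        reps = 100
        for _ in range(reps):
            rows = []
            for g in range(30):
                prob = rng.uniform(0.05, 0.4)
                for sid in meta["sample_id"]:
                    if rng.random() < prob:
                        rows.append((sid, f"G{g}"))
            res = gene_enrichment(driver_calls(rows), meta)
            n_hits += int((res["q"] < 0.05).any())
        assert n_hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestTimingEnrichment:
    def test_early_skewed_pathway_detected(self):
        rows = [dict(gene="p53", timing="early")] * 30 + \
               [dict(gene="p53", timing="late")] * 5 + \
               [dict(gene="other", timing="early")] * 100 + \
               [dict(gene="other", timing="late")] * 100
        res = timing_enrichment(pd.DataFrame(rows))
        row = res[res["unit"] == "p53"].iloc[0]
        assert row["direction"] == "early" and row["q"] < 0.05

    def test_background_matched_unit_has_unit_odds(self):
        rows = [dict(gene="G", timing="early")] * 10 + \
               [dict(gene="G", timing="late")] * 10 + \
               [dict(gene="other", timing="early")] * 50 + \
               [dict(gene="other", timing="late")] * 50
        res = timing_enrichment(pd.DataFrame(rows))
        assert res[res["unit"] == "G"].iloc[0]["odds_ratio"] \
            == pytest.approx(1.0)

    def test_sparse_units_skipped(self):
        rows = [dict(gene="rare", timing="early")] + \
               [dict(gene="other", timing="late")] * 10
        res = timing_enrichment(pd.DataFrame(rows))
        assert "rare" not in set(res["unit"])


class TestOrConcordance:
    def _frame(self, ors):
        return pd.DataFrame({"unit": [f"U{i}" for i in range(len(ors))],
                             "stratum": "pan", "odds_ratio": ors})

    def test_identical_vectors_correlate_perfectly(self):
        ors = [0.5, 1.0, 2.0, 4.0, 8.0]
        r, _ = or_concordance(self._frame(ors), self._frame(ors))
        assert r == pytest.approx(1.0)

    def test_reciprocal_vectors_anticorrelate(self):
        ors = np.array([0.5, 1.5, 2.0, 4.0, 8.0])
        r, _ = or_concordance(self._frame(ors), self._frame(1 / ors))
        assert r == pytest.approx(-1.0)

    def test_too_few_matched_units_is_an_error(self):
        with pytest.raises(MutclockError):
            or_concordance(self._frame([1.0, 2.0]), self._frame([1.0, 2.0]))


class TestHotspots:
    def _inputs(self):
        meta = make_meta(
            [dict(sample_id=f"P{i}", cohort="primary") for i in range(50)] +
            [dict(sample_id=f"M{i}", cohort="metastatic") for i in range(50)])
        rows = [dict(sample_id=f"M{i}", chrom="7", pos=100, ref="C", alt="T",
                     gene="EGFR") for i in range(10)]
        rows.append(dict(sample_id="P0", chrom="1", pos=5, ref="A", alt="G",
                         gene="X"))  # singleton: below min_patients
        return make_mutations(rows), meta

    def test_metastatic_only_variant_recovered(self):
        muts, meta = self._inputs()
        res = hotspot_scan(muts, meta)
        assert len(res) == 1
        row = res.iloc[0]
        assert row["gene"] == "EGFR" and row["direction"] == "metastatic"
        assert row["p"] == pytest.approx(
            fisher_p_enumeration(10, 40, 0, 50), abs=1e-12)

    def test_min_patient_filter(self):
        muts, meta = self._inputs()
        res = hotspot_scan(muts, meta, min_patients=11)
        assert res.empty


class TestCcfOutliers:
    def _calls(self, gene_means, n_per_gene=5):
        rows, sids = [], []
        for g, (gene, mean) in enumerate(gene_means.items()):
            for i in range(n_per_gene):
                sid = f"S{g}_{i}"
                rows.append(dict(sample_id=sid, gene=gene, ccf=mean))
                sids.append(sid)
        meta = make_meta([dict(sample_id=s) for s in sids])
        return pd.DataFrame(rows), meta

    def test_low_ccf_gene_flagged(self):
        means = {f"G{i}": 1.0 for i in range(9)}
        means["SUBCLONAL_GENE"] = 0.2
        calls, meta = self._calls(means)
        res = gene_ccf_outliers(calls, meta)
        flagged = res[res["outlier"]]
        assert list(flagged["gene"]) == ["SUBCLONAL_GENE"]
        assert flagged.iloc[0]["zscore"] < -2

    def test_zero_sd_makes_no_calls(self):
        calls, meta = self._calls({f"G{i}": 1.0 for i in range(5)})
        res = gene_ccf_outliers(calls, meta)
        assert not res["outlier"].any()

    def test_genes_below_minimum_excluded(self):
        means = {f"G{i}": 1.0 for i in range(5)}
        calls, meta = self._calls(means, n_per_gene=4)
        res = gene_ccf_outliers(calls, meta, min_drivers=5)
        assert res.empty


class TestGeneLengthConfound:
    def _resource(self, lengths):
        roles = pd.DataFrame([
            dict(gene=f"G{i}", role="other", chrom="1", start=1, end=l,
                 length_bp=l) for i, l in enumerate(lengths)])
        return GeneResource(roles=roles, pathways=pd.DataFrame(
            columns=["pathway", "gene"]))

    def test_single_longest_gene_percentile(self):
        res = self._resource(list(range(1000, 101000, 1000)))
        pct, _ = gene_length_confound(["G99"], res)
        assert pct == pytest.approx(1.0, abs=0.01)

    def test_top_decile_is_significant(self):
        res = self._resource(list(range(1000, 101000, 1000)))
        enriched = [f"G{i}" for i in range(90, 100)]
        pct, p = gene_length_confound(enriched, res)
        assert pct > 0.9 and p < 0.05

    def test_random_sample_is_null(self):
        rng = np.random.default_rng(4)
        res = self._resource(list(rng.integers(1000, 100000, size=200)))
        enriched = [f"G{i}" for i in rng.choice(200, size=40, replace=False)]
        pct, p = gene_length_confound(enriched, res)
        assert 0.35 < pct < 0.65 and p > 0.05

    def test_empty_set_is_an_error(self):
        res = self._resource([100, 200])
        with pytest.raises(MutclockError):
            gene_length_confound([], res)
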