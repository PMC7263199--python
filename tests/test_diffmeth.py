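import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from methylmark.diffmeth import (call_dmcs, feature_enrichment, ks_normality,
                                 region_differential, summarize_regions)
from methylmark.diffmeth import test_site as site_test


def fisher_enumeration_p(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed
    the observed table's (independent oracle)."""
    n, K, N = a + b + c + d, a + b, a + c
    obs = hypergeom.pmf(a, n, K, N)
    total = 0.0
    for x in range(max(0, K + N - n), min(K, N) + 1):
        px = hypergeom.pmf(x, n, K, N)
        if px <= obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestKSNormality:
    def test_accepts_normal_draws(self):
        hits = sum(ks_normality(np.random.default_rng(s).normal(0.4, 0.05, 1000))
                   for s in range(20))
        assert hits >= 18

    def test_rejects_uniform(self):
        assert not ks_normality(np.random.default_rng(0).uniform(0, 1, 1000))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.full(20, 0.3))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.arange(5))


class TestTestSite:
    def test_identical_vectors_null(self):
        v = np.linspace(0.1, 0.9, 20)
        for normal in (True, False):
            delta, p = site_test(v, v, paired=True, normal_dist=normal)
            assert delta == 0.0 and p > 0.9

    def test_paired_shift_detected(self, rng):
        normal = rng.normal(0.3, 0.05, 20)
        tumor = normal + 0.4
        delta, p = site_test(tumor, normal, paired=True, normal_dist=True)
        assert delta == pytest.approx(0.4, abs=1e-12)
        assert p < 1e-6

    @pytest.mark.parametrize("paired,normal", [(True, True), (True, False),
                                               (False, True), (False, False)])
    def test_group_swap_antisymmetry(self, rng, paired, normal):
        a = rng.normal(0.5, 0.1, 15)
        b = rng.normal(0.3, 0.1, 15)
        d1, p1 = site_test(a, b, paired, normal)
        d2, p2 = site_test(b, a, paired, normal)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            site_test(np.ones(5), np.ones(4), paired=True, normal_dist=True)


def _toy_sheet(n_pairs):
    rows = []
    for i in range(n_pairs):
        rows.append((f"T{i}", "BRCA", "tumor", f"P{i}"))
        rows.append((f"N{i}", "BRCA", "adjacent_normal", f"P{i}"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "cohort", "tissue", "patient_id"])
    return sheet.set_index("sample_id", drop=False)


class TestCallDmcs:
    def test_planted_marker_called_hyper(self, rng):
        sheet = _toy_sheet(50)
        probes = [f"cg{i}" for i in range(200)]
        base = rng.uniform(0.1, 0.4, (200, 1))
        vals = np.clip(base + rng.normal(0, 0.03, (200, 100)), 0, 1)
        beta = pd.DataFrame(vals, index=probes, columns=sheet.index)
        tum = [f"T{i}" for i in range(50)]
        beta.loc["cg0", tum] = np.clip(beta.loc["cg0", tum] + 0.4, 0, 1)
        out = call_dmcs(beta, sheet, mode="paired")
        assert out.loc["cg0", "direction"] == "hyper"

    def test_small_delta_is_ns_despite_tiny_p(self, rng):
        # a 0.15 shift with tiny noise: p astronomically small, still ns
        sheet = _toy_sheet(30)
        normal = np.tile(rng.normal(0.3, 0.005, 60), (5, 1))
        beta = pd.DataFrame(normal, index=[f"cg{i}" for i in range(5)],
                            columns=sheet.index)
        tum = [f"T{i}" for i in range(30)]
        beta.loc["cg0", tum] += 0.15
        out = call_dmcs(beta, sheet, mode="paired", normal_dist=True)
        assert out.loc["cg0", "p_value"] < 1e-10
        assert out.loc["cg0", "direction"] == "ns"

    def test_column_permutation_invariance_unpaired(self, rng):
        sheet = _toy_sheet(20)
        beta = pd.DataFrame(rng.random((50, 40)),
                            index=[f"cg{i}" for i in range(50)], columns=sheet.index)
        out1 = call_dmcs(beta, sheet, mode="unpaired", normal_dist=True)
        perm = list(rng.permutation(beta.columns))
        out2 = call_dmcs(beta[perm], sheet, mode="unpaired", normal_dist=True)
        np.testing.assert_allclose(out1["p_value"], out2["p_value"])
        np.testing.assert_allclose(out1["delta_beta"], out2["delta_beta"])

    def test_hyper_hypo_antisymmetric_under_label_swap(self, rng):
        sheet = _toy_sheet(25)
        beta = pd.DataFrame(rng.random((100, 50)),
                            index=[f"cg{i}" for i in range(100)], columns=sheet.index)
        tum = [f"T{i}" for i in range(25)]
        beta.loc[beta.index[:10], tum] = np.clip(
            beta.loc[beta.index[:10], tum] + 0.5, 0, 1)
        out = call_dmcs(beta, sheet, mode="unpaired", normal_dist=True)
        swapped = sheet.copy()
        swapped["tissue"] = swapped["tissue"].map(
            {"tumor": "adjacent_normal", "adjacent_normal": "tumor"})
        out_swap = call_dmcs(beta, swapped, mode="unpaired", normal_dist=True)
        hyper = set(out.index[out["direction"] == "hyper"])
        hypo_sw = set(out_swap.index[out_swap["direction"] == "hypo"])
        assert hyper == hypo_sw

    def test_requires_normals(self, rng):
        sheet = _toy_sheet(5)
        beta = pd.DataFrame(rng.random((5, 10)),
                            index=[f"cg{i}" for i in range(5)], columns=sheet.index)
        with pytest.raises(ValueError):
            call_dmcs(beta, sheet[sheet.tissue == "tumor"], mode="unpaired")

    def test_bh_fdr_monotone_and_bounded(self, rng):
        sheet = _toy_sheet(10)
        beta = pd.DataFrame(rng.random((80, 20)),
                            index=[f"cg{i}" for i in range(80)], columns=sheet.index)
        out = call_dmcs(beta, sheet, mode="unpaired", normal_dist=True)
        srt = out.sort_values("p_value")
        assert (srt["fdr"].to_numpy() >= srt["p_value"].to_numpy() - 1e-12).all()
        assert (np.diff(srt["fdr"].to_numpy()) >= -1e-12).all()


class TestRegions:
    @pytest.fixture
    def region_setup(self):
        annot = pd.DataFrame({
            "probe_id": ["cg1", "cg2", "cg3", "cg4"],
            "chrom": "chr1", "pos": [1, 2, 3, 4],
            "cgi_relation": ["Island", "Island", "NShore", "OpenSea"],
            "gene": ["G1", "G1", "G1", "G2"],
            "feature": ["TSS200", "TSS200", "Body", "Body"],
            "snp": False,
        }).set_index("probe_id", drop=False)
        beta = pd.DataFrame({"s1": [0.2, 0.4, 0.5, 0.9],
                             "s2": [0.2, np.nan, 0.6, 0.8]},
                            index=["cg1", "cg2", "cg3", "cg4"])
        return annot, beta

    def test_region_mean(self, region_setup):
        annot, beta = region_setup
        reg = summarize_regions(beta, annot, scheme="cgi")
        assert reg.loc[("G1", "Island"), "s1"] == pytest.approx(0.3)

    def test_single_cpg_region_is_identity(self, region_setup):
        annot, beta = region_setup
        reg = summarize_regions(beta, annot, scheme="cgi")
        assert reg.loc[("G1", "NShore"), "s1"] == pytest.approx(0.5)

    def test_missing_aware_mean(self, region_setup):
        annot, beta = region_setup
        reg = summarize_regions(beta, annot, scheme="cgi")
        assert reg.loc[("G1", "Island"), "s2"] == pytest.approx(0.2)

    def test_open_sea_omitted(self, region_setup):
        annot, beta = region_setup
        reg = summarize_regions(beta, annot, scheme="cgi")
        assert ("G2", "OpenSea") not in reg.index

    def test_region_differential_planted_and_null(self, rng):
        sheet = _toy_sheet(30)
        idx = pd.MultiIndex.from_tuples(
            [(f"G{i}", "Island") for i in range(20)], names=["gene", "region"])
        vals = np.clip(rng.normal(0.3, 0.02, (20, 60)), 0, 1)
        regions = pd.DataFrame(vals, index=idx, columns=sheet.index)
        tum = [f"T{i}" for i in range(30)]
        regions.loc[("G0", "Island"), tum] += 0.4
        table, counts = region_differential(regions, sheet)
        assert table.loc[("G0", "Island"), "direction"] == "hyper"
        assert counts["Island"]["hyper"] == 1
        # identical matrices -> all ns
        null = pd.DataFrame(np.tile(np.linspace(0.2, 0.4, 20)[:, None], (1, 60)),
                            index=idx, columns=sheet.index)
        _, counts0 = region_differential(null, sheet)
        assert counts0["Island"]["hyper"] == 0 and counts0["Island"]["hypo"] == 0

    def test_unpaired_data_directed_to_unpaired_mode(self, rng):
        sheet = _toy_sheet(5)
        sheet["patient_id"] = [f"Q{i}" for i in range(10)]  # break pairing
        idx = pd.MultiIndex.from_tuples([("G0", "Island")], names=["gene", "region"])
        regions = pd.DataFrame(rng.random((1, 10)), index=idx, columns=sheet.index)
        with pytest.raises(ValueError, match="unpaired"):
            region_differential(regions, sheet)


def _flat_annotation(n, feature_mask):
    return pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(n)],
        "chrom": "chr1", "pos": 1,
        "cgi_relation": np.where(feature_mask, "Island", "OpenSea"),
        "gene": "G", "feature": "Body", "snp": False,
    }).set_index("probe_id", drop=False)


class TestEnrichment:
    def test_balanced_table_no_association(self):
        mask = np.array([True] * 20 + [False] * 20)
        annot = _flat_annotation(40, mask)
        hyper = [f"cg{i}" for i in range(10)] + [f"cg{i}" for i in range(20, 30)]
        other = [f"cg{i}" for i in range(10, 20)] + [f"cg{i}" for i in range(30, 40)]
        res = feature_enrichment(hyper, other, annot, "Island")
        assert res.table == (10, 10, 10, 10)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_association_matches_enumeration(self):
        mask = np.array([True] * 25 + [False] * 25)
        annot = _flat_annotation(50, mask)
        # a=20 hyper islands, b=5 hyper open sea, c=5 / d=20 for the others
        hyper = [f"cg{i}" for i in range(20)] + [f"cg{i}" for i in range(25, 30)]
        other = [f"cg{i}" for i in range(20, 25)] + [f"cg{i}" for i in range(30, 50)]
        res = feature_enrichment(hyper, other, annot, "Island")
        assert res.table == (20, 5, 5, 20)
        assert res.odds_ratio == pytest.approx(16.0)
        assert res.p_value == pytest.approx(fisher_enumeration_p(20, 5, 5, 20), rel=1e-9)
        lo, hi = res.ci95
        assert lo < 16.0 < hi

    def test_zero_cell_flagged_infinite(self):
        mask = np.array([True] * 10 + [False] * 10)
        annot = _flat_annotation(20, mask)
        hyper = [f"cg{i}" for i in range(10)]          # all in feature -> b = 0
        other = [f"cg{i}" for i in range(10, 20)]
        res = feature_enrichment(hyper, other, annot, "Island")
        assert np.isinf(res.odds_ratio)
        assert res.degenerate and np.isinf(res.ci95[1])

    def test_empty_set_rejected(self):
        annot = _flat_annotation(4, np.array([True, True, False, False]))
        with pytest.raises(ValueError):
            feature_enrichment([], ["cg0"], annot, "Island")

    def test_reference_may_contain_hyper(self):
        # hyper-vs-all contrast: overlap removed from the reference
        mask = np.array([True] * 10 + [False] * 10)
        annot = _flat_annotation(20, mask)
        hyper = [f"cg{i}" for i in range(5)]
        res = feature_enrichment(hyper, annot.index, annot, "Island")
        a, b, c, d = res.table
        assert a + b == 5 and a + b + c + d == 20
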