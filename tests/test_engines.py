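"""The four DE engines plus Wilcoxon: oracles, calibration, symmetries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decombine import (
    ENGINE_ORDER,
    run_all_engines,
    run_nb_exact,
    run_nb_wald,
    run_score_test,
    run_voom_t,
    run_wilcoxon,
    SimConfig,
    simulate_dataset,
    tmm_factors,
)
from decombine.engines import _binom_exact_pvalue, _exact_nb_pvalue

from .conftest import make_counts, make_sheet


def nb_fixture(seed=0, n_genes=300, n1=3, n2=3, mean=100, phi=0.15):
    rng = np.random.default_rng(seed)
    r = 1.0 / phi
    arr = rng.negative_binomial(r, r / (r + mean), size=(n_genes, n1 + n2))
    return make_counts(arr), make_sheet(n1, n2)


class TestNBExact:
    def test_poisson_limit_matches_binomial_tail_sum(self):
        """With zero dispersion the conditional law is binomial."""
        # totals 15 and 30 in two equal groups of arbitrary size
        s1, t = 5, 15
        oracle = stats.binomtest(s1, t, 0.5).pvalue
        assert np.isclose(_binom_exact_pvalue(s1, t, 0.5), oracle, atol=1e-12)
        # beta-binomial with enormous size parameters converges to binomial
        approx = _exact_nb_pvalue(s1, t, 1e7, 1e7)
        assert np.isclose(approx, oracle, atol=1e-4)

    def test_exact_pvalue_against_enumeration_oracle(self):
        """Brute-force beta-binomial mass ordering on a small total."""
        s1, t, r1, r2 = 2, 12, 20.0, 30.0
        s = np.arange(t + 1)
        from scipy.special import betaln, gammaln

        logf = (
            gammaln(t + 1) - gammaln(s + 1) - gammaln(t - s + 1)
            + betaln(s + r1, t - s + r2) - betaln(r1, r2)
        )
        f = np.exp(logf)
        f /= f.sum()
        expect = f[f <= f[s1] * (1 + 1e-10)].sum()
        assert np.isclose(_exact_nb_pvalue(s1, t, r1, r2), expect, atol=1e-12)

    def test_strong_de_gene_detected(self):
        cm, sheet = nb_fixture(seed=1)
        arr = cm.counts.to_numpy().copy()
        arr[0] = [0, 0, 0, 50, 60, 55]
        cm = make_counts(arr)
        res = run_nb_exact(cm, sheet)
        assert res.table["p_value"].iloc[0] < 1e-4
        assert res.table["log2_fc"].iloc[0] > 4
        assert np.isfinite(res.table["log2_fc"]).all()

    def test_null_p_uniform(self, small_null_dataset):
        cm, sheet, _ = small_null_dataset
        from decombine import filter_by_expression

        res = run_nb_exact(filter_by_expression(cm, sheet), sheet)
        assert stats.kstest(res.table["p_value"], "uniform").pvalue > 0.01

    def test_gene_order_invariance(self):
        cm, sheet = nb_fixture(seed=2, n_genes=100)
        res1 = run_nb_exact(cm, sheet)
        order = np.random.default_rng(0).permutation(100)
        cm2 = make_counts(
            cm.counts.to_numpy()[order], genes=[cm.gene_ids[i] for i in order]
        )
        res2 = run_nb_exact(cm2, sheet)
        merged = res1.table["p_value"].reindex(res2.table.index)
        assert np.allclose(merged, res2.table["p_value"])


class TestVoom:
    def test_equal_variance_is_moderation_fixed_point(self):
        from decombine.engines import _fit_f_dist

        s2 = np.full(50, 0.73)
        d0, s0 = _fit_f_dist(s2, df=4)
        assert np.isinf(d0)
        assert np.isclose(s0, 0.73, rtol=1e-10)

    def test_weighted_fit_matches_wls_oracle(self):
        import statsmodels.api as sm

        cm, sheet = nb_fixture(seed=3, n_genes=40, n1=4, n2=4)
        res = run_voom_t(cm, sheet)
        w = res.extras["weights"]
        logcpm = res.extras["logcpm"]
        x = sheet.indicator()
        design = sm.add_constant(x)
        for g in (0, 7, 23):
            fit = sm.WLS(logcpm[g], design, weights=w[g]).fit()
            assert np.isclose(res.table["log2_fc"].iloc[g], fit.params[1], atol=1e-8)
            assert np.isclose(res.extras["s2"][g], fit.mse_resid, rtol=1e-8)

    def test_null_p_uniform(self, small_null_dataset):
        cm, sheet, _ = small_null_dataset
        from decombine import filter_by_expression

        res = run_voom_t(filter_by_expression(cm, sheet), sheet)
        assert stats.kstest(res.table["p_value"], "uniform").pvalue > 0.01


class TestNBWald:
    def test_null_p_uniform_and_calibrated(self, small_null_dataset):
        cm, sheet, _ = small_null_dataset
        from decombine import filter_by_expression

        res = run_nb_wald(filter_by_expression(cm, sheet), sheet)
        p = res.table["p_value"]
        assert 0.02 <= np.mean(p <= 0.05) <= 0.08
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_dispersion_trend_recovery(self):
        """Planted trend phi = 0.1 + 1/mu recovered within 20%."""
        rng = np.random.default_rng(7)
        n = 5000
        mu = np.clip(2.0 ** rng.normal(6, 2.5, n), 1, None)
        phi = 0.1 + 1.0 / mu
        r = 1.0 / phi
        counts = rng.negative_binomial(r[:, None], (r / (r + mu))[:, None], size=(n, 20))
        cm = make_counts(counts)
        res = run_nb_wald(cm, make_sheet(10, 10))
        assert abs(res.extras["trend_a0"] - 0.1) / 0.1 < 0.2
        assert abs(res.extras["trend_a1"] - 1.0) / 1.0 < 0.2

    def test_dispersion_outlier_not_shrunk(self):
        cm, sheet = nb_fixture(seed=4, n_genes=400, n1=5, n2=5, phi=0.05)
        # one gene with enormous overdispersion
        arr = cm.counts.to_numpy().copy()
        arr[0] = [1, 900, 5, 2000, 3, 1500, 8, 700, 2, 1200]
        res = run_nb_wald(make_counts(arr), sheet)
        mle = res.extras["dispersion_mle"][0]
        final = res.extras["dispersion_map"][0]
        assert np.isclose(final, mle)
        # a typical gene IS shrunk toward the trend
        assert not np.allclose(
            res.extras["dispersion_mle"][1:50], res.extras["dispersion_map"][1:50]
        )


class TestScoreTest:
    def test_permutation_enumeration_count(self):
        """n=3 vs 3: C(6,3)=20 distinct reassignments bound the minimum p."""
        cm, sheet = nb_fixture(seed=5, n_genes=30)
        arr = cm.counts.to_numpy().copy()
        arr[0] = [1, 2, 3, 4000, 5000, 6000]  # perfectly separated
        res = run_score_test(make_counts(arr), sheet, n_perm=1000, seed=0)
        p = res.table["p_value"]
        # the squared statistic is label-complement symmetric, so the most
        # extreme achievable p over the 20 reassignments is 2/20
        assert np.isclose(p.min(), 2.0 / 20.0)
        assert np.allclose(np.round(p * 20) / 20, p, atol=1e-12)

    def test_label_swap_flips_lfc_keeps_p(self):
        cm, sheet = nb_fixture(seed=6, n_genes=50)
        swapped = make_sheet(3, 3)
        swapped.table["condition"] = ["b"] * 3 + ["a"] * 3
        sw = type(sheet)(swapped.table, "condition", "a", "b")
        r1 = run_score_test(cm, sheet)
        r2 = run_score_test(cm, sw)
        assert np.allclose(r1.table["p_value"], r2.table["p_value"])
        assert np.allclose(r1.table["log2_fc"], -r2.table["log2_fc"])

    def test_asymptotic_null_uniform_large_n(self):
        cfg = SimConfig.from_preset(1, n_per_group=50, seed=13, n_genes=1500)
        cm, sheet, _ = simulate_dataset(cfg, 0)
        from decombine import filter_by_expression

        res = run_score_test(filter_by_expression(cm, sheet), sheet)
        assert stats.kstest(res.table["p_value"], "uniform").pvalue > 0.01

    def test_constant_gene_convention(self):
        # identical columns: CPM of every gene is constant across samples
        arr = np.vstack([np.full(6, 7), np.full(6, 50), np.full(6, 943)])
        cm = make_counts(arr)
        sheet = make_sheet(3, 3)
        res = run_score_test(cm, sheet)
        assert res.table["p_value"].iloc[0] == 1.0
        assert res.table["log2_fc"].iloc[0] == 0.0


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        """(1,2,3) vs (4,5,6): most extreme of C(6,3)=20 splits, p = 2/20."""
        arr = np.array([[10, 20, 30, 40, 50, 60]])
        filler = 1000 - arr.sum(axis=0, keepdims=True).repeat(1, 0)
        cm = make_counts(np.vstack([arr, 1000 - arr]))
        sheet = make_sheet(3, 3)
        res = run_wilcoxon(cm, sheet)
        assert np.isclose(res.table["p_value"].iloc[0], 0.1)

    def test_all_tied_gives_p_one(self):
        cm = make_counts(np.vstack([np.full(6, 50), np.full(6, 950)]))
        res = run_wilcoxon(cm, make_sheet(3, 3))
        assert res.table["p_value"].iloc[0] == 1.0

    def test_rank_invariance_under_monotone_count_scaling(self):
        cm, sheet = nb_fixture(seed=8, n_genes=60)
        res1 = run_wilcoxon(cm, sheet)
        # equal scaling of every sample leaves CPM ranks unchanged
        cm2 = make_counts(cm.counts.to_numpy() * 3)
        res2 = run_wilcoxon(cm2, sheet)
        assert np.allclose(res1.table["p_value"], res2.table["p_value"])


class TestRunAll:
    def test_contract_gene_sets_and_determinism(self, small_de_dataset):
        cm, sheet, truth = small_de_dataset
        from decombine import filter_by_expression

        filt = filter_by_expression(cm, sheet)
        res1 = run_all_engines(filt, sheet, include_wilcoxon=True, seed=3)
        res2 = run_all_engines(filt, sheet, include_wilcoxon=True, seed=3)
        assert set(res1) == set(ENGINE_ORDER) | {"wilcoxon"}
        genes = list(res1["nb_exact"].table.index)
        for name, r in res1.items():
            assert list(r.table.index) == genes
            pd.testing.assert_frame_equal(r.table, res2[name].table)
            assert (r.table["padj"] >= r.table["p_value"]).all()

    def test_engines_agree_on_strong_spikein_sign(self):
        cm, sheet = nb_fixture(seed=9, n_genes=200)
        arr = cm.counts.to_numpy().copy()
        arr[0] = [10, 12, 9, 400, 380, 420]
        arr[1] = [400, 380, 420, 10, 12, 9]
        res = run_all_engines(make_counts(arr), sheet, include_wilcoxon=True)
        for r in res.values():
            assert r.table["log2_fc"].iloc[0] > 0
            assert r.table["log2_fc"].iloc[1] < 0
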