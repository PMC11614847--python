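"""P-value combination, BH adjustment, DE calling, Max-P intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from decombine import (
    COMBINERS,
    bh_adjust,
    bonferroni_holm_combine,
    call_de,
    combine_all,
    fisher_combine,
    lancaster_combine,
    max_p_intersect,
    mean_log2fc,
    stouffer_combine,
    tippett_combine,
    wilkinson_combine,
)


class TestWorkedExamples:
    """Hand- or oracle-computed values, frozen."""

    def test_fisher(self):
        assert np.isclose(fisher_combine([[1, 1, 1, 1]])[0], 1.0)
        # X = -2(ln .5 + ln .5) = 2.77259; chi2(4) upper tail
        assert np.isclose(fisher_combine([[0.5, 0.5]])[0], 0.5965736, atol=1e-6)
        assert fisher_combine([[1e-300, 0.5, 0.5, 0.5]])[0] < 1e-200

    def test_stouffer(self):
        assert np.isclose(stouffer_combine([[0.5] * 4])[0], 0.5)
        # Z = 2 * 1.64485 / sqrt(2) = 2.32617 -> p = 0.0100046
        assert np.isclose(stouffer_combine([[0.05, 0.05]])[0], 0.0100046, atol=1e-6)
        p = [[0.1, 0.3, 0.7, 0.9]]
        assert np.isclose(
            stouffer_combine(p)[0], stouffer_combine([list(reversed(p[0]))])[0]
        )

    def test_lancaster(self):
        # w = (4,4), p = (.5,.5): T = 2 * chi2_4 median = 6.71338 vs chi2(8)
        t = 2 * stats.chi2.ppf(0.5, 4)
        expect = stats.chi2.sf(t, 8)
        assert np.isclose(expect, 0.567848, atol=1e-5)
        assert np.isclose(lancaster_combine([[0.5, 0.5]], [4, 4])[0], expect, atol=1e-8)
        assert np.isclose(lancaster_combine([[1, 1, 1, 1]])[0], 1.0, atol=1e-12)
        with pytest.raises(ValueError):
            lancaster_combine([[0.5, 0.5]], [1, -1])

    def test_lancaster_weight_two_reduces_to_fisher(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=(500, 4))
        assert np.allclose(lancaster_combine(p, [2, 2, 2, 2]), fisher_combine(p), atol=1e-10)

    def test_wilkinson(self):
        p = [[0.7, 0.5, 0.9, 0.6]]
        # r = k = 4: Beta(4,1) CDF = x^4 at the maximum (0.9)
        assert np.isclose(wilkinson_combine(p, r=4)[0], 0.9**4)
        assert np.isclose(wilkinson_combine([[0.5, 0.5, 0.5, 0.5]], r=4)[0], 0.0625)
        assert np.isclose(wilkinson_combine([[1, 1, 1, 1]], r=2)[0], 1.0)
        with pytest.raises(ValueError):
            wilkinson_combine(p, r=5)

    def test_wilkinson_r1_equals_tippett(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=(1000, 4))
        assert np.array_equal(wilkinson_combine(p, r=1), tippett_combine(p)) or np.allclose(
            wilkinson_combine(p, r=1), tippett_combine(p), rtol=0, atol=5e-16
        )

    def test_bonferroni_holm(self):
        assert np.isclose(
            bonferroni_holm_combine([[0.01, 0.5, 0.5, 0.5]])[0], 0.04
        )
        assert np.isclose(bonferroni_holm_combine([[1, 1, 1, 1]])[0], 1.0)
        assert np.isclose(bonferroni_holm_combine([[0.3]])[0], 0.3)

    def test_tippett(self):
        assert np.isclose(tippett_combine([[0.01, 0.5, 0.5, 0.5]])[0], 1 - 0.99**4)
        assert tippett_combine([[0.0, 0.5, 0.5, 0.5]])[0] < 1e-12
        assert np.isclose(tippett_combine([[1, 1, 1, 1]])[0], 1.0)


class TestCombinerProperties:
    @pytest.mark.parametrize("name", sorted(COMBINERS))
    def test_null_uniformity(self, name):
        """Independent uniform inputs yield a valid (uniform) combined p.

        The Holm bound is the one member of the family whose combined p is
        sub-uniform by construction (it is a step-down multiplicity bound,
        not an exact transform), so for it validity — never anti-
        conservative — is the correct null property.
        """
        rng = np.random.default_rng(42)
        p = rng.uniform(size=(10000, 4))
        out = COMBINERS[name](p)
        assert np.all((out >= 0) & (out <= 1))
        if name == "bonferroni_holm":
            for alpha in (0.01, 0.05, 0.1, 0.5):
                assert (out <= alpha).mean() <= alpha + 0.01
        else:
            assert stats.kstest(out, "uniform").pvalue > 0.01

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
        idx=st.integers(0, 3),
        delta=st.floats(0.001, 0.5),
        name=st.sampled_from(sorted(COMBINERS)),
    )
    def test_monotone_and_symmetric(self, p, idx, delta, name):
        fn = COMBINERS[name]
        base = fn([p])[0]
        bumped = list(p)
        bumped[idx] = min(1.0, bumped[idx] + delta)
        assert fn([bumped])[0] >= base - 1e-12
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(4))
        assert np.isclose(fn([[p[i] for i in perm]])[0], base, atol=1e-12)


class TestBH:
    def test_step_up_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_and_out_of_range(self):
        assert bh_adjust([0.3])[0] == 0.3
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    def test_never_below_raw_p_and_nan_excluded(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        out = bh_adjust(p)
        assert np.all(out >= p)
        with_nan = np.concatenate([p[:10], [np.nan], p[10:20]])
        out2 = bh_adjust(with_nan)
        assert np.isnan(out2[10])
        assert np.all(~np.isnan(np.delete(out2, 10)))


class TestCalling:
    def test_boundaries_inclusive(self):
        assert call_de([0.05], [1.0], 0.05, 1.0)[0]
        assert not call_de([0.051], [5.0], 0.05, 1.0)[0]
        assert call_de([0.01], [0.0], 0.05, 0.0)[0]

    def test_mean_log2fc_and_discordance(self):
        tables = {
            e: pd.DataFrame({"log2_fc": v}, index=["g1", "g2", "g3"])
            for e, v in zip(
                ["a", "b", "c", "d"],
                np.array([[1, 2, 1], [1, 0, -1], [1, 0, 1], [1, 0, -1]]).astype(float),
            )
        }
        out = mean_log2fc(tables)
        assert np.isclose(out.loc["g1", "mean_log2_fc"], 1.0)
        assert np.isclose(out.loc["g2", "mean_log2_fc"], 0.5)
        assert np.isclose(out.loc["g3", "mean_log2_fc"], 0.0)
        assert out.loc["g3", "discordance_count"] == 2
        assert out.loc["g1", "discordance_count"] == 0

    def test_max_p_definition_and_empty(self):
        def table(p, padj, lfc):
            return pd.DataFrame(
                {"p_value": p, "padj": padj, "log2_fc": lfc}, index=["g1", "g2"]
            )

        tables = {
            "e1": table([0.01, 0.001], [0.02, 0.002], [2, 3]),
            "e2": table([0.02, 0.01], [0.03, 0.02], [2, 3]),
            "e3": table([0.03, 0.5], [0.04, 0.6], [2, 3]),
            "e4": table([0.04, 0.001], [0.05, 0.002], [2, 3]),
        }
        out = max_p_intersect(tables, padj_thr=0.05, lfc_thr=1.0)
        assert list(out.index) == ["g1"]  # g2 missed by e3
        assert np.isclose(out.loc["g1", "p_max"], 0.04)
        none = {k: table([0.9, 0.9], [0.95, 0.95], [0, 0]) for k in tables}
        assert max_p_intersect(none).empty


class TestCombineAll:
    def _identical_tables(self):
        rng = np.random.default_rng(7)
        n = 300
        p = rng.uniform(size=n)
        genes = [f"g{i}" for i in range(n)]
        t = pd.DataFrame(
            {"p_value": p, "padj": bh_adjust(p), "log2_fc": rng.normal(size=n)},
            index=genes,
        )
        return {e: t.copy() for e in ["nb_exact", "voom_limma", "nb_wald", "score_test"]}

    def test_identical_engines_preserve_ranking(self):
        tables = self._identical_tables()
        out = combine_all(tables, combiners=["fisher", "stouffer", "tippett"])
        base_rank = tables["nb_exact"]["p_value"].rank()
        for name in ("fisher", "stouffer", "tippett"):
            assert (out[f"p_{name}"].rank() == base_rank).all()

    def test_uniform_inputs_give_uniform_combined(self):
        rng = np.random.default_rng(9)
        n = 10000
        genes = [f"g{i}" for i in range(n)]
        tables = {
            e: pd.DataFrame(
                {
                    "p_value": rng.uniform(size=n),
                    "padj": np.ones(n),
                    "log2_fc": np.zeros(n),
                },
                index=genes,
            )
            for e in ["nb_exact", "voom_limma", "nb_wald", "score_test"]
        }
        out = combine_all(tables, combiners=sorted(COMBINERS))
        for name in COMBINERS:
            if name == "bonferroni_holm":  # sub-uniform bound by construction
                assert (out[f"p_{name}"] <= 0.05).mean() <= 0.06
            else:
                assert stats.kstest(out[f"p_{name}"], "uniform").pvalue > 0.01

    def test_single_engine_gene_passes_through(self):
        tables = self._identical_tables()
        for e in ["voom_limma", "nb_wald", "score_test"]:
            tables[e].loc["g0", "p_value"] = np.nan
        out = combine_all(tables, combiners=["fisher"])
        assert np.isclose(out.loc["g0", "p_fisher"], tables["nb_exact"].loc["g0", "p_value"])
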