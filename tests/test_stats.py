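"""Correlations, regression, RM-ANOVA with sphericity correction, paired tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stereosim import (
    build_condition_table,
    correlate,
    fit_multiple_regression,
    load_fixture,
    paired_t_log,
    rm_anova_with_posthoc,
)
from stereosim._rng import substream


@pytest.fixture(scope="module")
def table3():
    return load_fixture("table3")


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_spearman_monotone_transform(self):
        x = np.linspace(1, 5, 12)
        res = correlate(x, np.exp(x), method="spearman")
        assert res.statistic == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        res = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate and math.isnan(res.statistic)

    def test_table3_regression_value(self, table3):
        """Frozen regression check on the packaged per-subject fixture."""
        res = correlate(np.log10(table3["cr"]), np.log10(table3["baseline"]))
        expected, _ = sps.pearsonr(np.log10(table3["cr"]), np.log10(table3["baseline"]))
        assert res.statistic == pytest.approx(float(expected))
        assert res.n == 7


class TestMultipleRegression:
    def test_noiseless_response_r2_one(self):
        rng = substream(0, "reg")
        x1, x2 = rng.normal(size=20), rng.normal(size=20)
        res = fit_multiple_regression(2 * x1 - x2 + 3, {"x1": x1, "x2": x2})
        assert res.r_squared == pytest.approx(1.0)

    def test_df_bookkeeping_single_predictor(self):
        rng = substream(1, "reg")
        x = rng.normal(size=14)
        res = fit_multiple_regression(x + rng.normal(scale=0.1, size=14), {"x": x})
        assert res.df == (1.0, 12.0)

    def test_collinear_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_multiple_regression(x, {"a": x, "b": 2 * x})

    def test_r_squared_invariant_to_predictor_rescaling(self):
        rng = substream(2, "reg")
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        y = x1 + 0.5 * x2 + rng.normal(size=30)
        r2a = fit_multiple_regression(y, {"x1": x1, "x2": x2}).r_squared
        r2b = fit_multiple_regression(y, {"x1": 100 * x1 + 7, "x2": -x2}).r_squared
        assert r2a == pytest.approx(r2b)


class TestRMAnova:
    def _matrix(self, n=12, k=4, effect=0.5, seed=0):
        rng = substream(seed, "anova")
        base = rng.normal(5.0, 1.0, n)[:, None]
        return pd.DataFrame(
            base + effect * np.arange(k)[None, :] + rng.normal(0, 0.4, (n, k)),
            columns=[f"c{j}" for j in range(k)],
        )

    def test_identical_conditions_f_zero(self):
        wide = pd.DataFrame(np.tile(np.arange(5.0)[:, None], (1, 3)), columns=list("abc"))
        anova, _ = rm_anova_with_posthoc(wide)
        assert anova.statistic == 0.0 and anova.p_value == 1.0

    def test_two_conditions_f_equals_t_squared(self):
        wide = self._matrix(k=2)
        anova, pairwise = rm_anova_with_posthoc(wide)
        t, _ = sps.ttest_rel(wide["c1"], wide["c0"])
        assert anova.statistic == pytest.approx(t * t)

    def test_gg_epsilon_bounds_and_fractional_dfs(self):
        wide = self._matrix(k=5)
        anova, _ = rm_anova_with_posthoc(wide)
        k = 5
        assert 1.0 / (k - 1) <= anova.epsilon <= 1.0
        assert anova.df[0] == pytest.approx(anova.epsilon * (k - 1))

    def test_bonferroni_adjustment(self):
        _, pairwise = rm_anova_with_posthoc(self._matrix(k=4, effect=0.2))
        m = len(pairwise)
        for _, row in pairwise.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, m * row["p_raw"]))
            assert row["p_bonferroni"] >= row["p_raw"] - 1e-15

    def test_missing_cells_rejected(self):
        wide = self._matrix().to_numpy()
        wide[2, 1] = np.nan
        with pytest.raises(ValueError):
            rm_anova_with_posthoc(wide, conditions=list("abcd"))

    def test_huynh_feldt_option(self):
        wide = self._matrix(k=4)
        gg, _ = rm_anova_with_posthoc(wide, correction="gg")
        hf, _ = rm_anova_with_posthoc(wide, correction="hf")
        assert hf.epsilon >= gg.epsilon - 1e-12


class TestPairedTLog:
    def test_identical_vectors(self):
        res = paired_t_log([40.0, 80.0], [40.0, 80.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_table3_frozen_p_value(self, table3):
        """Baseline versus CR-balanced thresholds of the seven amblyopic
        observers: the paired test on log10 values gives p = 0.005."""
        res = paired_t_log(table3["baseline"], table3["balanced_cr"])
        assert res.statistic == pytest.approx(4.3143, abs=5e-4)  # positive: thresholds improved
        assert res.df == 6.0
        assert round(res.p_value, 3) == 0.005

    def test_constant_ratio_degenerate(self):
        base = np.array([40.0, 80.0, 160.0])
        res = paired_t_log(base, base * 0.5)
        assert res.degenerate

    def test_scale_invariance(self):
        rng = substream(4, "pt")
        b = np.exp(rng.normal(3, 1, 10))
        t = b * np.exp(rng.normal(-0.2, 0.3, 10))
        r1, r2 = paired_t_log(b, t), paired_t_log(7.3 * b, 7.3 * t)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            paired_t_log([40.0, -1.0], [30.0, 20.0])


class TestConditionTable:
    def test_single_condition_equal_to_baseline(self):
        rng = substream(5, "ct")
        base = rng.normal(40, 5, 8)
        wide = pd.DataFrame({"baseline": base, "same": base})
        tab = build_condition_table(wide, baseline="baseline")
        assert tab.table.loc["same", "relative_change"] == 1.0
        assert not tab.table["significant"].any()

    def test_relative_change_from_printed_means(self):
        """Group means from the packaged tables reproduce the printed
        relative-change cells."""
        from stereosim import relative_change

        assert relative_change(1780.0, 40.0) == 44.5
        assert relative_change(9.84, 1.44) == 6.8

    def test_baseline_row_unflagged_and_unit(self):
        wide = self._effectful()
        tab = build_condition_table(wide, baseline="baseline")
        assert tab.table.loc["baseline", "relative_change"] == 1.0
        assert not tab.table.loc["baseline", "significant"]

    def test_strong_effect_flagged(self):
        tab = build_condition_table(self._effectful(), baseline="baseline")
        assert tab.table.loc["treated", "significant"]

    @staticmethod
    def _effectful():
        rng = substream(6, "ct")
        base = rng.normal(40, 4, 12)
        return pd.DataFrame(
            {
                "baseline": base,
                "mid": base + rng.normal(1.0, 2.0, 12),
                "treated": base * 2.2 + rng.normal(0, 2.0, 12),
            }
        )
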