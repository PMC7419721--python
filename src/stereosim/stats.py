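"""Group statistics for the simulated experiments and printed-table fixtures.

Wraps the field's standard machinery — scipy correlations and t-tests,
statsmodels OLS, pingouin repeated-measures ANOVA with Greenhouse–Geisser
sphericity correction (Huynh–Feldt behind a flag) — in the result containers
the rest of the pipeline consumes.  Paired comparisons on thresholds run on
log10 values; condition tables mirror the mean (SD) / relative-change layout
with significance flags from Bonferroni-corrected versus-baseline paired
tests at adjusted p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

from .scoring import relative_change

__all__ = [
    "StatResult",
    "ConditionTable",
    "correlate",
    "fit_multiple_regression",
    "rm_anova_with_posthoc",
    "paired_t_log",
    "build_condition_table",
]

PAIRWISE_FLAG_LEVEL = 0.01  # versus-baseline flags at Bonferroni-adjusted p < 0.01


@dataclass(frozen=True)
class StatResult:
    """One inferential result (correlation, regression, ANOVA or t-test).

    ``df`` is a single value for t-tests, a (df1, df2) pair for F-type
    results; ANOVA dfs may be fractional after sphericity correction.
    """

    kind: Literal["pearson", "spearman", "regression", "rm_anova", "paired_t"]
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    n: int
    r_squared: Optional[float] = None
    coef_table: Optional[pd.DataFrame] = None
    epsilon: Optional[float] = None
    degenerate: bool = False


@dataclass(frozen=True)
class ConditionTable:
    """Per-condition mean, SD, relative change from baseline and significance
    flag (Bonferroni-corrected paired comparison versus baseline)."""

    table: pd.DataFrame  # index: condition; columns: mean, sd, relative_change, significant
    baseline: str
    anova: Optional[StatResult] = None
    pairwise: Optional[pd.DataFrame] = None  # per-condition raw and adjusted p


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> StatResult:
    """Pearson or Spearman correlation with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    degenerate = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
    if degenerate:
        return StatResult(method, float("nan"), float(x.size - 2), float("nan"), x.size, degenerate=True)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
        r, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(method, float(r), float(x.size - 2), float(p), x.size)


def fit_multiple_regression(
    response: Sequence[float],
    predictors: pd.DataFrame | dict[str, Sequence[float]],
) -> StatResult:
    """OLS of the response on the named predictors (with intercept).

    Returns the overall F with its dfs, R², and a per-coefficient table of
    estimates and two-sided p values.  An exactly collinear design is
    rejected with a diagnostic rather than silently dropped.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(response, dtype=float)
    if len(X) != y.size:
        raise ValueError("response and predictors must have equal length")
    if y.size <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"collinear design matrix (rank-deficient): columns {list(design.columns)}")
    fit = sm.OLS(y, design).fit()
    coef = pd.DataFrame({"estimate": fit.params, "p": fit.pvalues})
    return StatResult(
        kind="regression",
        statistic=float(fit.fvalue),
        df=(float(fit.df_model), float(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        n=int(y.size),
        r_squared=float(fit.rsquared),
        coef_table=coef,
    )


def _as_wide(measurements: pd.DataFrame | np.ndarray, conditions: Sequence[str] | None) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        wide = measurements.copy()
    else:
        arr = np.asarray(measurements, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expect a subject x condition matrix")
        cols = list(conditions) if conditions is not None else [f"c{j}" for j in range(arr.shape[1])]
        wide = pd.DataFrame(arr, columns=cols)
    if wide.isna().any().any():
        raise ValueError("missing cells are not supported (no imputation)")
    if wide.shape[1] < 2 or wide.shape[0] < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    return wide


def rm_anova_with_posthoc(
    measurements: pd.DataFrame | np.ndarray,
    baseline: str | None = None,
    conditions: Sequence[str] | None = None,
    correction: Literal["gg", "hf"] = "gg",
) -> tuple[StatResult, pd.DataFrame]:
    """One-way repeated-measures ANOVA plus versus-baseline pairwise tests.

    The F statistic is reported with sphericity-corrected (fractional) dfs —
    Greenhouse–Geisser by default, Huynh–Feldt optionally.  Pairwise paired t
    tests compare each condition with the baseline column (the first column
    when unspecified); Bonferroni adjustment multiplies by the number of
    versus-baseline comparisons, and flags are set at adjusted p < 0.01.
    """
    wide = _as_wide(measurements, conditions)
    baseline = baseline if baseline is not None else wide.columns[0]
    if baseline not in wide.columns:
        raise ValueError(f"baseline {baseline!r} not among conditions {list(wide.columns)}")

    k = wide.shape[1]
    arr = wide.to_numpy()
    if np.allclose(arr, arr[:, [0]]):
        # all-identical conditions: F degenerates to 0 (pingouin cannot
        # produce a statistic from zero between-condition variance)
        f_val, eps, p = 0.0, 1.0, 1.0
        df1, df2 = float(k - 1), float((k - 1) * (wide.shape[0] - 1))
    else:
        long = wide.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="value"
        )
        aov = pg.rm_anova(
            data=long, dv="value", within="condition", subject="subject", correction=True
        ).iloc[0]
        eps = float(aov["eps"]) if k > 2 else 1.0
        if correction == "hf" and k > 2:
            eps = float(pg.epsilon(wide, correction="hf"))
            eps = min(eps, 1.0)
        f_val = float(aov["F"])
        df1 = eps * float(aov["ddof1"])
        df2 = eps * float(aov["ddof2"])
        p = float(sps.f.sf(f_val, df1, df2)) if k > 2 else float(aov["p_unc"])
    anova = StatResult("rm_anova", f_val, (df1, df2), p, wide.shape[0], epsilon=eps)

    others = [c for c in wide.columns if c != baseline]
    m = len(others)
    rows = []
    for cond in others:
        diffs = wide[cond] - wide[baseline]
        if float(np.ptp(diffs)) < 1e-12:
            t_val, p_raw = (0.0, 1.0) if float(diffs.iloc[0]) == 0.0 else (float("nan"), float("nan"))
        else:
            t_val, p_raw = sps.ttest_rel(wide[cond], wide[baseline])
        p_adj = min(1.0, m * p_raw) if np.isfinite(p_raw) else float("nan")
        rows.append(
            {
                "condition": cond,
                "t": float(t_val),
                "df": wide.shape[0] - 1,
                "p_raw": float(p_raw),
                "p_bonferroni": p_adj,
                "significant": bool(np.isfinite(p_adj) and p_adj < PAIRWISE_FLAG_LEVEL),
            }
        )
    return anova, pd.DataFrame(rows).set_index("condition")


def paired_t_log(baseline: Sequence[float], treated: Sequence[float]) -> StatResult:
    """Paired t-test on log10 thresholds (arcsec), two-sided.

    A zero-variance difference vector (e.g. treated = baseline * constant) is
    degenerate for the t statistic and is flagged rather than reported as an
    inferential result.
    """
    b = np.asarray(baseline, dtype=float)
    t = np.asarray(treated, dtype=float)
    if b.shape != t.shape:
        raise ValueError("paired vectors must have equal length")
    if np.any(b <= 0) or np.any(t <= 0):
        raise ValueError("thresholds must be positive for the log transform")
    d = np.log10(t) - np.log10(b)
    n = b.size
    if float(np.ptp(d)) < 1e-12:
        if d[0] == 0.0:
            return StatResult("paired_t", 0.0, float(n - 1), 1.0, n)
        return StatResult("paired_t", float("nan"), float(n - 1), float("nan"), n, degenerate=True)
    t_val, p = sps.ttest_rel(np.log10(b), np.log10(t))
    return StatResult("paired_t", float(t_val), float(n - 1), float(p), n)


def build_condition_table(
    measurements: pd.DataFrame | np.ndarray,
    baseline: str | None = None,
    conditions: Sequence[str] | None = None,
    correction: Literal["gg", "hf"] = "gg",
) -> ConditionTable:
    """Group condition table: mean (SD), relative change and versus-baseline
    significance flags from the repeated-measures procedure."""
    wide = _as_wide(measurements, conditions)
    baseline = baseline if baseline is not None else wide.columns[0]
    anova, pairwise = rm_anova_with_posthoc(wide, baseline=baseline, correction=correction)
    means = wide.mean(axis=0)
    sds = wide.std(axis=0, ddof=1)
    rows = []
    for cond in wide.columns:
        rows.append(
            {
                "condition": cond,
                "mean": float(means[cond]),
                "sd": float(sds[cond]),
                "relative_change": relative_change(float(means[cond]), float(means[baseline])),
                "significant": bool(pairwise["significant"].get(cond, False)),
            }
        )
    table = pd.DataFrame(rows).set_index("condition")
    return ConditionTable(table=table, baseline=baseline, anova=anova, pairwise=pairwise)
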