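"""Maximum-likelihood psychometric fitting.

Stereo sessions are fit with a cumulative normal on a base-2 log disparity
axis with the guess rate fixed at 0.25 (4AFC) and the lapse rate fixed (free
lapses are not identifiable from <= 140 staircase trials).  The stereo
threshold is the disparity at which the *full* fitted curve crosses 62.5%
correct — the midpoint between chance and perfect performance — so the
criterion holds verbatim even with a nonzero lapse.  Trials from both
interleaved staircases are pooled into one binomial likelihood.

The contrast-ratio task is fit the same way on a log10 ratio axis: the CR is
the 50% point of the probability of reporting the nondominant eye's letter.

A brute-force grid-search fitter is provided as an independent oracle for the
optimizer; it is used by the test suite, never by the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .observers import DISPARITY_RANGE
from .staircase import SessionResult, TrialRecord

__all__ = [
    "ThresholdEstimate",
    "CREstimate",
    "DegenerateDataError",
    "fit_stereo_threshold",
    "fit_stereo_threshold_oracle",
    "estimate_cr",
]

GAMMA_4AFC = 0.25
CRITERION = 0.625
ALPHA_BOUNDS = (math.log2(0.5), math.log2(8192.0))  # (-1, 13)
BETA_BOUNDS = (0.1, 8.0)
_MIN_TRIALS = 20
_EPS = 1e-9


class DegenerateDataError(ValueError):
    """Raised when the data cannot constrain a psychometric fit."""


@dataclass(frozen=True)
class ThresholdEstimate:
    """Fitted stereo psychometric function and its 62.5%-correct threshold.

    ``threshold`` is in arcsec and is NaN when ``measurable`` is False (no
    62.5% crossing inside [1, 4096] arcsec, an out-of-bound optimum, or a
    failed optimization).
    """

    threshold: float
    alpha: float
    beta: float
    lambda_used: float
    n_trials: int
    log_likelihood: float
    converged: bool
    measurable: bool

    def percent_correct(self, log2_disparity):
        z = (np.asarray(log2_disparity, dtype=float) - self.alpha) / self.beta
        p = GAMMA_4AFC + (1.0 - GAMMA_4AFC - self.lambda_used) * ndtr(z)
        return float(p) if np.isscalar(log2_disparity) else p


@dataclass(frozen=True)
class CREstimate:
    cr: float
    sigma: float
    n_trials: int
    log_likelihood: float
    converged: bool


def _pool_trials(trials: Iterable[TrialRecord] | SessionResult) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(trials, SessionResult):
        trials = trials.trials
    recs = list(trials)
    if len(recs) < _MIN_TRIALS:
        raise DegenerateDataError(f"need at least {_MIN_TRIALS} trials, got {len(recs)}")
    x = np.log2([t.disparity for t in recs])
    y = np.array([t.correct for t in recs], dtype=float)
    levels, inverse = np.unique(np.round(x, 12), return_inverse=True)
    if levels.size < 2:
        raise DegenerateDataError("trials span a single disparity; fit is unconstrained")
    n = np.bincount(inverse).astype(float)
    k = np.bincount(inverse, weights=y)
    return levels, n, k


def _binom_nll(x: np.ndarray, n: np.ndarray, k: np.ndarray, alpha, beta, gamma: float, lapse: float):
    """Negative binomial log-likelihood; alpha/beta may be arrays (broadcast)."""
    a = np.asarray(alpha, dtype=float)[..., None]
    b = np.asarray(beta, dtype=float)[..., None]
    p = gamma + (1.0 - gamma - lapse) * ndtr((x - a) / b)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    ll = k * np.log(p) + (n - k) * np.log1p(-p)
    return -ll.sum(axis=-1)


def _threshold_from(alpha: float, beta: float, lapse: float) -> float:
    pc = (CRITERION - GAMMA_4AFC) / (1.0 - GAMMA_4AFC - lapse)
    return float(2.0 ** (alpha + beta * norm.ppf(pc)))


def _finalize(alpha: float, beta: float, lapse: float, n_trials: int, nll: float, converged: bool) -> ThresholdEstimate:
    thr = _threshold_from(alpha, beta, lapse)
    lo, hi = DISPARITY_RANGE
    interior = (
        ALPHA_BOUNDS[0] + 1e-6 < alpha < ALPHA_BOUNDS[1] - 1e-6
        and beta < BETA_BOUNDS[1] - 1e-6
    )
    measurable = bool(converged and interior and lo <= thr <= hi)
    return ThresholdEstimate(
        threshold=thr if measurable else float("nan"),
        alpha=alpha,
        beta=beta,
        lambda_used=lapse,
        n_trials=n_trials,
        log_likelihood=-nll,
        converged=converged,
        measurable=measurable,
    )


def fit_stereo_threshold(
    trials: Iterable[TrialRecord] | SessionResult,
    lambda_fixed: float = 0.01,
) -> ThresholdEstimate:
    """Binomial MLE of (alpha, beta) with gamma = 0.25 and the lapse fixed.

    Multi-start L-BFGS-B over bounded (alpha, beta); the threshold is where
    the fitted curve crosses 62.5% correct.  ``measurable`` is False when the
    crossing falls outside [1, 4096] arcsec or the optimum hits a bound
    (e.g. responses at chance everywhere push alpha to its ceiling).
    """
    x, n, k = _pool_trials(trials)
    n_trials = int(n.sum())

    def nll(theta):
        return float(_binom_nll(x, n, k, theta[0], theta[1], GAMMA_4AFC, lambda_fixed))

    # coarse NLL scan picks the start basins (the surface is multimodal when a
    # sharp-step solution competes with a shallow one)
    a_scan = np.arange(ALPHA_BOUNDS[0], ALPHA_BOUNDS[1] + 1e-9, 0.25)
    b_scan = np.array([0.12, 0.3, 0.7, 1.5, 3.0, 6.0])
    A, B = np.meshgrid(a_scan, b_scan, indexing="ij")
    scan = _binom_nll(x, n, k, A.ravel(), B.ravel(), GAMMA_4AFC, lambda_fixed)
    order = np.argsort(scan)
    starts = [(float(A.ravel()[i]), float(B.ravel()[i])) for i in order[:4]]
    spread = max(0.5, float(x.max() - x.min()) / 4.0)
    starts += [(float(np.average(x, weights=n)), spread), (float(x.max()), 2.0)]
    best = None
    for s in starts:
        res = minimize(
            nll,
            x0=np.clip(s, (ALPHA_BOUNDS[0], BETA_BOUNDS[0]), (ALPHA_BOUNDS[1], BETA_BOUNDS[1])),
            method="L-BFGS-B",
            bounds=[ALPHA_BOUNDS, BETA_BOUNDS],
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = float(best.x[0]), float(best.x[1])
    return _finalize(alpha, beta, lambda_fixed, n_trials, float(best.fun), bool(best.success))


def fit_stereo_threshold_oracle(
    trials: Iterable[TrialRecord] | SessionResult,
    lambda_fixed: float = 0.01,
    alpha_grid: Sequence[float] | None = None,
    beta_grid: Sequence[float] | None = None,
) -> ThresholdEstimate:
    """Exhaustive grid-search MLE over (alpha, beta) — the independent oracle.

    Deliberately avoids any iterative optimizer so it can cross-check
    :func:`fit_stereo_threshold`; not intended for pipeline use.
    """
    x, n, k = _pool_trials(trials)
    if alpha_grid is None:
        alpha_grid = np.arange(ALPHA_BOUNDS[0], ALPHA_BOUNDS[1] + 1e-9, 0.02)
    if beta_grid is None:
        beta_grid = np.arange(BETA_BOUNDS[0], 4.0 + 1e-9, 0.02)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if alpha_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("empty parameter grid")
    A, B = np.meshgrid(alpha_grid, beta_grid, indexing="ij")
    nll = _binom_nll(x, n, k, A.ravel(), B.ravel(), GAMMA_4AFC, lambda_fixed)
    # chance-level data produce a flat ridge whose MLE limit runs off to
    # alpha -> +inf; break near-ties toward the largest alpha so that limit
    # lands on the grid edge (and is then reported unmeasurable)
    ties = np.flatnonzero(nll <= nll.min() + 1e-9)
    i = int(ties[np.argmax(A.ravel()[ties])])
    alpha, beta = float(A.ravel()[i]), float(B.ravel()[i])
    est = _finalize(alpha, beta, lambda_fixed, int(n.sum()), float(nll[i]), converged=True)
    if est.measurable:
        # grid edges mean the optimum was not bracketed
        on_edge = alpha in (alpha_grid[0], alpha_grid[-1]) or beta == beta_grid[-1]
        if on_edge:
            est = ThresholdEstimate(
                float("nan"), alpha, beta, lambda_fixed, est.n_trials,
                est.log_likelihood, True, False,
            )
    return est


def estimate_cr(
    letter_trials: Sequence[tuple[float, bool]],
    sigma_bounds: tuple[float, float] = (0.02, 1.5),
    mu_bounds: tuple[float, float] = (-2.5, 2.5),
) -> CREstimate:
    """MLE cumulative-normal fit of P(report nondominant) vs log10 ratio.

    The CR estimate is the fitted 50% balance point, ``10**mu``.  One-sided
    data (every report identical) cannot constrain the balance point and
    yield ``converged = False``.
    """
    if len(letter_trials) < _MIN_TRIALS:
        raise DegenerateDataError(f"need at least {_MIN_TRIALS} trials, got {len(letter_trials)}")
    ratios = np.array([r for r, _ in letter_trials], dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("presented ratios must be positive")
    x = np.log10(ratios)
    if np.unique(np.round(x, 12)).size < 2:
        raise DegenerateDataError("trials span a single ratio; fit is unconstrained")
    y = np.array([bool(f) for _, f in letter_trials], dtype=float)
    n_trials = len(letter_trials)
    if y.min() == y.max():
        return CREstimate(float("nan"), float("nan"), n_trials, float("nan"), converged=False)

    def nll(theta):
        p = np.clip(ndtr((x - theta[0]) / theta[1]), _EPS, 1.0 - _EPS)
        return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())

    best = None
    for mu0 in (float(np.median(x)), 0.0):
        for s0 in (0.1, 0.3):
            res = minimize(
                nll, x0=(mu0, s0), method="L-BFGS-B", bounds=[mu_bounds, sigma_bounds]
            )
            if best is None or res.fun < best.fun:
                best = res
    mu, sigma = float(best.x[0]), float(best.x[1])
    interior = mu_bounds[0] + 1e-6 < mu < mu_bounds[1] - 1e-6
    converged = bool(best.success and interior)
    return CREstimate(
        cr=10.0**mu if converged else float("nan"),
        sigma=sigma,
        n_trials=n_trials,
        log_likelihood=-float(best.fun),
        converged=converged,
    )
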