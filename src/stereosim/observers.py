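"""Generative model of dichoptic observers.

The package's synthetic data come from a simulated observer with three linked
components:

* a 4AFC stereo psychometric function — cumulative normal on a log2 disparity
  (arcsec) axis with guess rate 0.25 and a small lapse rate;
* a dichoptic-letter report function — cumulative normal on a log10
  contrast-ratio axis whose 50% point is the observer's contrast ratio (CR),
  the standard interocular-suppression measure (CR = 1 means balanced eyes,
  larger means the nondominant eye needs proportionally more contrast);
* a contrast-imbalance mechanism that couples the two: stereo thresholds rise
  when the presented interocular contrast deviates from the observer's
  *balance point*.

The balance point ``b`` is 1 for normally-sighted observers (any reduction of
the dominant eye's stimulus contrast elevates the stereo threshold, at
``kappa`` log10 units per 10% contrast decrement) and equals ``cr_true`` for
amblyopic observers (their nondominant eye is suppressed, so presenting the
dominant eye at ``1/CR`` of the nondominant contrast *neutralizes* the
suppression and releases ``kappa_release * log10(CR)`` log10 units of
threshold elevation).  Observers are defined so that ``stereo.alpha`` is the
threshold location *at equal presented contrast*, i.e. with the suppression
penalty included; rebalancing can therefore only lower the effective
threshold of an amblyope, and attenuating a normal observer's dominant eye can
only raise it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

from ._rng import substream

__all__ = [
    "PsychometricParams",
    "SimulatedObserver",
    "BangerterEffect",
    "BANGERTER_DEFAULTS",
    "TruncatedDist",
    "CohortSpec",
    "stereo_percent_correct",
    "cr_report_probability",
    "simulate_trial",
    "apply_bangerter",
    "sample_cohort",
    "true_threshold",
]

LOG2_10 = math.log2(10.0)

DISPARITY_RANGE = (1.0, 4096.0)  # arcsec
CONTRAST_RANGE = (1.0, 100.0)  # percent Michelson


@dataclass(frozen=True)
class PsychometricParams:
    """Cumulative-normal psychometric function on a log2-arcsec axis.

    alpha : threshold location (log2 arcsec)
    beta : spread in octaves
    gamma : guess rate, fixed at 0.25 for the 4AFC stereo task
    lapse : lapse rate
    """

    alpha: float
    beta: float
    gamma: float = 0.25
    lapse: float = 0.01

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError(f"lapse must be in [0, 0.1], got {self.lapse}")
        if not self.gamma + self.lapse < 1.0:
            raise ValueError("gamma + lapse must be < 1")

    def percent_correct(self, log2_disparity) -> np.ndarray | float:
        z = (np.asarray(log2_disparity, dtype=float) - self.alpha) / self.beta
        p = self.gamma + (1.0 - self.gamma - self.lapse) * ndtr(z)
        return float(p) if np.isscalar(log2_disparity) else p


@dataclass(frozen=True)
class SimulatedObserver:
    """Ground-truth observer for the stereo and dichoptic-letter tasks.

    kappa : imbalance sensitivity, log10 threshold-elevation units per 10%
        contrast decrement away from the balance point.
    kappa_release : suppression-release sensitivity, log10 threshold units
        recovered per log10 unit of neutralized suppression (amblyopes only;
        inert when the balance point is 1).
    cr_true : dichoptic-letter balance ratio (>= 1; nondominant/dominant).
    sigma_cr : spread of the letter-report function on log10 ratio axis.
    """

    stereo: PsychometricParams
    kappa: float = 0.35
    cr_true: float = 1.0
    sigma_cr: float = 0.2
    kappa_release: float = 0.2
    va_dominant: float = 0.0
    va_nondominant: float = 0.0
    group: Literal["normal", "amblyopic"] = "normal"

    def __post_init__(self) -> None:
        if self.cr_true < 1.0:
            raise ValueError(f"cr_true must be >= 1 (dominance convention), got {self.cr_true}")
        if self.kappa < 0 or self.kappa_release < 0:
            raise ValueError("kappa and kappa_release must be nonnegative")
        if self.sigma_cr <= 0:
            raise ValueError("sigma_cr must be positive")
        for va in (self.va_dominant, self.va_nondominant):
            if not -0.3 <= va <= 1.5:
                raise ValueError(f"VA (logMAR) must lie in [-0.3, 1.5], got {va}")
        if self.group not in ("normal", "amblyopic"):
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def stereo_balance(self) -> float:
        """Presented contrast ratio (nondominant/dominant) at which the
        stereo system is internally balanced: 1 for normals, CR for amblyopes."""
        return self.cr_true if self.group == "amblyopic" else 1.0

    @property
    def va_difference(self) -> float:
        return abs(self.va_nondominant - self.va_dominant)


def _validate_stimulus(disparity: float, contrast_dominant: float, contrast_nondominant: float) -> None:
    lo, hi = DISPARITY_RANGE
    if not lo <= disparity <= hi:
        raise ValueError(f"disparity must lie in [{lo:g}, {hi:g}] arcsec, got {disparity}")
    clo, chi = CONTRAST_RANGE
    for name, c in (("contrast_dominant", contrast_dominant), ("contrast_nondominant", contrast_nondominant)):
        if not clo <= c <= chi:
            raise ValueError(f"{name} must lie in [{clo:g}, {chi:g}] percent, got {c}")


def effective_alpha(observer: SimulatedObserver, contrast_dominant: float, contrast_nondominant: float) -> float:
    """Threshold location (log2 arcsec) under a presented contrast pair.

    With balance point ``b`` and presented ratio ``rho = c_nd / c_d``::

        alpha_eff = alpha
                    + kappa * max(0, c_nd / b - c_d) / 10 * log2(10)
                    + kappa_release * (max(0, log10 b - log10 rho) - log10 b) * log2(10)

    For ``b = 1`` this reduces to the plain penalty
    ``kappa * max(0, c_nd - c_d) / 10`` log10 units (equal contrast is the
    optimum).  For an amblyope (``b = cr_true``) the stored ``alpha`` already
    contains the full suppression penalty ``kappa_release * log10(b)``;
    presenting the dominant eye at reduced contrast releases it, with the
    minimum effective threshold reached exactly at ``rho = b``.
    """
    b = observer.stereo_balance
    rho = contrast_nondominant / contrast_dominant
    imbalance = max(0.0, contrast_nondominant / b - contrast_dominant)  # percent
    residual_suppression = max(0.0, math.log10(b) - math.log10(rho))
    shift_log10 = (
        observer.kappa * imbalance / 10.0
        + observer.kappa_release * (residual_suppression - math.log10(b))
    )
    return observer.stereo.alpha + shift_log10 * LOG2_10


def stereo_percent_correct(
    observer: SimulatedObserver,
    disparity: float,
    contrast_dominant: float = 80.0,
    contrast_nondominant: float = 80.0,
):
    """Probability of a correct 4AFC response at a disparity (arcsec).

    Monotone nondecreasing in disparity; at equal presented contrast it is the
    observer's baseline function, and contrast imbalance shifts the threshold
    per :func:`effective_alpha`.
    """
    d = np.asarray(disparity, dtype=float)
    scalar = d.ndim == 0
    for di in np.atleast_1d(d):
        _validate_stimulus(float(di), contrast_dominant, contrast_nondominant)
    a_eff = effective_alpha(observer, contrast_dominant, contrast_nondominant)
    ps = observer.stereo
    p = ps.gamma + (1.0 - ps.gamma - ps.lapse) * ndtr((np.log2(d) - a_eff) / ps.beta)
    return float(p) if scalar else p


def true_threshold(
    observer: SimulatedObserver,
    contrast_dominant: float = 80.0,
    contrast_nondominant: float = 80.0,
    criterion: float = 0.625,
) -> float:
    """Model-implied threshold (arcsec) at the criterion percent-correct.

    May fall outside the measurable [1, 4096] arcsec range; callers decide how
    to treat that (the session machinery reports such runs as unmeasurable).
    """
    ps = observer.stereo
    pc = (criterion - ps.gamma) / (1.0 - ps.gamma - ps.lapse)
    if not 0.0 < pc < 1.0:
        raise ValueError(f"criterion {criterion} unreachable for this observer")
    a_eff = effective_alpha(observer, contrast_dominant, contrast_nondominant)
    return float(2.0 ** (a_eff + ps.beta * norm.ppf(pc)))


def cr_report_probability(observer: SimulatedObserver, presented_ratio: float):
    """Probability the nondominant eye's letter is reported when the letters
    are presented at contrast ratio ``presented_ratio`` (nondominant/dominant).

    The 50% point sits at ``cr_true`` by construction; the function is
    strictly increasing in the presented ratio.
    """
    r = np.asarray(presented_ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError(f"presented_ratio must be positive, got {presented_ratio}")
    p = ndtr((np.log10(r) - math.log10(observer.cr_true)) / observer.sigma_cr)
    return float(p) if r.ndim == 0 else p


def simulate_trial(
    observer: SimulatedObserver,
    disparity: float,
    contrast_pair: tuple[float, float],
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli 4AFC stereo trial; ``contrast_pair`` is (dominant, nondominant)."""
    c_dom, c_nd = contrast_pair
    p = stereo_percent_correct(observer, disparity, c_dom, c_nd)
    return bool(rng.random() < p)


# --------------------------------------------------------------------------
# Bangerter-filter degradation (phenomenological)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BangerterEffect:
    """Phenomenological effect of one Bangerter filter on the dominant eye.

    va_decrement is added to the filtered eye's logMAR acuity; cr_multiplier
    scales the letter-task balance ratio; stereo_multiplier scales the
    equal-contrast stereo threshold (arcsec).
    """

    filter_label: str
    va_decrement: float
    cr_multiplier: float
    stereo_multiplier: float

    def __post_init__(self) -> None:
        if self.va_decrement < 0:
            raise ValueError("va_decrement must be >= 0")
        if self.cr_multiplier < 1 or self.stereo_multiplier < 1:
            raise ValueError("multipliers must be >= 1")


#: Default per-filter effects, from the group relative-change columns of the
#: degradation experiment (filters in increasing density order; effects are
#: nondecreasing with density).  va_decrement is the group-mean interocular VA
#: difference under the filter minus its baseline value.
BANGERTER_DEFAULTS: dict[str, BangerterEffect] = {
    "0.8": BangerterEffect("0.8", 0.10, 1.0, 1.0),
    "0.6": BangerterEffect("0.6", 0.27, 1.3, 1.0),
    "0.4": BangerterEffect("0.4", 0.46, 1.7, 1.2),
    "0.1": BangerterEffect("0.1", 0.52, 2.5, 1.2),
    "<0.1": BangerterEffect("<0.1", 0.95, 6.8, 2.2),
}


def apply_bangerter(observer: SimulatedObserver, effect: BangerterEffect | str) -> SimulatedObserver:
    """Return a copy of a normal observer degraded by a Bangerter filter.

    The filter sits before the dominant (filtered) eye: its acuity drops by
    ``va_decrement``, the balance ratio is multiplied by ``cr_multiplier`` and
    the equal-contrast stereo threshold by ``stereo_multiplier``.  The input
    observer is unchanged.
    """
    if isinstance(effect, str):
        try:
            effect = BANGERTER_DEFAULTS[effect]
        except KeyError:
            raise ValueError(
                f"unknown filter label {effect!r}; known: {sorted(BANGERTER_DEFAULTS)}"
            ) from None
    if observer.group != "normal":
        raise ValueError("Bangerter degradation applies to normal-group observers only")
    stereo = replace(observer.stereo, alpha=observer.stereo.alpha + math.log2(effect.stereo_multiplier))
    return replace(
        observer,
        stereo=stereo,
        va_dominant=observer.va_dominant + effect.va_decrement,
        cr_true=observer.cr_true * effect.cr_multiplier,
    )


# --------------------------------------------------------------------------
# Cohort sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncatedDist:
    """Truncated sampling family parameterized by arithmetic mean/SD.

    family "lognormal": moment-matched lognormal truncated to [lower, upper]
    (used for CR and thresholds — strictly positive, right-skewed).
    family "normal": normal truncated to [lower, upper] (used for VA
    differences).  Sampling is by inverse-CDF so a given generator state maps
    to exactly one draw.
    """

    family: Literal["lognormal", "normal"]
    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("truncation bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError(f"empty truncation interval [{self.lower}, {self.upper}]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.family == "lognormal" and (self.mean <= 0 or self.lower <= 0):
            raise ValueError("lognormal family needs positive mean and lower bound")

    def _norm_params(self) -> tuple[float, float, float, float]:
        if self.family == "lognormal":
            s2 = math.log1p((self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - s2 / 2.0
            sigma = math.sqrt(s2)
            lo, hi = math.log(self.lower), math.log(self.upper)
        else:
            mu, sigma = self.mean, self.sd
            lo, hi = self.lower, self.upper
        return mu, sigma, lo, hi

    def sample(self, rng: np.random.Generator, size: int | None = None):
        mu, sigma, lo, hi = self._norm_params()
        a, b = norm.cdf(lo, mu, sigma), norm.cdf(hi, mu, sigma)
        u = rng.uniform(a, b, size=size)
        x = norm.ppf(u, mu, sigma)
        if self.family == "lognormal":
            x = np.exp(x)
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class CohortSpec:
    """Generative recipe for a cohort of simulated observers.

    The defaults (see :meth:`normal` / :meth:`amblyopic`) are calibrated to
    the study populations: normals with CR near 1.45 +/- 0.33 in [1.03, 2.19],
    equal-contrast thresholds near 40 +/- 14 arcsec in [15, 73] and interocular
    VA differences <= 0.10 logMAR; amblyopes with CR 9.62 +/- 11.27 in
    [1.29, 39.16], VA differences 0.36 +/- 0.30 in [0.02, 0.96] and thresholds
    generated from CR (suppression-linked) so that deep suppressors range up to
    and beyond the 4096-arcsec measurable ceiling.
    """

    n: int
    group: Literal["normal", "amblyopic"]
    cr: TruncatedDist
    va_diff: TruncatedDist
    seed: int = 0
    # normal group: threshold drawn directly (arcsec)
    threshold: TruncatedDist | None = None
    # amblyopic group: log2 threshold = log2(thr_at_cr_floor) +
    #   thr_slope * (log10 cr - log10 cr.lower) + N(0, thr_noise_octaves)
    thr_at_cr_floor: float = 40.0
    thr_slope: float = 4.2
    thr_noise_octaves: float = 0.9
    beta: TruncatedDist = field(
        default=TruncatedDist("lognormal", 1.0, 0.25, 0.4, 2.5)
    )
    kappa: float = 0.35
    kappa_release: TruncatedDist = field(
        default=TruncatedDist("lognormal", 0.2, 0.12, 0.02, 0.8)
    )
    sigma_cr: float = 0.2
    lapse: float = 0.01

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.group == "normal" and self.threshold is None:
            raise ValueError("normal cohort needs a threshold distribution")

    @classmethod
    def normal(cls, n: int = 19, seed: int = 0) -> "CohortSpec":
        return cls(
            n=n,
            group="normal",
            cr=TruncatedDist("lognormal", 1.45, 0.33, 1.03, 2.19),
            va_diff=TruncatedDist("normal", 0.02, 0.04, 0.0, 0.10),
            threshold=TruncatedDist("lognormal", 40.0, 14.0, 15.0, 73.0),
            seed=seed,
        )

    @classmethod
    def amblyopic(cls, n: int = 21, seed: int = 0) -> "CohortSpec":
        return cls(
            n=n,
            group="amblyopic",
            cr=TruncatedDist("lognormal", 9.62, 11.27, 1.29, 39.16),
            va_diff=TruncatedDist("normal", 0.36, 0.30, 0.02, 0.96),
            sigma_cr=0.25,
            seed=seed,
        )


def sample_cohort(spec: CohortSpec) -> list[SimulatedObserver]:
    """Draw ``spec.n`` observers; per-observer substreams are derived from the
    cohort seed by index, so cohorts replay exactly and grow stably with n.

    Amblyopic thresholds are suppression-linked (log-linear in log10 CR plus
    noise) while the VA difference is drawn independently, so across a cohort
    the stereo threshold correlates strongly with CR and only weakly with the
    acuity deficit.
    """
    observers: list[SimulatedObserver] = []
    for i in range(spec.n):
        rng = substream(spec.seed, "cohort", spec.group, i)
        cr = float(spec.cr.sample(rng))
        va_diff = float(spec.va_diff.sample(rng))
        beta = float(spec.beta.sample(rng))
        k_rel = float(spec.kappa_release.sample(rng))
        if spec.group == "normal":
            alpha = math.log2(float(spec.threshold.sample(rng)))
            va_dom = float(np.clip(rng.normal(-0.05, 0.08), -0.3, 0.1))
        else:
            alpha = (
                math.log2(spec.thr_at_cr_floor)
                + spec.thr_slope * (math.log10(cr) - math.log10(spec.cr.lower))
                + rng.normal(0.0, spec.thr_noise_octaves)
            )
            va_dom = float(np.clip(rng.normal(0.0, 0.10), -0.3, 0.5))
        observers.append(
            SimulatedObserver(
                stereo=PsychometricParams(alpha=alpha, beta=beta, lapse=spec.lapse),
                kappa=spec.kappa,
                cr_true=cr,
                sigma_cr=spec.sigma_cr,
                kappa_release=k_rel,
                va_dominant=va_dom,
                va_nondominant=va_dom + va_diff,
                group=spec.group,
            )
        )
    return observers
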