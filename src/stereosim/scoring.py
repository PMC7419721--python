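"""Derived clinical measures and contrast rebalancing.

* BF score: ordinal binocular-function rank — log10 of the best graded
  stereo level (1.6 for 40 arcsec up to 3.3 for 2000 arcsec), 4 for fusion
  without measurable stereo, 5 for suppression without stereo.
* Relative change: condition mean / baseline mean, reported to one decimal
  (round-half-to-even), the convention used by the group condition tables.
* Contrast rebalancing: given a measured CR, set the dominant eye's stimulus
  contrast so the presented nondominant/dominant ratio equals CR (or CR
  scaled by +/-25%), neutralizing suppression.  The nondominant eye stays at
  the 80% baseline contrast; the dominant eye is attenuated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

__all__ = [
    "BinocularOutcome",
    "ContrastCondition",
    "bf_score",
    "relative_change",
    "rebalance_contrasts",
    "REBALANCE_VARIANTS",
]

_RPST_RANGE = (40.0, 2000.0)


@dataclass(frozen=True)
class BinocularOutcome:
    """Clinical binocular-function outcome: best graded stereo level (arcsec)
    if any, else the Worth-4-Dot classification."""

    best_rpst_level: Optional[float] = None
    worth4dot: Literal["fusion", "suppression", "not_tested"] = "not_tested"

    def __post_init__(self) -> None:
        if self.best_rpst_level is None and self.worth4dot == "not_tested":
            raise ValueError("need a Worth 4 Dot outcome when no stereo level is present")


def bf_score(outcome: BinocularOutcome) -> float:
    """Ordinal binocular-function rank.

    Measurable graded stereo maps to round(log10(level), 1) — 1.6 at
    40 arcsec through 3.3 at 2000 arcsec; otherwise 4 (fusion) or 5
    (suppression).  Monotone nondecreasing in the stereo level and ordered
    below the no-stereo codes.
    """
    if outcome.best_rpst_level is not None:
        level = float(outcome.best_rpst_level)
        lo, hi = _RPST_RANGE
        if not lo <= level <= hi:
            raise ValueError(f"graded stereo level must lie in [{lo:g}, {hi:g}] arcsec, got {level}")
        return round(math.log10(level), 1)
    return 4.0 if outcome.worth4dot == "fusion" else 5.0


def relative_change(condition_mean: float, baseline_mean: float) -> float:
    """Condition/baseline ratio to one decimal, round-half-to-even.

    Scale-invariant before rounding: relative_change(a*k, b*k) equals
    relative_change(a, b) for any k > 0.
    """
    if baseline_mean == 0:
        raise ValueError("baseline mean must be nonzero")
    return round(condition_mean / baseline_mean, 1)


@dataclass(frozen=True)
class ContrastCondition:
    """A dichoptic contrast pair (percent Michelson) for one test condition."""

    variant: Literal["equal", "cr", "cr_plus_25", "cr_minus_25"]
    contrast_nondominant: float
    contrast_dominant: float
    clamped: bool = False

    def __post_init__(self) -> None:
        for c in (self.contrast_nondominant, self.contrast_dominant):
            if not 1.0 <= c <= 100.0:
                raise ValueError(f"contrast must lie in [1, 100] percent, got {c}")

    @property
    def presented_ratio(self) -> float:
        return self.contrast_nondominant / self.contrast_dominant


#: Effective-CR scale factor per rebalance variant ("CR+25%CR" scales the
#: attenuation, not the contrast, by 25%).
REBALANCE_VARIANTS: dict[str, float] = {
    "equal": float("nan"),  # no CR-based attenuation
    "cr": 1.0,
    "cr_plus_25": 1.25,
    "cr_minus_25": 0.75,
}


def rebalance_contrasts(cr: float, variant: str, base_contrast: float = 80.0) -> ContrastCondition:
    """Contrast pair for one rebalancing condition.

    The nondominant eye stays at ``base_contrast``; the dominant eye is set to
    ``base_contrast / cr_eff`` with ``cr_eff`` = 1 (equal), CR, 1.25*CR or
    0.75*CR.  The dominant contrast clamps at the 1% display floor (flagged),
    otherwise the achieved nondominant/dominant ratio equals ``cr_eff``
    exactly.
    """
    if variant not in REBALANCE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; known: {sorted(REBALANCE_VARIANTS)}")
    if cr < 1.0:
        raise ValueError(f"cr must be >= 1 (dominance convention), got {cr}")
    if not 1.0 <= base_contrast <= 100.0:
        raise ValueError(f"base_contrast must lie in [1, 100] percent, got {base_contrast}")
    cr_eff = 1.0 if variant == "equal" else REBALANCE_VARIANTS[variant] * cr
    dominant = base_contrast / cr_eff
    # display floor 1%, ceiling 100% (cr_minus_25 can push above base)
    bounded = min(100.0, max(1.0, dominant))
    return ContrastCondition(
        variant=variant,  # type: ignore[arg-type]
        contrast_nondominant=base_contrast,
        contrast_dominant=bounded,
        clamped=bounded != dominant,
    )
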