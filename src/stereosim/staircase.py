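"""Interleaved adaptive staircases for the 4AFC stereo task.

Two staircases run in parallel: one with a two-down/one-up rule (converging
near 70.7% correct) and one with a one-down/one-up rule (50%).  On each trial
one of the still-active staircases is selected at random to control the
disparity.  Each staircase terminates after 70 trials or nine reversals,
whichever happens first; the session ends when both are done.  Disparities
are clamped to the representable [1, 4096] arcsec range.

The start level and step schedule are configurable; by default a session
starts at 1024 arcsec with a 2-octave step that halves at each of the first
two reversals down to a 0.5-octave floor.  A reversal is a change in the
direction of *applied* level movement; a move fully absorbed by the range
clamp does not count as movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._rng import substream
from .observers import DISPARITY_RANGE, SimulatedObserver, cr_report_probability, simulate_trial

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "SessionResult",
    "StaircaseSummary",
    "staircase_update",
    "select_staircase",
    "run_stereo_session",
    "run_cr_session",
]

MAX_TRIALS = 70
MAX_REVERSALS = 9
_LEVEL_LO = math.log2(DISPARITY_RANGE[0])  # 0.0
_LEVEL_HI = math.log2(DISPARITY_RANGE[1])  # 12.0

Rule = Literal["two_down_one_up", "one_down_one_up"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Session-level staircase settings (levels in log2 arcsec, steps in octaves)."""

    start_level: float = math.log2(1024.0)
    initial_step: float = 2.0
    step_floor: float = 0.5
    contrast_dominant: float = 80.0
    contrast_nondominant: float = 80.0

    def __post_init__(self) -> None:
        if not _LEVEL_LO <= self.start_level <= _LEVEL_HI:
            raise ValueError("start_level outside the representable disparity range")
        if self.initial_step <= 0 or self.step_floor <= 0:
            raise ValueError("steps must be positive")


@dataclass(frozen=True)
class StaircaseState:
    rule: Rule
    level: float
    step: float
    initial_step: float = 2.0
    step_floor: float = 0.5
    reversal_count: int = 0
    consecutive_correct: int = 0
    trial_count: int = 0
    last_direction: Literal["up", "down", "none"] = "none"
    done: bool = False
    reversal_levels: tuple[float, ...] = ()

    @classmethod
    def from_config(cls, rule: Rule, config: StaircaseConfig) -> "StaircaseState":
        return cls(
            rule=rule,
            level=config.start_level,
            step=config.initial_step,
            initial_step=config.initial_step,
            step_floor=config.step_floor,
        )


def _scheduled_step(state: StaircaseState) -> float:
    # step halves at each of the first two reversals, then floors
    return max(state.step_floor, state.initial_step / 2 ** min(state.reversal_count, 2))


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance one staircase by one trial outcome and return the new state.

    One-down/one-up moves down on a correct response, up on an error.
    Two-down/one-up moves down only after two consecutive corrects (the
    counter then resets) and up on any error.  Reversals are counted on
    direction changes of applied movement; termination at 70 trials or 9
    reversals.
    """
    if state.done:
        raise ValueError("cannot update a terminated staircase")

    direction: str | None = None
    consecutive = state.consecutive_correct
    if state.rule == "one_down_one_up":
        direction = "down" if correct else "up"
    elif state.rule == "two_down_one_up":
        if correct:
            consecutive += 1
            if consecutive >= 2:
                direction = "down"
                consecutive = 0
        else:
            direction = "up"
            consecutive = 0
    else:  # pragma: no cover - guarded by type
        raise ValueError(f"unknown rule {state.rule!r}")

    level = state.level
    reversals = state.reversal_count
    reversal_levels = state.reversal_levels
    last_direction = state.last_direction
    if direction is not None:
        proposed = level + (state.step if direction == "up" else -state.step)
        new_level = min(_LEVEL_HI, max(_LEVEL_LO, proposed))
        if new_level != level:  # clamped-to-no-change moves are not movement
            if last_direction != "none" and direction != last_direction:
                reversals += 1
                reversal_levels = reversal_levels + (level,)
            last_direction = direction
            level = new_level

    trial_count = state.trial_count + 1
    new_state = replace(
        state,
        level=level,
        reversal_count=reversals,
        consecutive_correct=consecutive,
        trial_count=trial_count,
        last_direction=last_direction,
        done=trial_count >= MAX_TRIALS or reversals >= MAX_REVERSALS,
        reversal_levels=reversal_levels,
    )
    return replace(new_state, step=_scheduled_step(new_state))


def select_staircase(states: dict[str, StaircaseState], rng: np.random.Generator) -> str:
    """Uniformly select one of the non-terminated staircases."""
    active = sorted(sid for sid, s in states.items() if not s.done)
    if not active:
        raise ValueError("all staircases are done; the session should have ended")
    return active[int(rng.integers(len(active)))]


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    staircase_id: str
    disparity: float  # arcsec
    correct: bool
    sector_position: int  # 1..4


@dataclass(frozen=True)
class StaircaseSummary:
    staircase_id: str
    rule: Rule
    trial_count: int
    reversal_count: int
    reversal_levels: tuple[float, ...]  # log2 arcsec at each reversal
    final_level: float


@dataclass(frozen=True)
class SessionResult:
    """Full trial log of one stereo measurement run (both staircases pooled)."""

    trials: tuple[TrialRecord, ...]
    summaries: dict[str, StaircaseSummary]
    seed: int
    config: StaircaseConfig

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def run_stereo_session(
    observer: SimulatedObserver,
    config: StaircaseConfig | None = None,
    seed: int = 0,
) -> SessionResult:
    """Simulate one complete stereo session for an observer.

    Loops select -> present -> respond -> update until both staircases have
    terminated; at most 140 trials.  All randomness (staircase selection,
    sector position, response) comes from one substream of ``seed``, so the
    result is bit-identical on replay.
    """
    config = config or StaircaseConfig()
    rng = substream(seed, "stereo-session")
    states: dict[str, StaircaseState] = {
        "A": StaircaseState.from_config("two_down_one_up", config),
        "B": StaircaseState.from_config("one_down_one_up", config),
    }
    rules = {sid: s.rule for sid, s in states.items()}
    contrast_pair = (config.contrast_dominant, config.contrast_nondominant)
    trials: list[TrialRecord] = []
    index = 0
    while any(not s.done for s in states.values()):
        sid = select_staircase(states, rng)
        disparity = float(2.0 ** states[sid].level)
        sector = int(rng.integers(1, 5))
        correct = simulate_trial(observer, disparity, contrast_pair, rng)
        states[sid] = staircase_update(states[sid], correct)
        trials.append(TrialRecord(index, sid, disparity, correct, sector))
        index += 1
    summaries = {
        sid: StaircaseSummary(
            staircase_id=sid,
            rule=rules[sid],
            trial_count=s.trial_count,
            reversal_count=s.reversal_count,
            reversal_levels=s.reversal_levels,
            final_level=s.level,
        )
        for sid, s in states.items()
    }
    return SessionResult(trials=tuple(trials), summaries=summaries, seed=seed, config=config)


def run_cr_session(
    observer: SimulatedObserver,
    seed: int = 0,
    n_trials: int = 60,
    start_log_ratio: float = 0.0,
    initial_step: float = 0.3,
    step_floor: float = 0.1,
    log_ratio_bounds: tuple[float, float] = (-2.0, 2.5),
) -> list[tuple[float, bool]]:
    """Simulate the dichoptic-letter contrast-ratio task.

    A one-down/one-up staircase on the log10 presented ratio tracks the 50%
    balance point: when the nondominant eye's letter is reported the ratio is
    lowered, otherwise raised.  Step halves at each of the first two reversals.
    Returns (presented_ratio, reported_nondominant) tuples for fitting.
    """
    rng = substream(seed, "cr-session")
    lo, hi = log_ratio_bounds
    x = float(np.clip(start_log_ratio, lo, hi))
    step = initial_step
    reversals = 0
    last_direction: str | None = None
    out: list[tuple[float, bool]] = []
    for _ in range(n_trials):
        ratio = 10.0**x
        reported = bool(rng.random() < cr_report_probability(observer, ratio))
        out.append((ratio, reported))
        direction = "down" if reported else "up"
        if last_direction is not None and direction != last_direction:
            reversals += 1
            step = max(step_floor, initial_step / 2 ** min(reversals, 2))
        last_direction = direction
        x = float(np.clip(x + (step if direction == "up" else -step), lo, hi))
    return out
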