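"""Runnable replicas of the three study designs on simulated cohorts.

* Experiment 1 — amblyopic cohort: measure CR (dichoptic-letter staircase)
  and equal-contrast stereo threshold per observer, then correlate stereo
  with CR and with the interocular VA difference and fit the multiple
  regression (the suppression-versus-acuity dissociation).
* Experiment 2 — normal cohort: stereo thresholds under progressive
  dominant-eye contrast decrements (0–40%), and VA / CR / stereo under each
  Bangerter filter, each summarized as a condition table with
  repeated-measures ANOVA and Bonferroni versus-baseline flags.
* Experiment 3 — amblyopic subsample with measurable baseline stereo:
  thresholds with the dominant eye attenuated by the measured CR and
  CR ± 25%CR, with the paired log-threshold test against baseline.

All randomness derives from the single config seed through named substreams
(cohort, per-observer letter task, per-observer-and-condition stereo
session), so any stage replays independently and a rerun with the same
config is identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .io import cohort_to_frame, session_to_json
from .observers import (
    BANGERTER_DEFAULTS,
    CohortSpec,
    SimulatedObserver,
    apply_bangerter,
    sample_cohort,
    true_threshold,
)
from .psychometric import estimate_cr, fit_stereo_threshold
from .scoring import REBALANCE_VARIANTS, rebalance_contrasts
from .staircase import StaircaseConfig, run_cr_session, run_stereo_session
from .stats import ConditionTable, StatResult, build_condition_table, correlate, fit_multiple_regression, paired_t_log

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

CONTRAST_DECREMENTS = (0, 10, 20, 30, 40)  # percent, 0 = baseline
FILTER_CONDITIONS = ("baseline", "0.8", "0.6", "0.4", "0.1", "<0.1")
REBALANCE_CONDITIONS = ("equal", "cr", "cr_plus_25", "cr_minus_25")
MEASURABLE_CEILING = 4096.0  # arcsec stand-in for unmeasurable runs in group tables
VA_TEST_RETEST_SD = 0.05  # logMAR measurement noise on acuity


def _seed_for(seed: int, *keys) -> int:
    return int(substream(seed, *keys).integers(2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment replica.

    ``conditions`` defaults to the study design for the experiment id
    (Experiment 2 contrast decrements 0–40% in 10% steps and filters 0.8,
    0.6, 0.4, 0.1, <0.1; Experiment 3 variants equal / CR / CR ± 25%CR); any
    condition outside the design is rejected before simulation.
    """

    experiment: int
    seed: int = 0
    n: Optional[int] = None
    conditions: Optional[tuple] = None
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    cohort: Optional[CohortSpec] = None
    pool_factor: int = 6  # Exp 3: candidate pool size per required subject

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment id must be 1, 2 or 3")
        if self.conditions is None:
            return
        conds = tuple(self.conditions)
        if self.experiment == 1 and conds:
            raise ValueError("Experiment 1 has no manipulated conditions")
        if self.experiment == 2:
            numeric = all(isinstance(c, (int, float)) for c in conds)
            allowed = set(CONTRAST_DECREMENTS) if numeric else set(FILTER_CONDITIONS)
            bad = [c for c in conds if c not in allowed]
            if bad or (numeric and 0 not in conds) or (not numeric and "baseline" not in conds):
                raise ValueError(
                    f"Experiment 2 conditions must be drawn from {sorted(allowed, key=str)} "
                    f"and include the baseline; got {conds}"
                )
        if self.experiment == 3:
            bad = [c for c in conds if c not in REBALANCE_CONDITIONS]
            if bad or "equal" not in conds:
                raise ValueError(
                    f"Experiment 3 conditions must be drawn from {REBALANCE_CONDITIONS} "
                    f"and include 'equal'; got {conds}"
                )


@dataclass
class ExperimentResult:
    """Results bundle: cohort truth, per-subject measurements, condition
    tables, inferential statistics, and the raw session logs."""

    experiment: int
    seed: int
    cohort: pd.DataFrame
    measurements: dict[str, pd.DataFrame]
    tables: dict[str, ConditionTable]
    stats: dict[str, StatResult]
    sessions: dict[str, object] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as plain CSV/JSON under one run directory."""
        out = Path(outdir)
        (out / "sessions").mkdir(parents=True, exist_ok=True)
        (out / "tables").mkdir(exist_ok=True)
        (out / "stats").mkdir(exist_ok=True)
        self.cohort.to_csv(out / "cohort.csv", index=False)
        for name, frame in self.measurements.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        for name, tab in self.tables.items():
            tab.table.to_csv(out / "tables" / f"{name}.csv")
            if tab.pairwise is not None:
                tab.pairwise.to_csv(out / "tables" / f"{name}_pairwise.csv")
        stats_payload = {}
        for name, s in self.stats.items():
            d = {
                "kind": s.kind, "statistic": s.statistic, "df": s.df,
                "p_value": s.p_value, "n": s.n, "r_squared": s.r_squared,
                "epsilon": s.epsilon,
            }
            if s.coef_table is not None:
                d["coefficients"] = s.coef_table.to_dict(orient="index")
            stats_payload[name] = d
        (out / "stats" / "stats.json").write_text(
            json.dumps(stats_payload, indent=2, default=float)
        )
        for key, session in self.sessions.items():
            (out / "sessions" / f"{key}.json").write_text(session_to_json(session))
        (out / "config.json").write_text(
            json.dumps({"experiment": self.experiment, "seed": self.seed}, indent=2)
        )


def _measure_stereo(
    observer: SimulatedObserver,
    staircase: StaircaseConfig,
    contrast_pair: tuple[float, float],
    seed: int,
):
    config = dataclasses.replace(
        staircase, contrast_dominant=contrast_pair[0], contrast_nondominant=contrast_pair[1]
    )
    session = run_stereo_session(observer, config, seed=seed)
    est = fit_stereo_threshold(session)
    return session, est


def _measure_cr(observer: SimulatedObserver, seed: int):
    trials = run_cr_session(observer, seed=seed)
    return trials, estimate_cr(trials)


# --------------------------------------------------------------------------


def _run_experiment_1(config: ExperimentConfig, keep_sessions: bool) -> ExperimentResult:
    n = config.n or 21
    spec = config.cohort or CohortSpec.amblyopic(n=n, seed=_seed_for(config.seed, "exp1", "cohort"))
    cohort = sample_cohort(spec)
    sessions: dict[str, object] = {}
    rows = []
    for i, obs in enumerate(cohort):
        _, cr_est = _measure_cr(obs, _seed_for(config.seed, "exp1", "cr", i))
        session, est = _measure_stereo(
            obs, config.staircase, (80.0, 80.0), _seed_for(config.seed, "exp1", "stereo", i)
        )
        if keep_sessions:
            sessions[f"s{i:02d}_stereo"] = session
        rows.append(
            {
                "observer": i,
                "cr_true": obs.cr_true,
                "cr_est": cr_est.cr,
                "va_diff": obs.va_difference,
                "threshold": est.threshold,
                "measurable": est.measurable,
                "true_threshold": true_threshold(obs),
            }
        )
    meas = pd.DataFrame(rows)
    ok = meas[meas["measurable"] & np.isfinite(meas["cr_est"])]
    stats: dict[str, StatResult] = {}
    if len(ok) >= 4:
        log_thr = np.log10(ok["threshold"])
        stats["stereo_vs_cr"] = correlate(np.log10(ok["cr_est"]), log_thr)
        stats["stereo_vs_va"] = correlate(ok["va_diff"], log_thr)
        stats["regression"] = fit_multiple_regression(
            log_thr, {"va_diff": ok["va_diff"], "log_cr": np.log10(ok["cr_est"])}
        )
    return ExperimentResult(1, config.seed, cohort_to_frame(cohort), {"subjects": meas}, {}, stats, sessions)


def _run_experiment_2(config: ExperimentConfig, keep_sessions: bool) -> ExperimentResult:
    n = config.n or 19
    spec = config.cohort or CohortSpec.normal(n=n, seed=_seed_for(config.seed, "exp2", "cohort"))
    cohort = sample_cohort(spec)
    conds = tuple(config.conditions) if config.conditions is not None else None
    numeric = conds is None or all(isinstance(c, (int, float)) for c in conds)
    decrements = tuple(sorted(conds)) if (conds is not None and numeric) else CONTRAST_DECREMENTS
    filters = conds if (conds is not None and not numeric) else FILTER_CONDITIONS
    run_contrast = conds is None or numeric
    run_filters = conds is None or not numeric

    sessions: dict[str, object] = {}
    measurements: dict[str, pd.DataFrame] = {}
    tables: dict[str, ConditionTable] = {}
    stats: dict[str, StatResult] = {}

    if run_contrast:
        cols = {}
        for dec in decrements:
            label = "baseline" if dec == 0 else str(int(dec))
            vals = []
            for i, obs in enumerate(cohort):
                session, est = _measure_stereo(
                    obs, config.staircase, (80.0 - dec, 80.0),
                    _seed_for(config.seed, "exp2", "contrast", dec, i),
                )
                if keep_sessions:
                    sessions[f"contrast{dec:02d}_s{i:02d}"] = session
                vals.append(est.threshold if est.measurable else MEASURABLE_CEILING)
            cols[label] = vals
        wide = pd.DataFrame(cols)
        measurements["contrast_thresholds"] = wide
        tables["contrast_stereo"] = build_condition_table(wide, baseline="baseline")
        stats["contrast_anova"] = tables["contrast_stereo"].anova

    if run_filters:
        va_cols, cr_cols, st_cols = {}, {}, {}
        for label in filters:
            va, cr, st = [], [], []
            for i, obs in enumerate(cohort):
                degraded = obs if label == "baseline" else apply_bangerter(obs, label)
                rng = substream(config.seed, "exp2", "va-noise", label, i)
                va.append(abs(degraded.va_difference + rng.normal(0.0, VA_TEST_RETEST_SD)))
                _, cr_est = _measure_cr(degraded, _seed_for(config.seed, "exp2", "cr", label, i))
                cr.append(cr_est.cr if cr_est.converged else degraded.cr_true)
                session, est = _measure_stereo(
                    degraded, config.staircase, (80.0, 80.0),
                    _seed_for(config.seed, "exp2", "bangerter", label, i),
                )
                if keep_sessions:
                    sessions[f"filter{label}_s{i:02d}"] = session
                st.append(est.threshold if est.measurable else MEASURABLE_CEILING)
            va_cols[label], cr_cols[label], st_cols[label] = va, cr, st
        for name, cols in (("va", va_cols), ("cr", cr_cols), ("stereo", st_cols)):
            wide = pd.DataFrame(cols)
            measurements[f"bangerter_{name}"] = wide
            tables[f"bangerter_{name}"] = build_condition_table(wide, baseline="baseline")
            stats[f"bangerter_{name}_anova"] = tables[f"bangerter_{name}"].anova

    return ExperimentResult(2, config.seed, cohort_to_frame(cohort), measurements, tables, stats, sessions)


def _run_experiment_3(config: ExperimentConfig, keep_sessions: bool) -> ExperimentResult:
    n = config.n or 7
    variants = tuple(config.conditions) if config.conditions is not None else REBALANCE_CONDITIONS
    pool_spec = config.cohort or CohortSpec.amblyopic(
        n=n * config.pool_factor, seed=_seed_for(config.seed, "exp3", "cohort")
    )
    pool = sample_cohort(pool_spec)

    sessions: dict[str, object] = {}
    rows = []
    selected: list[tuple[int, SimulatedObserver, float, object]] = []
    for i, obs in enumerate(pool):
        if len(selected) == n:
            break
        _, cr_est = _measure_cr(obs, _seed_for(config.seed, "exp3", "cr", i))
        if not cr_est.converged or not np.isfinite(cr_est.cr) or cr_est.cr < 1.0:
            continue
        session, est = _measure_stereo(
            obs, config.staircase, (80.0, 80.0), _seed_for(config.seed, "exp3", "equal", i)
        )
        if not est.measurable:
            continue
        if keep_sessions:
            sessions[f"s{i:02d}_equal"] = session
        selected.append((i, obs, cr_est.cr, est))
    if len(selected) < n:
        raise RuntimeError(
            f"could only assemble {len(selected)} of {n} measurable subjects; increase pool_factor"
        )

    for i, obs, cr_meas, est_equal in selected:
        row = {
            "observer": i,
            "cr_est": cr_meas,
            "cr_true": obs.cr_true,
            "equal": est_equal.threshold,
            "true_equal": true_threshold(obs),
            "true_balanced_at_cr_true": true_threshold(obs, 80.0 / obs.cr_true, 80.0),
        }
        for variant in variants:
            if variant == "equal":
                continue
            cond = rebalance_contrasts(cr_meas, variant)
            session, est = _measure_stereo(
                obs, config.staircase,
                (cond.contrast_dominant, cond.contrast_nondominant),
                _seed_for(config.seed, "exp3", variant, i),
            )
            if keep_sessions:
                sessions[f"s{i:02d}_{variant}"] = session
            row[variant] = est.threshold if est.measurable else MEASURABLE_CEILING
            row[f"true_{variant}"] = true_threshold(
                obs, cond.contrast_dominant, cond.contrast_nondominant
            )
        rows.append(row)
    meas = pd.DataFrame(rows)

    stats: dict[str, StatResult] = {}
    if "cr" in variants:
        both = meas[np.isfinite(meas["equal"]) & np.isfinite(meas["cr"])]
        stats["paired_t_equal_vs_cr"] = paired_t_log(both["equal"], both["cr"])
    cohort_frame = cohort_to_frame([obs for _, obs, _, _ in selected])
    return ExperimentResult(3, config.seed, cohort_frame, {"subjects": meas}, {}, stats, sessions)


def run_experiment(config: ExperimentConfig, keep_sessions: bool = False, outdir: str | Path | None = None) -> ExperimentResult:
    """Run one experiment replica end to end.

    ``keep_sessions`` retains every trial log in the bundle (and writes them
    when ``outdir`` is given); group tables and statistics are always
    produced.
    """
    runner = {1: _run_experiment_1, 2: _run_experiment_2, 3: _run_experiment_3}[config.experiment]
    result = runner(config, keep_sessions)
    if outdir is not None:
        result.write(outdir)
    return result
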