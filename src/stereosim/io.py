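"""Fixtures, configuration and serialization.

The package ships the three printed group tables as checksummed CSV fixtures:

* ``table1`` — group stereoacuity under progressive dominant-eye contrast
  decrement (mean, SD, printed relative change, significance flag);
* ``table2`` — interocular VA, CR and stereoacuity under each Bangerter
  filter (same layout per measure);
* ``table3`` — the seven individual amblyopic observers of the rebalancing
  experiment (CR, baseline threshold, and thresholds with the dominant eye
  attenuated by CR and CR ± 25%CR).

Sessions and estimates serialize to JSON, cohorts to CSV, and cohort specs to
YAML/JSON configs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .observers import CohortSpec, PsychometricParams, SimulatedObserver, TruncatedDist
from .psychometric import CREstimate, ThresholdEstimate
from .staircase import SessionResult, StaircaseConfig, StaircaseSummary, TrialRecord

__all__ = [
    "load_fixture",
    "FIXTURE_CHECKSUMS",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "cohort_spec_from_config",
    "session_to_json",
    "session_from_json",
    "estimate_to_dict",
]

FIXTURE_CHECKSUMS = {
    "table1": "a870ed39d4f109ac222d4192a527f07eeabc576942b5afce9ef6153714676f8d",
    "table2": "1b0e25ee9cc04f30e8668e6ff68793d721a335871495f6d4310abc90ab7eebf7",
    "table3": "9262b1b405dd430b2e1f6166f9f7f1ca030642576de1f83c283afbe7a9bb8a6e",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged printed-table fixture, verifying its checksum.

    A checksum mismatch means the packaged values were altered and is a hard
    failure: downstream regression tests rely on these numbers verbatim.
    """
    if name not in FIXTURE_CHECKSUMS:
        raise ValueError(f"unknown fixture {name!r}; known: {sorted(FIXTURE_CHECKSUMS)}")
    ref = resources.files("stereosim.data").joinpath(f"{name}.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name!r} failed its checksum ({digest}); packaged data corrupted"
        )
    import io as _io

    return pd.read_csv(_io.BytesIO(raw))


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "alpha", "beta", "gamma", "lapse", "kappa", "cr_true", "sigma_cr",
    "kappa_release", "va_dominant", "va_nondominant", "group",
]


def cohort_to_frame(cohort: list[SimulatedObserver]) -> pd.DataFrame:
    """One row per observer; columns document the full generative truth."""
    rows = []
    for obs in cohort:
        rows.append(
            {
                "alpha": obs.stereo.alpha,
                "beta": obs.stereo.beta,
                "gamma": obs.stereo.gamma,
                "lapse": obs.stereo.lapse,
                "kappa": obs.kappa,
                "cr_true": obs.cr_true,
                "sigma_cr": obs.sigma_cr,
                "kappa_release": obs.kappa_release,
                "va_dominant": obs.va_dominant,
                "va_nondominant": obs.va_nondominant,
                "group": obs.group,
            }
        )
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[SimulatedObserver]:
    cohort = []
    for _, row in frame.iterrows():
        cohort.append(
            SimulatedObserver(
                stereo=PsychometricParams(
                    alpha=float(row["alpha"]), beta=float(row["beta"]),
                    gamma=float(row["gamma"]), lapse=float(row["lapse"]),
                ),
                kappa=float(row["kappa"]),
                cr_true=float(row["cr_true"]),
                sigma_cr=float(row["sigma_cr"]),
                kappa_release=float(row["kappa_release"]),
                va_dominant=float(row["va_dominant"]),
                va_nondominant=float(row["va_nondominant"]),
                group=str(row["group"]),
            )
        )
    return cohort


def write_cohort_csv(cohort: list[SimulatedObserver], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[SimulatedObserver]:
    return frame_to_cohort(pd.read_csv(path))


def cohort_spec_from_config(path: str | Path) -> CohortSpec:
    """Build a CohortSpec from a YAML/JSON config file.

    Minimal form: ``{group: normal|amblyopic, n: int, seed: int}`` picks the
    calibrated defaults; distribution blocks (``cr``, ``va_diff``,
    ``threshold``) with family/mean/sd/lower/upper override them.
    """
    text = Path(path).read_text()
    cfg: dict[str, Any] = yaml.safe_load(text)
    group = cfg.pop("group")
    n = int(cfg.pop("n", 0)) or (19 if group == "normal" else 21)
    seed = int(cfg.pop("seed", 0))
    spec = CohortSpec.normal(n=n, seed=seed) if group == "normal" else CohortSpec.amblyopic(n=n, seed=seed)
    dist_fields = {"cr", "va_diff", "threshold", "beta", "kappa_release"}
    overrides: dict[str, Any] = {}
    for key, value in cfg.items():
        if key in dist_fields:
            overrides[key] = TruncatedDist(**value)
        else:
            overrides[key] = value
    return dataclasses.replace(spec, **overrides) if overrides else spec


# --------------------------------------------------------------------------
# Sessions and estimates
# --------------------------------------------------------------------------


def session_to_json(session: SessionResult) -> str:
    payload = {
        "seed": session.seed,
        "config": dataclasses.asdict(session.config),
        "summaries": {
            sid: dataclasses.asdict(s) for sid, s in sorted(session.summaries.items())
        },
        "trials": [dataclasses.asdict(t) for t in session.trials],
    }
    return json.dumps(payload, indent=2)


def session_from_json(text: str) -> SessionResult:
    payload = json.loads(text)
    config = StaircaseConfig(**payload["config"])
    trials = tuple(TrialRecord(**t) for t in payload["trials"])
    summaries = {
        sid: StaircaseSummary(**{**s, "reversal_levels": tuple(s["reversal_levels"])})
        for sid, s in payload["summaries"].items()
    }
    return SessionResult(trials=trials, summaries=summaries, seed=payload["seed"], config=config)


def estimate_to_dict(est: ThresholdEstimate | CREstimate) -> dict[str, Any]:
    d = dataclasses.asdict(est)
    return {k: (None if isinstance(v, float) and not np.isfinite(v) else v) for k, v in d.items()}
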