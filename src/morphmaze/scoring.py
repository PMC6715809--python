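"""Automated behavioural scoring and learning curves.

Three ways to call a trial correct:

* MANUAL — the experimenter's judgement: did the animal commit to the cued
  area?  Reproduced here as choice == cue with hint trials excluded (the
  convention used for the hand-scored curves).
* REWARD — pellet-count thresholding: a trial is correct when the number of
  pellets dispensed reaches the phase's threshold (3 in phase 1, 2 in phases
  2-5, 1 in phases 6-7).  Hint trials stay in: the single guidance pellet
  falls below threshold, so hint-assisted trials score incorrect by design.
* SENSOR — raw sensor truth: the first reward-area sensor crossed matches
  the cued side.  Includes hint trials by default, which is exactly what
  inflates early-phase sensor curves (the animal follows the hint to the
  correct area).  Sensor scores are unreliable in phases 1-4, where the
  rat's tail can trip a sensor; they are emitted with a warning.

Timed-out trials are incorrect under every method.  Daily percent-correct
series are smoothed with a trailing 3-day rolling mean (partial windows at
the start of training use the days available, so curves begin on day 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import Outcome, SessionRecord, TrialRecord, read_session_jsonl
from .phases import PhaseConfig

__all__ = [
    "ScoreMethod",
    "ScoreSeries",
    "PELLET_THRESHOLDS",
    "reward_score",
    "sensor_score",
    "choice_score",
    "rolling_curve",
    "trials_frame",
    "score_daily",
    "load_logs",
]

PELLET_THRESHOLDS: dict[int, int] = {1: 3, 2: 2, 3: 2, 4: 2, 5: 2, 6: 1, 7: 1}

SENSOR_UNRELIABLE_PHASES = frozenset({1, 2, 3, 4})


class ScoreMethod:
    MANUAL = "MANUAL"
    REWARD = "REWARD"
    SENSOR = "SENSOR"
    ALL = (MANUAL, REWARD, SENSOR)


def _threshold(phase: int | PhaseConfig) -> int:
    p = phase.phase if isinstance(phase, PhaseConfig) else int(phase)
    if p not in PELLET_THRESHOLDS:
        raise ValueError(f"unknown phase {p}")
    if isinstance(phase, PhaseConfig):
        return phase.pellet_threshold
    return PELLET_THRESHOLDS[p]


def reward_score(trial: TrialRecord, phase: int | PhaseConfig) -> Outcome:
    """Correct iff the pellets dispensed reach the phase threshold."""
    if trial.pellets < 0:
        raise ValueError("pellets must be >= 0")
    return (
        Outcome.CORRECT if trial.pellets >= _threshold(phase) else Outcome.INCORRECT
    )


def sensor_score(trial: TrialRecord) -> Outcome:
    """Correct iff the first reward-area sensor crossed matches the cue.

    Timed-out trials (no sensor crossing) are incorrect.
    """
    if trial.chosen_side is None:
        return Outcome.INCORRECT
    return (
        Outcome.CORRECT
        if trial.chosen_side is trial.cued_side
        else Outcome.INCORRECT
    )


choice_score = sensor_score  # the MANUAL-equivalent per-trial rule


def rolling_curve(daily_percents: Sequence[float], window: int = 3) -> np.ndarray:
    """Trailing rolling mean; partial windows at the series start."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(list(daily_percents), dtype=float)
    if s.empty:
        raise ValueError("empty series")
    return s.rolling(window, min_periods=1).mean().to_numpy()


def trials_frame(sessions: Iterable[SessionRecord]) -> pd.DataFrame:
    """Flatten sessions into one tidy trial-level DataFrame."""
    rows = []
    for s in sessions:
        for b, block in enumerate(s.blocks):
            for rec in block:
                rows.append(
                    {
                        "animal": s.animal_id,
                        "day": s.day,
                        "phase": s.phase_cfg.phase,
                        "block": b,
                        "trial": rec.trial_index,
                        "cued": rec.cued_side.letter,
                        "chosen": (
                            rec.chosen_side.letter if rec.chosen_side else None
                        ),
                        "rt_ms": rec.reaction_time_ms,
                        "pellets": rec.pellets,
                        "outcome": rec.outcome.value,
                        "is_hint": rec.is_hint_trial,
                    }
                )
    return pd.DataFrame(rows)


def _trial_correct(df: pd.DataFrame, method: str) -> pd.Series:
    if method == ScoreMethod.REWARD:
        thr = df["phase"].map(PELLET_THRESHOLDS)
        return df["pellets"] >= thr
    # MANUAL and SENSOR both reduce to first-sensor-equals-cue at trial level
    return (df["chosen"] == df["cued"]) & df["chosen"].notna()


def score_daily(
    df: pd.DataFrame,
    method: str = ScoreMethod.REWARD,
    exclude_hints: bool | None = None,
    window: int = 3,
) -> pd.DataFrame:
    """Per-animal daily percent correct for one method, with rolling mean.

    ``exclude_hints`` defaults to True only for MANUAL (the hand-scoring
    convention drops hint trials).  REWARD keeps them — the single hint
    pellet falls below threshold, so guided trials score incorrect
    automatically — and raw SENSOR keeps them too, which is what inflates
    early-phase sensor curves.  Returns columns animal, day, phase, method,
    n_trials, pct_correct, pct_rolling, sensor_unreliable.
    """
    if method not in ScoreMethod.ALL:
        raise ValueError(f"unknown method {method!r}")
    if df.empty:
        raise ValueError("no trials to score")
    if exclude_hints is None:
        exclude_hints = method == ScoreMethod.MANUAL
    data = df[~df["is_hint"]] if exclude_hints else df
    data = data.copy()
    data["correct"] = _trial_correct(data, method)
    if method == ScoreMethod.SENSOR and set(data["phase"]) & SENSOR_UNRELIABLE_PHASES:
        warnings.warn(
            "sensor scores are unreliable for phases 1-4 (tail-triggered sensors)",
            UserWarning,
            stacklevel=2,
        )
    out = (
        data.groupby(["animal", "day", "phase"], as_index=False)
        .agg(n_trials=("correct", "size"), pct_correct=("correct", "mean"))
    )
    out["pct_correct"] *= 100.0
    out["method"] = method
    out = out.sort_values(["animal", "day"]).reset_index(drop=True)
    out["pct_rolling"] = (
        out.groupby("animal")["pct_correct"]
        .transform(lambda s: s.rolling(window, min_periods=1).mean())
    )
    out["sensor_unreliable"] = (method == ScoreMethod.SENSOR) & out["phase"].isin(
        sorted(SENSOR_UNRELIABLE_PHASES)
    )
    return out


@dataclass(frozen=True)
class ScoreSeries:
    """One animal's daily learning curve for one scoring method."""

    animal_id: str
    method: str
    frame: pd.DataFrame  # day, phase, n_trials, pct_correct, pct_rolling

    @property
    def rolling(self) -> np.ndarray:
        return self.frame["pct_rolling"].to_numpy()


def load_logs(paths: Iterable[str | Path]) -> pd.DataFrame:
    """Read JSONL event logs into one trial-level frame."""
    sessions = [read_session_jsonl(p) for p in sorted(map(Path, paths))]
    if not sessions:
        raise ValueError("no logs found")
    return trials_frame(sessions)
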