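"""Constrained pseudorandom trial schedules for a two-alternative forced-choice task.

Each block of trials needs a sequence of cued/rewarded sides that a rat cannot
exploit without attending to the cue.  Unconstrained coin flips fail in two
ways: long same-side runs let the animal develop a side bias, and frequent
side switches reward the rodent's innate tendency to alternate between food
sites.  The generator therefore draws i.i.d. fair-coin sequences and rejects
any candidate that (a) repeats one side more than ``max_run_length`` times in
a row, (b) has a switch fraction outside ``alternation_band``, or (c) is not
counterbalanced to within ``max_side_imbalance`` trials.  Rejection of the
whole sequence (rather than local repair) keeps the accepted set uniformly
distributed, so transition statistics are unbiased within the constraint set.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Side",
    "SequenceConstraints",
    "SequenceStats",
    "BlockSchedule",
    "ScheduleInfeasibleError",
    "generate_sequence",
    "validate_sequence",
    "sequence_stats",
    "monte_carlo_audit",
    "MonteCarloAudit",
    "enumerate_valid_sequences",
    "sample_accepted_matrix",
    "write_schedule_csv",
    "read_schedule_csv",
]


class Side(Enum):
    """One of the two reward areas. Serialized as 0 (left) / 1 (right)."""

    LEFT = 0
    RIGHT = 1

    @property
    def complement(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT

    @property
    def letter(self) -> str:
        return "L" if self is Side.LEFT else "R"

    @classmethod
    def from_letter(cls, s: str) -> "Side":
        s = s.strip().upper()
        if s in ("L", "LEFT", "0"):
            return cls.LEFT
        if s in ("R", "RIGHT", "1"):
            return cls.RIGHT
        raise ValueError(f"not a side: {s!r}")

    def __repr__(self) -> str:  # compact traces in logs and tests
        return self.letter


class ScheduleInfeasibleError(RuntimeError):
    """Raised when rejection sampling exhausts ``max_rejections`` attempts."""


@dataclass(frozen=True)
class SequenceConstraints:
    """Rejection rules applied to every candidate block sequence.

    Parameters
    ----------
    max_run_length:
        Longest permitted run of identical sides (default 3; candidates with
        a run of 4+ are discarded).
    alternation_band:
        Closed interval for the fraction of side-switch transitions.  The
        default [0.35, 0.45] centres the accepted set on 40% switches / 60%
        same-side transitions, which actively discourages the rodent
        alternation strategy.
    max_side_imbalance:
        Maximum allowed ``|#left - #right|`` (default 1: exact counterbalance
        for even block lengths).
    max_rejections:
        Attempt budget before :class:`ScheduleInfeasibleError` is raised.
    """

    max_run_length: int = 3
    alternation_band: tuple[float, float] = (0.35, 0.45)
    max_side_imbalance: int = 1
    max_rejections: int = 100_000

    def __post_init__(self) -> None:
        lo, hi = self.alternation_band
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("alternation_band must satisfy 0 <= lo <= hi <= 1")
        if self.max_side_imbalance < 0:
            raise ValueError("max_side_imbalance must be >= 0")
        if self.max_rejections < 1:
            raise ValueError("max_rejections must be >= 1")


@dataclass(frozen=True)
class SequenceStats:
    """Descriptive statistics of one block sequence."""

    n: int
    frac_left: float
    alternation_frac: float
    max_run: int
    n_LR_transitions: int
    n_RL_transitions: int


@dataclass(frozen=True)
class BlockSchedule:
    """An accepted sequence of cued sides for one block, with its provenance."""

    sides: tuple[Side, ...]
    seed: int
    constraints_used: SequenceConstraints = field(default_factory=SequenceConstraints)

    def __len__(self) -> int:
        return len(self.sides)

    def __iter__(self):
        return iter(self.sides)

    @property
    def stats(self) -> SequenceStats:
        return sequence_stats(self.sides)


def _as_int_array(sides: Sequence[Side | int]) -> np.ndarray:
    vals = [s.value if isinstance(s, Side) else int(s) for s in sides]
    arr = np.asarray(vals, dtype=np.int8)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("sides must be 0/1 or Side values")
    return arr


def sequence_stats(sides: Sequence[Side | int]) -> SequenceStats:
    """Compute counts of runs, switches and directional transitions.

    For a single-trial sequence there are no transitions; the alternation
    fraction is reported as 0.0.
    """
    x = _as_int_array(sides)
    n = x.size
    if n == 0:
        raise ValueError("empty sequence")
    frac_left = float((x == Side.LEFT.value).mean())
    if n == 1:
        return SequenceStats(1, frac_left, 0.0, 1, 0, 0)
    switch = x[1:] != x[:-1]
    n_lr = int(((x[:-1] == Side.LEFT.value) & switch).sum())
    n_rl = int(((x[:-1] == Side.RIGHT.value) & switch).sum())
    # longest run = longest gap between switch positions
    run_breaks = np.flatnonzero(switch)
    edges = np.concatenate(([-1], run_breaks, [n - 1]))
    max_run = int(np.diff(edges).max())
    return SequenceStats(n, frac_left, float(switch.mean()), max_run, n_lr, n_rl)


def validate_sequence(
    sides: Sequence[Side | int], constraints: SequenceConstraints | None = None
) -> tuple[bool, SequenceStats]:
    """Check one sequence against the rejection rules.

    Returns ``(ok, stats)``; stats are always computed.  The alternation rule
    is vacuous for single-trial sequences (no transitions exist).
    """
    constraints = constraints or SequenceConstraints()
    stats = sequence_stats(sides)
    lo, hi = constraints.alternation_band
    ok = stats.max_run <= constraints.max_run_length
    if stats.n > 1:
        ok = ok and lo <= stats.alternation_frac <= hi
    n_left = round(stats.frac_left * stats.n)
    ok = ok and abs(2 * n_left - stats.n) <= constraints.max_side_imbalance
    return ok, stats


def generate_sequence(
    n_trials: int,
    constraints: SequenceConstraints | None = None,
    seed: int | None = None,
) -> BlockSchedule:
    """Draw one accepted block sequence by whole-sequence rejection sampling.

    Candidates are i.i.d. fair coin flips; any constraint violation discards
    the entire candidate and a fresh one is drawn.  Raises
    :class:`ScheduleInfeasibleError` after ``max_rejections`` failed attempts
    (the signature of an infeasible constraint set, e.g. an alternation band
    containing no achievable switch count for the given length).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    constraints = constraints or SequenceConstraints()
    seed = 0 if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    for _ in range(constraints.max_rejections):
        candidate = rng.integers(0, 2, size=n_trials)
        ok, _ = validate_sequence(candidate, constraints)
        if ok:
            sides = tuple(Side(int(v)) for v in candidate)
            return BlockSchedule(sides=sides, seed=seed, constraints_used=constraints)
    raise ScheduleInfeasibleError(
        f"no accepted sequence of length {n_trials} in "
        f"{constraints.max_rejections} attempts; constraints likely infeasible"
    )


def sample_accepted_matrix(
    n_sequences: int,
    n_trials: int,
    constraints: SequenceConstraints | None = None,
    rng: np.random.Generator | int | None = None,
    batch: int = 200_000,
) -> np.ndarray:
    """Vectorised rejection sampler returning ``(n_sequences, n_trials)`` 0/1 rows.

    Same candidate distribution and acceptance rule as
    :func:`generate_sequence` (i.i.d. fair coins filtered through the
    constraints), evaluated in batches for Monte-Carlo work where acceptance
    probabilities of ~1e-3 make per-sequence Python loops impractical.
    """
    constraints = constraints or SequenceConstraints()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    lo, hi = constraints.alternation_band
    accepted: list[np.ndarray] = []
    n_acc = 0
    drawn = 0
    budget = (n_sequences + 1) * constraints.max_rejections
    while n_acc < n_sequences:
        if drawn >= budget:
            raise ScheduleInfeasibleError(
                f"acceptance too rare: {n_acc}/{n_sequences} accepted "
                f"after {drawn} candidates"
            )
        x = rng.integers(0, 2, size=(batch, n_trials), dtype=np.int8)
        drawn += batch
        n_left = (x == 0).sum(axis=1)
        ok = np.abs(n_trials - 2 * n_left) <= constraints.max_side_imbalance
        if n_trials > 1:
            switch = x[:, 1:] != x[:, :-1]
            af = switch.mean(axis=1)
            ok &= (af >= lo) & (af <= hi)
            if n_trials > constraints.max_run_length:
                eq = ~switch
                k = constraints.max_run_length
                over = np.ones_like(eq[:, : eq.shape[1] - k + 1], dtype=bool)
                for j in range(k):
                    over &= eq[:, j : eq.shape[1] - k + 1 + j]
                ok &= ~over.any(axis=1)
        hits = x[ok]
        accepted.append(hits)
        n_acc += len(hits)
    return np.concatenate(accepted)[:n_sequences]


@dataclass(frozen=True)
class MonteCarloAudit:
    """Per-sequence stats plus aggregates from repeated schedule generation."""

    n_sequences: int
    n_trials: int
    per_sequence: list[SequenceStats]
    mean_frac_left: float
    mean_alternation_frac: float
    min_alternation_frac: float
    max_alternation_frac: float
    max_max_run: int

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "n_trials": self.n_trials,
            "mean_frac_left": self.mean_frac_left,
            "mean_alternation_frac": self.mean_alternation_frac,
            "min_alternation_frac": self.min_alternation_frac,
            "max_alternation_frac": self.max_alternation_frac,
            "max_max_run": self.max_max_run,
        }


def monte_carlo_audit(
    n_sequences: int,
    n_trials: int,
    constraints: SequenceConstraints | None = None,
    seed: int | None = None,
) -> MonteCarloAudit:
    """Generate many accepted sequences and summarise their statistics.

    This is the generator self-test: run the block-schedule draw thousands of
    times and confirm that side balance, alternation fraction and run lengths
    stay inside the intended envelope.  Deterministic given ``seed``.
    """
    x = sample_accepted_matrix(n_sequences, n_trials, constraints, rng=seed)
    per_seq = [sequence_stats(row) for row in x]
    alt = np.array([s.alternation_frac for s in per_seq])
    return MonteCarloAudit(
        n_sequences=n_sequences,
        n_trials=n_trials,
        per_sequence=per_seq,
        mean_frac_left=float(np.mean([s.frac_left for s in per_seq])),
        mean_alternation_frac=float(alt.mean()),
        min_alternation_frac=float(alt.min()),
        max_alternation_frac=float(alt.max()),
        max_max_run=int(max(s.max_run for s in per_seq)),
    )


def enumerate_valid_sequences(
    n_trials: int, constraints: SequenceConstraints | None = None
) -> list[tuple[int, ...]]:
    """Exhaustively enumerate every 0/1 sequence passing the constraints.

    Exponential in ``n_trials``; guarded to n <= 20.  Used to compute exact
    acceptance probabilities and to certify that rejection sampling can reach
    the full accepted set.
    """
    if n_trials > 20:
        raise ValueError("exhaustive enumeration limited to n_trials <= 20")
    constraints = constraints or SequenceConstraints()
    return [
        seq
        for seq in product((0, 1), repeat=n_trials)
        if validate_sequence(seq, constraints)[0]
    ]


# ---------------------------------------------------------------------------
# File interface: CSV of trial_index,side plus a JSON sidecar with provenance.

def write_schedule_csv(schedule: BlockSchedule, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_index", "side"])
        for i, side in enumerate(schedule.sides):
            w.writerow([i, side.letter])
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "seed": schedule.seed,
        "constraints": {
            "max_run_length": schedule.constraints_used.max_run_length,
            "alternation_band": list(schedule.constraints_used.alternation_band),
            "max_side_imbalance": schedule.constraints_used.max_side_imbalance,
            "max_rejections": schedule.constraints_used.max_rejections,
        },
    }
    sidecar.write_text(json.dumps(meta, indent=2))


def read_schedule_csv(path: str | Path) -> BlockSchedule:
    path = Path(path)
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    sides = tuple(
        Side.from_letter(r["side"])
        for r in sorted(rows, key=lambda r: int(r["trial_index"]))
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    seed = 0
    constraints = SequenceConstraints()
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seed = int(meta.get("seed", 0))
        c = meta.get("constraints", {})
        constraints = SequenceConstraints(
            max_run_length=c.get("max_run_length", 3),
            alternation_band=tuple(c.get("alternation_band", (0.35, 0.45))),
            max_side_imbalance=c.get("max_side_imbalance", 1),
            max_rejections=c.get("max_rejections", 100_000),
        )
    return BlockSchedule(sides=sides, seed=seed, constraints_used=constraints)
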