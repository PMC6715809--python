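"""Null response strategies: generator certification and compliance scoring.

A rat can earn rewards without ever learning the tone-to-place association by
following a cue-ignoring policy: always going to one side, spontaneously
alternating, returning to the last rewarded side (win-stay) or avoiding it
(win-shift).  The schedule generator is certified only if none of these
policies, simulated on many generated blocks, can score above a ceiling
(60% by default).  The same policy machinery scores recorded response
streams for *compliance*: given the animal's first response in a block, how
many of its remaining responses match what the policy would have done.

Policies receive reward feedback only, never the cue — they are the null
models the cue-driven behaviour must beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schedule import (
    BlockSchedule,
    SequenceConstraints,
    Side,
    sample_accepted_matrix,
)

__all__ = [
    "Policy",
    "PolicyState",
    "StrategyResult",
    "StrategyAudit",
    "policy_choice",
    "simulate_strategy",
    "audit_generator",
    "compliance",
]


class Policy(str, Enum):
    ALWAYS_LEFT = "ALWAYS_LEFT"
    ALWAYS_RIGHT = "ALWAYS_RIGHT"
    WIN_STAY = "WIN_STAY"
    WIN_SHIFT = "WIN_SHIFT"
    SPONT_ALTERNATE = "SPONT_ALTERNATE"
    RANDOM = "RANDOM"


ALL_POLICIES: tuple[Policy, ...] = tuple(Policy)


@dataclass
class PolicyState:
    """Reward-history state carried across trials within one block.

    ``last_rewarded_side`` updates only on rewarded trials; both fields are
    empty before the first trial of a block.
    """

    last_choice: Side | None = None
    last_rewarded_side: Side | None = None

    def update(self, choice: Side, rewarded: bool) -> None:
        self.last_choice = choice
        if rewarded:
            self.last_rewarded_side = choice


def policy_choice(
    policy: Policy, state: PolicyState, rng: np.random.Generator
) -> Side:
    """Next choice of a policy given its state.

    Win-stay returns the most recently rewarded side and win-shift its
    complement; while no reward has occurred yet they fall back on repeating
    / complementing the last choice.  On the very first trial (no history at
    all) the history-dependent policies choose uniformly at random.
    """
    if policy is Policy.ALWAYS_LEFT:
        return Side.LEFT
    if policy is Policy.ALWAYS_RIGHT:
        return Side.RIGHT
    if policy is Policy.RANDOM:
        return Side(int(rng.integers(0, 2)))
    if state.last_choice is None:
        return Side(int(rng.integers(0, 2)))
    if policy is Policy.SPONT_ALTERNATE:
        return state.last_choice.complement
    anchor = (
        state.last_rewarded_side
        if state.last_rewarded_side is not None
        else state.last_choice
    )
    if policy is Policy.WIN_STAY:
        return anchor
    if policy is Policy.WIN_SHIFT:
        return anchor.complement
    raise ValueError(f"unknown policy {policy!r}")


@dataclass(frozen=True)
class StrategyResult:
    policy_name: str
    percent_correct: float
    per_trial_choices: tuple[Side, ...]


def simulate_strategy(
    policy: Policy,
    schedule: BlockSchedule | Sequence[Side],
    seed: int | None = None,
    first_choice: Side | None = None,
) -> StrategyResult:
    """Run a policy against one block schedule.

    A choice is correct iff it equals the scheduled side for that trial, and
    correct choices are rewarded (feeding the policy's reward history).
    Deterministic for the non-RANDOM policies once the first choice is fixed;
    ``first_choice`` overrides the seeded uniform first draw.
    """
    sides = tuple(schedule)
    if not sides:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(0 if seed is None else seed)
    state = PolicyState()
    choices: list[Side] = []
    n_correct = 0
    history_dependent = policy in (
        Policy.WIN_STAY, Policy.WIN_SHIFT, Policy.SPONT_ALTERNATE
    )
    for t, cued in enumerate(sides):
        if t == 0 and first_choice is not None and history_dependent:
            choice = first_choice
        else:
            choice = policy_choice(policy, state, rng)
        correct = choice is cued
        state.update(choice, rewarded=correct)
        choices.append(choice)
        n_correct += correct
    return StrategyResult(
        policy_name=policy.value,
        percent_correct=100.0 * n_correct / len(sides),
        per_trial_choices=tuple(choices),
    )


def _simulate_policy_matrix(
    policy: Policy,
    x: np.ndarray,
    rng: np.random.Generator,
    first_choices: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised counterpart of :func:`simulate_strategy`.

    ``x`` is an ``(n_sequences, n_trials)`` 0/1 schedule matrix; returns the
    percent correct per sequence.  Trace-equivalent to the scalar simulator
    for the deterministic policies given the same first choices.
    """
    ns, n = x.shape
    if policy is Policy.ALWAYS_LEFT:
        choice = np.zeros_like(x)
    elif policy is Policy.ALWAYS_RIGHT:
        choice = np.ones_like(x)
    elif policy is Policy.RANDOM:
        choice = rng.integers(0, 2, size=(ns, n), dtype=np.int8)
    else:
        choice = np.zeros_like(x)
        if first_choices is None:
            first_choices = rng.integers(0, 2, size=ns, dtype=np.int8)
        choice[:, 0] = first_choices
        last_choice = first_choices.astype(np.int8).copy()
        # -1 encodes "no reward yet"
        last_rew = np.where(last_choice == x[:, 0], last_choice, -1).astype(np.int8)
        for t in range(1, n):
            anchor = np.where(last_rew >= 0, last_rew, last_choice)
            if policy is Policy.WIN_STAY:
                c = anchor
            elif policy is Policy.WIN_SHIFT:
                c = 1 - anchor
            elif policy is Policy.SPONT_ALTERNATE:
                c = 1 - last_choice
            else:  # pragma: no cover
                raise ValueError(policy)
            c = c.astype(np.int8)
            choice[:, t] = c
            rewarded = c == x[:, t]
            last_rew = np.where(rewarded, c, last_rew)
            last_choice = c
    return 100.0 * (choice == x).mean(axis=1)


@dataclass(frozen=True)
class StrategyAudit:
    """Mean per-policy scores across session lengths plus the certification flag."""

    table: pd.DataFrame  # columns: policy, session_length, mean_pct_correct
    ceiling: float
    certified: bool
    max_mean_pct_correct: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def audit_generator(
    constraints: SequenceConstraints | None = None,
    session_lengths: Iterable[int] = (10, 15, 20, 25),
    n_sequences: int = 10_000,
    seed: int | None = None,
    ceiling: float = 60.0,
    policies: Sequence[Policy] = ALL_POLICIES,
) -> StrategyAudit:
    """Certify the schedule generator against the null-strategy battery.

    For each session length, ``n_sequences`` accepted schedules are generated
    and every policy is simulated on each; the generator is certified iff the
    maximum mean percent correct over all policy x length cells stays at or
    below ``ceiling``.
    """
    lengths = list(session_lengths)
    if not lengths:
        raise ValueError("session_lengths must be non-empty")
    ss = np.random.SeedSequence(0 if seed is None else seed)
    rows = []
    for length, child in zip(lengths, ss.spawn(len(lengths))):
        rng = np.random.default_rng(child)
        x = sample_accepted_matrix(n_sequences, length, constraints, rng=rng)
        for policy in policies:
            pct = _simulate_policy_matrix(policy, x, rng)
            rows.append(
                {
                    "policy": policy.value,
                    "session_length": length,
                    "mean_pct_correct": float(pct.mean()),
                }
            )
    table = pd.DataFrame(rows)
    max_mean = float(table["mean_pct_correct"].max())
    return StrategyAudit(
        table=table,
        ceiling=ceiling,
        certified=max_mean <= ceiling,
        max_mean_pct_correct=max_mean,
    )


def compliance(
    responses: Sequence[Side],
    outcomes: Sequence[bool],
    policy: Policy,
    seed: int | None = None,
) -> float:
    """Percent of responses 2..n matching a policy seeded by the first response.

    The policy's state is initialised from the animal's observed first
    response (and whether it was rewarded); each later trial is predicted
    from the *actual* choice/reward history up to that point, so one deviant
    response does not cascade through the rest of the block.
    """
    responses = list(responses)
    outcomes = list(outcomes)
    if len(responses) != len(outcomes):
        raise ValueError("responses and outcomes must have the same length")
    if len(responses) < 2:
        raise ValueError("need at least 2 trials to score compliance")
    rng = np.random.default_rng(0 if seed is None else seed)
    state = PolicyState()
    state.update(responses[0], rewarded=bool(outcomes[0]))
    n_match = 0
    for t in range(1, len(responses)):
        predicted = policy_choice(policy, state, rng)
        n_match += predicted is responses[t]
        state.update(responses[t], rewarded=bool(outcomes[t]))
    return 100.0 * n_match / (len(responses) - 1)
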