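"""Virtual rat: a stochastic subject with the statistical structure real
animals show in this task.

Per-trial choice accuracy follows a saturating learning curve over training
days, p(day) = p_start + (p_asymptote - p_start) * (1 - exp(-learning_rate *
day)).  Reaction times are log-normal — positive, right-skewed, unimodal —
parameterised by their *mode* (which grows with maze length over phases 5-7,
in the 1-2 s range once the association is learned) and an outcome-specific
log-scale spread, narrower on correct than on incorrect trials.  On a small
fraction of trials the animal times out, and on another fraction it lapses
into a cue-ignoring strategy (spontaneous alternation by default) instead of
answering the cue.

The default training calendar covers 42 days: 10 days of phase 1, 4 days
each for phases 2-4, 6 days each for phases 5-6, and 8 days of phase 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .engine import SessionRecord, run_session, write_session_jsonl
from .phases import PhaseConfig, phase_config
from .schedule import SequenceConstraints, Side
from .strategies import Policy, PolicyState, policy_choice

__all__ = [
    "SubjectParams",
    "VirtualRat",
    "accuracy_on_day",
    "DEFAULT_TRAINING_PLAN",
    "default_hint_fraction",
    "hint_delay_for_day",
    "simulate_training",
    "write_training_logs",
]

DEFAULT_RT_MODES: dict[int, int] = {
    1: 800, 2: 900, 3: 1000, 4: 1100, 5: 1200, 6: 1500, 7: 1800,
}

# (phase, days in phase): 10 + 4*3 + 6 + 6 + 8 = 42 training days
DEFAULT_TRAINING_PLAN: tuple[tuple[int, int], ...] = (
    (1, 10), (2, 4), (3, 4), (4, 4), (5, 6), (6, 6), (7, 8),
)


@dataclass(frozen=True)
class SubjectParams:
    """Behavioural parameters of one virtual animal.

    ``rt_sigma_correct`` < ``rt_sigma_incorrect`` encodes that an animal that
    knows the task responds consistently when right, while wrong trials mix
    very fast strategy-driven responses with slow distracted ones.
    """

    learning_rate: float = 0.065  # per training day
    p_start: float = 0.55
    p_asymptote: float = 0.90
    rt_mode_ms_per_phase: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_RT_MODES)
    )
    rt_sigma_correct: float = 0.25
    rt_sigma_incorrect: float = 0.45
    p_timeout: float = 0.02
    p_strategy_lapse: float = 0.06
    lapse_policy: Policy = Policy.SPONT_ALTERNATE
    iti_mode_ms: int = 2500
    iti_sigma: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.p_start <= self.p_asymptote <= 1.0:
            raise ValueError("need 0.5 <= p_start <= p_asymptote <= 1")
        if not self.rt_sigma_correct < self.rt_sigma_incorrect:
            raise ValueError("rt_sigma_correct must be < rt_sigma_incorrect")
        modes = [self.rt_mode_ms_per_phase.get(p) for p in (5, 6, 7)]
        if any(m is None for m in modes) or not (modes[0] <= modes[1] <= modes[2]):
            raise ValueError("rt modes must be non-decreasing over phases 5-7")
        if not (0 <= self.p_timeout < 1 and 0 <= self.p_strategy_lapse < 1):
            raise ValueError("probabilities must lie in [0, 1)")


def accuracy_on_day(day: int | float, params: SubjectParams) -> float:
    """Probability of a cue-driven (non-lapse, non-timeout) correct choice."""
    return params.p_start + (params.p_asymptote - params.p_start) * (
        1.0 - np.exp(-params.learning_rate * day)
    )


def _lognormal_from_mode(
    rng: np.random.Generator, mode_ms: float, sigma: float
) -> float:
    # mode of lognormal(mu, sigma) is exp(mu - sigma^2) => mu = ln(mode) + sigma^2
    mu = np.log(mode_ms) + sigma**2
    return float(rng.lognormal(mu, sigma))


class VirtualRat:
    """Stateful subject usable directly as an engine callback.

    ``day`` selects the point on the learning curve; the lapse policy's
    reward history is carried within a block and reset by
    :meth:`reset_block` (the engine calls it at every block start).  The rat
    infers its own reward from the cue it was shown, which is exact outside
    hint trials.
    """

    def __init__(self, params: SubjectParams | None = None, day: int = 1,
                 rng: np.random.Generator | None = None):
        self.params = params or SubjectParams()
        self.day = day
        self.rng = rng if rng is not None else np.random.default_rng(self.params.seed)
        self._lapse_state = PolicyState()

    def reset_block(self) -> None:
        self._lapse_state = PolicyState()

    def sample_iti(self) -> float:
        return _lognormal_from_mode(
            self.rng, self.params.iti_mode_ms, self.params.iti_sigma
        )

    def __call__(
        self, cued_side: Side, phase: PhaseConfig
    ) -> tuple[Side, float] | None:
        p = self.params
        u = self.rng.random()
        if u < p.p_timeout:
            return None  # no choice made; lapse-policy state unchanged
        if u < p.p_timeout + p.p_strategy_lapse:
            choice = policy_choice(p.lapse_policy, self._lapse_state, self.rng)
        else:
            p_corr = accuracy_on_day(self.day, p)
            choice = (
                cued_side if self.rng.random() < p_corr else cued_side.complement
            )
        correct = choice is cued_side
        self._lapse_state.update(choice, rewarded=correct)
        mode = p.rt_mode_ms_per_phase.get(phase.phase, 1500)
        sigma = p.rt_sigma_correct if correct else p.rt_sigma_incorrect
        for _ in range(100):  # truncate at timeout by resampling
            latency = _lognormal_from_mode(self.rng, mode, sigma)
            if latency < phase.timeout_ms:
                return choice, latency
        return None


def default_hint_fraction(phase: int, day_in_phase: int) -> float:
    """Fraction of hint trials per phase/day.

    Hints guide the animal heavily on the first two days of phase 1 (where
    reward follows the cue automatically on most trials), taper for the rest
    of phase 1, linger at a low rate in phase 2, and vanish afterwards.
    """
    if phase == 1:
        return 0.9 if day_in_phase <= 2 else 0.3
    if phase == 2:
        return 0.15
    return 0.0


def hint_delay_for_day(day_in_phase: int, n_days: int, max_delay_ms: int = 2000) -> int:
    """Linear cue-to-hint delay ramp, 0 ms on day 1 up to ``max_delay_ms``."""
    if n_days <= 1:
        return max_delay_ms
    frac = (day_in_phase - 1) / (n_days - 1)
    return int(round(min(1.0, frac) * max_delay_ms))


def simulate_training(
    params: SubjectParams | None = None,
    plan: Sequence[tuple[int, int]] = DEFAULT_TRAINING_PLAN,
    animal_id: str = "sim",
    seed: int | None = None,
    constraints: SequenceConstraints | None = None,
) -> list[SessionRecord]:
    """Simulate a full training course: one session per day along ``plan``.

    ``plan`` is a sequence of (phase, n_days).  Deterministic given ``seed``
    (defaulting to ``params.seed``): the same seed reproduces the identical
    event logs end-to-end.
    """
    params = params or SubjectParams()
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    sessions: list[SessionRecord] = []
    day = 0
    for phase_num, n_days in plan:
        for day_in_phase in range(1, n_days + 1):
            day += 1
            cfg = phase_config(phase_num)
            if cfg.hint_enabled and phase_num == 1:
                cfg = phase_config(
                    phase_num,
                    hint_delay_ms=hint_delay_for_day(day_in_phase, n_days),
                )
            child = master.spawn(1)[0]
            rat_seed, session_seed = (
                int(v % (2**31)) for v in child.generate_state(2)
            )
            rat = VirtualRat(params, day=day, rng=np.random.default_rng(rat_seed))
            sessions.append(
                run_session(
                    cfg,
                    rat,
                    seed=session_seed,
                    constraints=constraints,
                    hint_fraction=default_hint_fraction(phase_num, day_in_phase),
                    iti_ms=rat.sample_iti,
                    animal_id=animal_id,
                    day=day,
                )
            )
    return sessions


def write_training_logs(
    out_dir: str | Path,
    n_animals: int = 4,
    params: SubjectParams | None = None,
    plan: Sequence[tuple[int, int]] = DEFAULT_TRAINING_PLAN,
    seed: int = 0,
) -> list[Path]:
    """Write one JSONL event log per animal-day under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or SubjectParams()
    paths = []
    for a in range(n_animals):
        animal = f"rat{a + 1}"
        sessions = simulate_training(
            params, plan=plan, animal_id=animal, seed=seed + a
        )
        for s in sessions:
            p = out_dir / f"{animal}_day{s.day:02d}.jsonl"
            write_session_jsonl(s, p)
            paths.append(p)
    return paths
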