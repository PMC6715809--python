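"""Discrete-event trial state machine and the canonical JSONL event log.

A trial starts when the nose-poke sensor fires, which triggers the cue tone.
It ends when the subject crosses a reward-area sensor or when the phase's
maximum trial time elapses.  Correct pre-hint choices dispense the phase's
full pellet reward; on hint trials a single guidance pellet is dispensed at
the cued area once the hint delay passes without a response, and a response
that merely follows the hint earns nothing further.  Timestamps are integer
milliseconds on a simulated session clock; the event log is lossless — the
per-trial records can be reconstructed from it exactly.

The subject is any callable ``(cued_side, phase_cfg) -> (Side, latency_ms) |
None`` (None meaning no response before timeout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .phases import PhaseConfig, phase_config
from .schedule import BlockSchedule, SequenceConstraints, Side, generate_sequence

__all__ = [
    "EventKind",
    "Outcome",
    "TrialEvent",
    "TrialRecord",
    "SessionRecord",
    "run_trial",
    "run_block",
    "run_session",
    "records_from_events",
    "write_session_jsonl",
    "read_session_jsonl",
]

SubjectCallback = Callable[[Side, PhaseConfig], "tuple[Side, float] | None"]


class EventKind(str, Enum):
    NOSE_POKE = "NOSE_POKE"
    CUE_ON = "CUE_ON"
    SENSOR_LEFT = "SENSOR_LEFT"
    SENSOR_RIGHT = "SENSOR_RIGHT"
    FEEDER_DISPENSE = "FEEDER_DISPENSE"
    HINT_DISPENSE = "HINT_DISPENSE"
    TIMEOUT = "TIMEOUT"
    TRIAL_END = "TRIAL_END"


class Outcome(str, Enum):
    CORRECT = "CORRECT"
    INCORRECT = "INCORRECT"
    TIMEOUT = "TIMEOUT"


@dataclass(frozen=True)
class TrialEvent:
    t_ms: int
    kind: EventKind
    payload: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    cued_side: Side
    chosen_side: Side | None
    reaction_time_ms: int | None
    pellets: int
    outcome: Outcome
    is_hint_trial: bool


@dataclass
class SessionRecord:
    """One day's four blocks of trials plus the full tagged event stream."""

    phase_cfg: PhaseConfig
    seed: int
    animal_id: str = "sim"
    day: int = 1
    schedules: list[BlockSchedule] = field(default_factory=list)
    blocks: list[list[TrialRecord]] = field(default_factory=list)
    # (block_index, trial_index, event)
    events: list[tuple[int, int, TrialEvent]] = field(default_factory=list)

    @property
    def trials(self) -> list[TrialRecord]:
        return [t for block in self.blocks for t in block]


def run_trial(
    cued_side: Side,
    phase: PhaseConfig,
    subject: SubjectCallback,
    t0: int = 0,
    trial_index: int = 0,
    is_hint: bool = False,
) -> tuple[TrialRecord, list[TrialEvent]]:
    """Execute one trial and emit its event stream.

    ``is_hint`` marks a hint trial: if the subject has not responded by
    ``hint_delay_ms`` a single pellet drops at the cued area; a correct
    response *before* the hint still earns the full reward.
    """
    response = subject(cued_side, phase)
    hint_active = is_hint and phase.hint_enabled
    events: list[TrialEvent] = [
        TrialEvent(t0, EventKind.NOSE_POKE),
        TrialEvent(
            t0,
            EventKind.CUE_ON,
            {"tone_hz": phase.tone_for(cued_side), "hint": bool(hint_active)},
        ),
    ]
    if response is not None:
        chosen, latency = response
        latency = int(round(latency))
        if latency < 0:
            raise ValueError("subject latency must be >= 0")
        if latency >= phase.timeout_ms:
            response = None  # too slow: the clock wins
    pellets = 0
    if response is None:
        hint_fired = hint_active and phase.hint_delay_ms < phase.timeout_ms
        if hint_fired:
            events.append(
                TrialEvent(
                    t0 + phase.hint_delay_ms,
                    EventKind.HINT_DISPENSE,
                    {"side": cued_side.letter, "pellets": 1},
                )
            )
            pellets = 1
        t_end = t0 + phase.timeout_ms
        events.append(TrialEvent(t_end, EventKind.TIMEOUT))
        events.append(TrialEvent(t_end, EventKind.TRIAL_END))
        record = TrialRecord(
            trial_index, cued_side, None, None, pellets, Outcome.TIMEOUT, is_hint
        )
        return record, events

    chosen, latency = response
    latency = int(round(latency))
    hint_fired = hint_active and phase.hint_delay_ms < latency
    if hint_fired:
        events.append(
            TrialEvent(
                t0 + phase.hint_delay_ms,
                EventKind.HINT_DISPENSE,
                {"side": cued_side.letter, "pellets": 1},
            )
        )
        pellets += 1
    t_resp = t0 + latency
    sensor = (
        EventKind.SENSOR_LEFT if chosen is Side.LEFT else EventKind.SENSOR_RIGHT
    )
    events.append(TrialEvent(t_resp, sensor))
    correct = chosen is cued_side
    if correct and not hint_fired:
        events.append(
            TrialEvent(
                t_resp,
                EventKind.FEEDER_DISPENSE,
                {"side": cued_side.letter, "pellets": phase.reward_pellets},
            )
        )
        pellets += phase.reward_pellets
    events.append(TrialEvent(t_resp, EventKind.TRIAL_END))
    record = TrialRecord(
        trial_index,
        cued_side,
        chosen,
        latency,
        pellets,
        Outcome.CORRECT if correct else Outcome.INCORRECT,
        is_hint,
    )
    return record, events


def run_block(
    schedule: BlockSchedule | Sequence[Side],
    phase: PhaseConfig,
    subject: SubjectCallback,
    start_t: int = 0,
    hint_mask: Sequence[bool] | None = None,
    iti_ms: Callable[[], float] | float = 2000,
) -> tuple[list[TrialRecord], list[tuple[int, TrialEvent]], int]:
    """Run every trial of one block in schedule order.

    The next trial's nose-poke follows the previous trial's end by the
    inter-trial interval ``iti_ms`` (a constant or a 0-arg sampler): the
    subject may re-initiate immediately after a trial ends.  Returns the
    records, the events tagged with trial indices, and the block end time.
    """
    sides = tuple(schedule)
    if len(sides) != phase.trials_per_block:
        raise ValueError(
            f"schedule length {len(sides)} != trials_per_block "
            f"{phase.trials_per_block}"
        )
    if hint_mask is not None and len(hint_mask) != len(sides):
        raise ValueError("hint_mask length mismatch")
    records: list[TrialRecord] = []
    tagged: list[tuple[int, TrialEvent]] = []
    t = int(start_t)
    for i, cued in enumerate(sides):
        is_hint = bool(hint_mask[i]) if hint_mask is not None else False
        rec, events = run_trial(cued, phase, subject, t0=t, trial_index=i,
                                is_hint=is_hint)
        records.append(rec)
        tagged.extend((i, ev) for ev in events)
        gap = iti_ms() if callable(iti_ms) else iti_ms
        t = events[-1].t_ms + max(0, int(round(gap)))
    return records, tagged, t


def run_session(
    phase: PhaseConfig | int,
    subject: SubjectCallback,
    seed: int,
    constraints: SequenceConstraints | None = None,
    hint_fraction: float = 0.0,
    iti_ms: Callable[[], float] | float = 2000,
    animal_id: str = "sim",
    day: int = 1,
) -> SessionRecord:
    """Run one full session: ``blocks_per_session`` freshly scheduled blocks.

    Each block gets its own schedule seed (spawned from ``seed`` and logged
    in the BlockSchedule for audit replay).  ``hint_fraction`` is the
    per-trial probability of a hint trial when the phase allows hints.
    """
    cfg = phase if isinstance(phase, PhaseConfig) else phase_config(phase)
    ss = np.random.SeedSequence(seed)
    block_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.blocks_per_session)]
    hint_rng = np.random.default_rng(ss.spawn(1)[0])
    session = SessionRecord(phase_cfg=cfg, seed=seed, animal_id=animal_id, day=day)
    t = 0
    for b, bseed in enumerate(block_seeds):
        sched = generate_sequence(cfg.trials_per_block, constraints, seed=bseed)
        mask = None
        if cfg.hint_enabled and hint_fraction > 0:
            mask = hint_rng.random(cfg.trials_per_block) < hint_fraction
        reset = getattr(subject, "reset_block", None)
        if callable(reset):
            reset()
        records, tagged, t = run_block(
            sched, cfg, subject, start_t=t, hint_mask=mask, iti_ms=iti_ms
        )
        session.schedules.append(sched)
        session.blocks.append(records)
        session.events.extend((b, i, ev) for i, ev in tagged)
    return session


# ---------------------------------------------------------------------------
# Log reconstruction and JSONL serialization

def records_from_events(
    events: Sequence[TrialEvent], tone_map=None
) -> TrialRecord:
    """Rebuild one trial's record from its event stream.

    The log is the source of truth for scoring: cued side comes from the cue
    tone, the choice from the first reward-area sensor crossing, the
    reaction time from sensor minus nose-poke timestamps, and pellets from
    the dispense events.
    """
    from .phases import DEFAULT_TONE_MAP

    tone_map = tone_map or DEFAULT_TONE_MAP
    t_poke = None
    cued = None
    is_hint = False
    chosen = None
    rt = None
    pellets = 0
    timed_out = False
    for ev in events:
        if ev.kind is EventKind.NOSE_POKE and t_poke is None:
            t_poke = ev.t_ms
        elif ev.kind is EventKind.CUE_ON:
            cued = tone_map[ev.payload["tone_hz"]]
            is_hint = bool(ev.payload.get("hint", False))
        elif ev.kind in (EventKind.SENSOR_LEFT, EventKind.SENSOR_RIGHT):
            if chosen is None:
                chosen = (
                    Side.LEFT if ev.kind is EventKind.SENSOR_LEFT else Side.RIGHT
                )
                rt = ev.t_ms - t_poke
        elif ev.kind in (EventKind.FEEDER_DISPENSE, EventKind.HINT_DISPENSE):
            pellets += int(ev.payload["pellets"])
        elif ev.kind is EventKind.TIMEOUT:
            timed_out = True
    if cued is None or t_poke is None:
        raise ValueError("incomplete trial event stream")
    if timed_out and chosen is None:
        outcome = Outcome.TIMEOUT
    elif chosen is cued:
        outcome = Outcome.CORRECT
    else:
        outcome = Outcome.INCORRECT
    return TrialRecord(0, cued, chosen, rt, pellets, outcome, is_hint)


def write_session_jsonl(session: SessionRecord, path: str | Path) -> None:
    """Write a session as JSON-lines: one header line, then one line per event."""
    cfg = session.phase_cfg
    header = {
        "kind": "SESSION_HEADER",
        "phase": cfg.phase,
        "animal": session.animal_id,
        "day": session.day,
        "seed": session.seed,
        "config": {
            "trials_per_block": cfg.trials_per_block,
            "blocks_per_session": cfg.blocks_per_session,
            "pellet_threshold": cfg.pellet_threshold,
            "reward_pellets": cfg.reward_pellets,
            "timeout_ms": cfg.timeout_ms,
            "hint_enabled": cfg.hint_enabled,
            "hint_delay_ms": cfg.hint_delay_ms,
            "central_arm_cm": cfg.central_arm_cm,
            "tone_map": {str(hz): s.letter for hz, s in cfg.tone_map.items()},
        },
        "block_seeds": [s.seed for s in session.schedules],
    }
    with Path(path).open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for block, trial, ev in session.events:
            fh.write(
                json.dumps(
                    {
                        "t_ms": ev.t_ms,
                        "trial": trial,
                        "block": block,
                        "kind": ev.kind.value,
                        "payload": ev.payload,
                    }
                )
                + "\n"
            )


def read_session_jsonl(path: str | Path) -> SessionRecord:
    """Read a JSONL event log back into a SessionRecord.

    Trial records are reconstructed from the events (see
    :func:`records_from_events`); block schedules are rebuilt from the
    logged per-block seeds when present.
    """
    lines = Path(path).read_text().splitlines()
    header = json.loads(lines[0])
    if header.get("kind") != "SESSION_HEADER":
        raise ValueError("missing session header line")
    c = header["config"]
    tone_map = {int(hz): Side.from_letter(s) for hz, s in c["tone_map"].items()}
    cfg = PhaseConfig(
        phase=header["phase"],
        trials_per_block=c["trials_per_block"],
        blocks_per_session=c["blocks_per_session"],
        pellet_threshold=c["pellet_threshold"],
        reward_pellets=c["reward_pellets"],
        timeout_ms=c["timeout_ms"],
        hint_enabled=c["hint_enabled"],
        hint_delay_ms=c["hint_delay_ms"],
        central_arm_cm=c["central_arm_cm"],
        tone_map=tone_map,
    )
    session = SessionRecord(
        phase_cfg=cfg,
        seed=header.get("seed", 0),
        animal_id=header.get("animal", "sim"),
        day=header.get("day", 1),
    )
    per_trial: dict[tuple[int, int], list[TrialEvent]] = {}
    for line in lines[1:]:
        d = json.loads(line)
        ev = TrialEvent(d["t_ms"], EventKind(d["kind"]), d.get("payload", {}))
        session.events.append((d["block"], d["trial"], ev))
        per_trial.setdefault((d["block"], d["trial"]), []).append(ev)
    for bseed in header.get("block_seeds", []):
        session.schedules.append(
            generate_sequence(cfg.trials_per_block, seed=bseed)
        )
    n_blocks = max((b for b, _ in per_trial), default=-1) + 1
    for b in range(n_blocks):
        trials = sorted(t for bb, t in per_trial if bb == b)
        block = []
        for t in trials:
            rec = records_from_events(per_trial[(b, t)], tone_map)
            block.append(
                TrialRecord(
                    t,
                    rec.cued_side,
                    rec.chosen_side,
                    rec.reaction_time_ms,
                    rec.pellets,
                    rec.outcome,
                    rec.is_hint_trial,
                )
            )
        session.blocks.append(block)
    return session
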