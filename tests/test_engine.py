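"""Trial state machine: event streams, block/session composition, and the
lossless JSONL event log."""

import numpy as np
import pytest

from morphmaze import (
    EventKind,
    Outcome,
    Side,
    generate_sequence,
    phase_config,
    read_session_jsonl,
    records_from_events,
    run_block,
    run_session,
    run_trial,
    write_session_jsonl,
)
from conftest import make_session

L, R = Side.LEFT, Side.RIGHT


def fixed_subject(side=None, latency=800.0):
    """Subject answering the cued side (or a fixed side) at a fixed latency."""

    def cb(cued, phase):
        return (side or cued), latency

    return cb


def silent_subject(cued, phase):
    return None


class TestRunTrial:
    def test_correct_phase1_trial_dispenses_three_pellets(self):
        cfg = phase_config(1)
        rec, events = run_trial(L, cfg, fixed_subject(latency=800))
        assert rec.outcome is Outcome.CORRECT
        assert rec.pellets == 3
        assert rec.reaction_time_ms == 800
        kinds = [e.kind for e in events]
        assert kinds == [
            EventKind.NOSE_POKE,
            EventKind.CUE_ON,
            EventKind.SENSOR_LEFT,
            EventKind.FEEDER_DISPENSE,
            EventKind.TRIAL_END,
        ]

    def test_silent_subject_times_out(self):
        cfg = phase_config(7)
        rec, events = run_trial(R, cfg, silent_subject, t0=500)
        assert rec.outcome is Outcome.TIMEOUT
        assert rec.chosen_side is None and rec.reaction_time_ms is None
        assert rec.pellets == 0
        timeout = next(e for e in events if e.kind is EventKind.TIMEOUT)
        assert timeout.t_ms == 500 + cfg.timeout_ms

    def test_hint_trial_followed_after_hint_earns_one_pellet(self):
        cfg = phase_config(1, hint_delay_ms=1000)
        rec, events = run_trial(
            L, cfg, fixed_subject(latency=2500), is_hint=True
        )
        assert rec.outcome is Outcome.CORRECT  # sensor truth
        assert rec.pellets == 1  # hint pellet only: reward scoring calls it wrong
        kinds = [e.kind for e in events]
        assert EventKind.HINT_DISPENSE in kinds
        assert EventKind.FEEDER_DISPENSE not in kinds

    def test_hint_trial_answered_before_hint_earns_full_reward(self):
        cfg = phase_config(1, hint_delay_ms=2000)
        rec, events = run_trial(L, cfg, fixed_subject(latency=900), is_hint=True)
        assert rec.pellets == cfg.reward_pellets == 3
        assert all(e.kind is not EventKind.HINT_DISPENSE for e in events)

    def test_incorrect_choice_no_reward(self):
        cfg = phase_config(5)
        rec, _ = run_trial(L, cfg, fixed_subject(side=R, latency=1200))
        assert rec.outcome is Outcome.INCORRECT
        assert rec.pellets == 0

    def test_negative_latency_rejected(self):
        with pytest.raises(ValueError):
            run_trial(L, phase_config(1), fixed_subject(latency=-1))

    def test_overlong_latency_becomes_timeout(self):
        cfg = phase_config(1)
        rec, _ = run_trial(L, cfg, fixed_subject(latency=cfg.timeout_ms + 1))
        assert rec.outcome is Outcome.TIMEOUT


def random_subject(seed):
    rng = np.random.default_rng(seed)

    def cb(cued, phase):
        u = rng.random()
        if u < 0.1:
            return None
        side = Side(int(rng.integers(0, 2)))
        return side, float(rng.uniform(0, phase.timeout_ms * 1.2))

    return cb


class TestEventInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_event_stream_well_formed_for_arbitrary_subject(self, seed):
        cfg = phase_config(3)
        subject = random_subject(seed)
        schedule = generate_sequence(cfg.trials_per_block, seed=seed)
        records, tagged, _ = run_block(schedule, cfg, subject,
                                       hint_mask=[True] * len(schedule))
        by_trial = {}
        for i, ev in tagged:
            by_trial.setdefault(i, []).append(ev)
        for i, events in by_trial.items():
            ts = [e.t_ms for e in events]
            assert ts == sorted(ts)  # non-decreasing within a trial
            kinds = [e.kind for e in events]
            assert kinds.count(EventKind.NOSE_POKE) == 1
            assert kinds.count(EventKind.TRIAL_END) == 1
            assert kinds[-1] is EventKind.TRIAL_END
            assert kinds.index(EventKind.CUE_ON) > kinds.index(EventKind.NOSE_POKE) or (
                events[kinds.index(EventKind.CUE_ON)].t_ms
                >= events[kinds.index(EventKind.NOSE_POKE)].t_ms
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_records_reconstructed_from_events_match(self, seed):
        cfg = phase_config(2)
        schedule = generate_sequence(cfg.trials_per_block, seed=seed)
        records, tagged, _ = run_block(
            schedule, cfg, random_subject(seed), hint_mask=[seed % 2 == 0] * 15
        )
        by_trial = {}
        for i, ev in tagged:
            by_trial.setdefault(i, []).append(ev)
        for rec in records:
            rebuilt = records_from_events(by_trial[rec.trial_index], cfg.tone_map)
            assert rebuilt.cued_side is rec.cued_side
            assert rebuilt.chosen_side is rec.chosen_side
            assert rebuilt.reaction_time_ms == rec.reaction_time_ms
            assert rebuilt.pellets == rec.pellets
            assert rebuilt.outcome is rec.outcome
            assert rebuilt.is_hint_trial == rec.is_hint_trial

    def test_reaction_time_equals_sensor_minus_nosepoke(self):
        cfg = phase_config(6)
        rec, events = run_trial(R, cfg, fixed_subject(latency=1234), t0=99_000)
        poke = next(e for e in events if e.kind is EventKind.NOSE_POKE)
        sensor = next(
            e for e in events
            if e.kind in (EventKind.SENSOR_LEFT, EventKind.SENSOR_RIGHT)
        )
        assert rec.reaction_time_ms == sensor.t_ms - poke.t_ms == 1234


class TestSessions:
    def test_phase7_session_has_100_trials(self):
        s = make_session(7, day=40, seed=1)
        assert len(s.blocks) == 4
        assert len(s.trials) == 100

    def test_phase1_session_has_40_trials(self):
        s = make_session(1, day=1, seed=1)
        assert len(s.trials) == 40

    def test_block_schedule_length_mismatch_raises(self):
        cfg = phase_config(7)
        with pytest.raises(ValueError):
            run_block(generate_sequence(10, seed=0), cfg, fixed_subject())

    def test_trials_start_after_previous_trial_end(self):
        cfg = phase_config(5)
        schedule = generate_sequence(cfg.trials_per_block, seed=3)
        _, tagged, _ = run_block(schedule, cfg, fixed_subject(), iti_ms=1500)
        pokes = [ev.t_ms for i, ev in tagged if ev.kind is EventKind.NOSE_POKE]
        ends = [ev.t_ms for i, ev in tagged if ev.kind is EventKind.TRIAL_END]
        for nxt, end in zip(pokes[1:], ends):
            assert nxt == end + 1500

    def test_jsonl_roundtrip_identity(self, tmp_path):
        s = make_session(2, day=12, seed=77, hint_fraction=0.3, animal_id="rat9")
        path = tmp_path / "s.jsonl"
        write_session_jsonl(s, path)
        back = read_session_jsonl(path)
        assert back.animal_id == "rat9" and back.day == 12
        assert back.phase_cfg == s.phase_cfg
        assert [[r for r in b] for b in back.blocks] == [
            [r for r in b] for b in s.blocks
        ]
        assert [s_.sides for s_ in back.schedules] == [
            s_.sides for s_ in s.schedules
        ]
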