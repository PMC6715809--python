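"""Per-phase task parameters for the seven-stage training protocol.

Training proceeds through seven phases of increasing difficulty.  Phases 1-4
are cue training in the reduced maze (the animal learns to nose-poke, attend
to the tone and commit to a reward area); phases 5-7 add a working-memory
component by moving the maze arms 20, 50 and 80 cm back from the start box.
Blocks grow from 10 trials (phase 1) through 15 (phases 2-5) and 20
(phase 6) to 25 trials (phase 7); every session is four blocks.

Pellet counts per correct trial mirror the scoring thresholds (3 in phase 1,
2 in phases 2-5, 1 in phases 6-7).  Only the phase-1 trial timeout (6 s) is
fixed by the protocol; later phases keep 6 s through phase 5 and then scale
with arm length (8 s, 10 s) because trials lengthen as the maze grows — a
configurable stand-in, overridable per phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .schedule import Side

__all__ = ["PhaseConfig", "DEFAULT_PHASES", "phase_config", "load_phase_overrides"]

DEFAULT_TONE_MAP: dict[int, Side] = {7: Side.LEFT, 14: Side.RIGHT}


@dataclass(frozen=True)
class PhaseConfig:
    phase: int
    trials_per_block: int
    pellet_threshold: int  # pellets required for a reward-scored correct
    reward_pellets: int  # pellets dispensed on a correct (non hint-assisted) choice
    timeout_ms: int
    hint_enabled: bool
    hint_delay_ms: int
    central_arm_cm: int
    blocks_per_session: int = 4
    tone_map: Mapping[int, Side] = field(
        default_factory=lambda: dict(DEFAULT_TONE_MAP)
    )

    def __post_init__(self) -> None:
        if not 1 <= self.phase <= 7:
            raise ValueError("phase must be 1..7")
        if self.trials_per_block < 1 or self.blocks_per_session < 1:
            raise ValueError("trials_per_block and blocks_per_session must be >= 1")
        if self.timeout_ms <= 0:
            raise ValueError("timeout_ms must be positive")
        if set(self.tone_map.values()) != {Side.LEFT, Side.RIGHT}:
            raise ValueError("tone_map must map the two tones to the two sides")

    def tone_for(self, side: Side) -> int:
        for hz, s in self.tone_map.items():
            if s is side:
                return hz
        raise ValueError(f"no tone mapped to {side}")  # pragma: no cover


_DEFAULTS: dict[int, dict] = {
    1: dict(trials_per_block=10, pellet_threshold=3, reward_pellets=3,
            timeout_ms=6000, hint_enabled=True, hint_delay_ms=1000,
            central_arm_cm=0),
    2: dict(trials_per_block=15, pellet_threshold=2, reward_pellets=2,
            timeout_ms=6000, hint_enabled=True, hint_delay_ms=2000,
            central_arm_cm=0),
    3: dict(trials_per_block=15, pellet_threshold=2, reward_pellets=2,
            timeout_ms=6000, hint_enabled=False, hint_delay_ms=0,
            central_arm_cm=0),
    4: dict(trials_per_block=15, pellet_threshold=2, reward_pellets=2,
            timeout_ms=6000, hint_enabled=False, hint_delay_ms=0,
            central_arm_cm=0),
    5: dict(trials_per_block=15, pellet_threshold=2, reward_pellets=2,
            timeout_ms=6000, hint_enabled=False, hint_delay_ms=0,
            central_arm_cm=20),
    6: dict(trials_per_block=20, pellet_threshold=1, reward_pellets=1,
            timeout_ms=8000, hint_enabled=False, hint_delay_ms=0,
            central_arm_cm=50),
    7: dict(trials_per_block=25, pellet_threshold=1, reward_pellets=1,
            timeout_ms=10000, hint_enabled=False, hint_delay_ms=0,
            central_arm_cm=80),
}

DEFAULT_PHASES: dict[int, PhaseConfig] = {
    p: PhaseConfig(phase=p, **kw) for p, kw in _DEFAULTS.items()
}


def phase_config(phase: int, **overrides) -> PhaseConfig:
    """Default configuration for a phase, with keyword overrides."""
    if phase not in DEFAULT_PHASES:
        raise ValueError(f"unknown phase {phase}; expected 1..7")
    base = DEFAULT_PHASES[phase]
    return replace(base, **overrides) if overrides else base


def load_phase_overrides(path: str | Path) -> dict[int, PhaseConfig]:
    """Load per-phase overrides from a YAML file.

    Layout: a top-level ``phases`` mapping of phase number to any subset of
    :class:`PhaseConfig` fields, e.g. ``phases: {7: {timeout_ms: 9000}}``.
    ``tone_map`` values may use side letters ("L"/"R").
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = dict(DEFAULT_PHASES)
    for phase, fields_ in (raw.get("phases") or {}).items():
        phase = int(phase)
        fields_ = dict(fields_ or {})
        if "tone_map" in fields_:
            fields_["tone_map"] = {
                int(hz): Side.from_letter(str(s))
                for hz, s in fields_["tone_map"].items()
            }
        out[phase] = phase_config(phase, **fields_)
    return out
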