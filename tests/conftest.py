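import numpy as np
import pytest

from morphmaze import (
    SequenceConstraints,
    Side,
    SubjectParams,
    VirtualRat,
    run_session,
    trials_frame,
)


@pytest.fixture(scope="session")
def default_constraints() -> SequenceConstraints:
    return SequenceConstraints()


def make_session(phase: int, day: int, seed: int, params: SubjectParams | None = None,
                 hint_fraction: float = 0.0, animal_id: str = "sim"):
    params = params or SubjectParams()
    rat = VirtualRat(params, day=day, rng=np.random.default_rng(seed))
    return run_session(
        phase, rat, seed=seed, hint_fraction=hint_fraction,
        iti_ms=rat.sample_iti, animal_id=animal_id, day=day,
    )


@pytest.fixture(scope="session")
def late_training_frame():
    """Trial frame from well-trained subjects across phases 5-7 (no hints)."""
    sessions = []
    day = 30
    for phase in (5, 6, 7):
        for rep in range(2):
            sessions.append(make_session(phase, day, seed=100 * phase + rep))
            day += 1
    return trials_frame(sessions)


def sides(letters: str) -> list[Side]:
    return [Side.from_letter(ch) for ch in letters]
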