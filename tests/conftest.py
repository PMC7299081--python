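import pytest

from playcog.schema import GameplayEvent, LevelSession, default_schema
from playcog.simulate import Cohort, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A 40-child cohort shared by feature/model tests."""
    return simulate_cohort(SimConfig(n_children=40, seed=7))


@pytest.fixture(scope="session")
def midsize_cohort() -> Cohort:
    """A 200-child cohort at the study's sample size."""
    return simulate_cohort(SimConfig(n_children=200, seed=42))


def make_session(child_id, game_id, level, events, attempted=True, completed=False):
    return LevelSession(
        child_id=child_id,
        game_id=game_id,
        level=level,
        attempted=attempted,
        completed=completed,
        events=[GameplayEvent(t, g, o) for t, g, o in events],
    )


@pytest.fixture
def toy_sessions(schema):
    """One child, hand-written events on the first two games."""
    return [
        make_session("k1", "st", 1, [(500, "tap", "correct"),
                                     (900, "tap", "incorrect"),
                                     (1400, "tap", "correct")]),
        make_session("k1", "st", 2, [], attempted=False),
        make_session("k1", "at", 1, [(100, "tap", "background"),
                                     (2100, "tap", "correct")]),
        make_session("k1", "at", 2, [], attempted=False),
    ]
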