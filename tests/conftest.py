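import numpy as np
import pytest

import lickometry as lk


@pytest.fixture(scope="session")
def week_plan():
    """One 7-day period of 10% ethanol vs water (ethanol RIGHT first)."""
    return lk.make_two_bottle_plan("2024-03-01 10:00:00", [(7, 10.0)])


@pytest.fixture(scope="session")
def swap_plan():
    """Water week, then 3/7/10% ethanol with bottle sides swapped at each
    stage boundary — the standard escalating schedule."""
    return lk.make_two_bottle_plan(
        "2024-01-01 10:00:00", [(7, 0.0), (3, 3.0), (7, 7.0), (28, 10.0)]
    )


@pytest.fixture(scope="session")
def cage_profiles():
    ps = [0.2, 0.4, 0.5, 0.7, 0.9]
    return [
        lk.MouseProfile(tag=f"M{i}", ethanol_preference=p, dark_bout_rate=6.0)
        for i, p in enumerate(ps)
    ]


@pytest.fixture(scope="session")
def week_session(week_plan, cage_profiles):
    """The fixed-seed 5-mouse, 7-day clean margin-mode session used by the
    end-to-end checks (rates sized to give >500 bouts per mouse)."""
    return lk.simulate_session(cage_profiles, week_plan, seed=1234)


@pytest.fixture(scope="session")
def week_results(week_session):
    return lk.recover_bouts(week_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
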