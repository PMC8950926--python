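"""Shared fixtures: simulated sessions built once per test run."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/helpers importable

from rollagait import (
    PathSegment,
    SimulationConfig,
    analyze_session,
    simulate_session,
)


@pytest.fixture(scope="session")
def default_trial():
    """Default 60 s straight walk (seed 1) with ground truth."""
    return simulate_session(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_trial):
    session, _ = default_trial
    return analyze_session(session)


@pytest.fixture(scope="session")
def short_config():
    """A quick 8 s configuration for tests that re-simulate."""
    return SimulationConfig(seed=3, path=(PathSegment(8.0, 0.0),))
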