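"""Shared fixtures: scenario runs are expensive, so each is simulated
once per session and reused by the module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from burstcode import synthgen
from burstcode.pipeline import ScenarioConfig, motivation_analysis, run_scenario

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def chord_report():
    """Full chord-trained hypermouse run (570 cells, 19 FOVs)."""
    return run_scenario(ScenarioConfig("chord_hypermouse", seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def chord_cohort():
    """Raw cohort behind the chord scenario: cells, responses, FOV tables."""
    from burstcode import pipeline as pl

    return pl.simulate_cohort(
        pl.SCENARIOS["chord_hypermouse"]["composition"],
        "two_chord", "Cal520", 19, FIXTURE_SEED,
    )


@pytest.fixture(scope="session")
def bbn_report():
    """BBN-trained hypermouse run (681 cells, 22 FOVs)."""
    return run_scenario(ScenarioConfig("bbn_hypermouse", seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def trained_report():
    """Pooled trained-stage population (1112 cells) tested with the
    trained sound only."""
    return run_scenario(ScenarioConfig("trained_cal520", seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def motivation_result():
    return motivation_analysis(n_replicates=50, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def small_experiment():
    """A small BBN session (4 cells, 24 trials) with a rendered movie."""
    protocol = synthgen.ProtocolConfig(
        paradigm="BBN", n_trials=24, seed=3, start_ms=2000.0
    )
    cells = synthgen.make_population(
        {"NB": 3, "HB": 1}, paradigm="BBN", seed=4, indicator="Cal520"
    )
    return synthgen.simulate_experiment(
        protocol, cells, indicator="Cal520", seed=5, with_movie=True
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
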