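"""Shared fixtures: the default synthetic scenario and its discovery run.

Both are session-scoped — the reference scenario (3 cohorts x 200 samples,
2000 genes, seed 42) is simulated once and the full signature-discovery
pipeline run once, then reused by the derivation, scoring, survival and
acceptance tests.
"""

import numpy as np
import pytest

from miracle import SimulationConfig, run_discovery, simulate_cohorts


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_sim(default_config):
    return simulate_cohorts(default_config)


@pytest.fixture(scope="session")
def discovery(default_sim):
    return run_discovery(default_sim.expression, default_sim.clinical)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
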