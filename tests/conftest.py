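"""Shared fixtures: fixture meshes and the three CI-profile scenario runs.

The scenario runs (baseline SAVR, enlarged-root Y-AAE, TAVR-in-SAVR) are
session-scoped because each integrates three cardiac cycles plus fourteen
residence-time cycles; several test modules interrogate the same runs.
"""

import numpy as np
import pytest

from aortaflow import geometry as G
from aortaflow.pipeline import ScenarioConfig, run_scenario


@pytest.fixture(scope="session")
def pipe_mesh():
    return G.build_fixture_mesh("pipe", (2.0, 20.0), 0.8)


@pytest.fixture(scope="session")
def channel_mesh():
    return G.build_fixture_mesh("channel", (10.0, 2.0), 0.25)


@pytest.fixture(scope="session")
def cavity_mesh():
    return G.build_fixture_mesh("cavity", (5.0, 5.0), 0.5)


@pytest.fixture(scope="session")
def root_mesh_2d():
    params = G.RootParameters(goa_diameter=17.0)
    return G.build_root_mesh(params, 1.6, "2d")


def _scenario(label, scenario, valve_diameter):
    cfg = ScenarioConfig(label=label, scenario=scenario,
                         valve_diameter=valve_diameter, profile="ci")
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def baseline_run():
    """Native 23 mm annulus with a 23 mm surgical valve (17 mm orifice)."""
    return _scenario("baseline", "baseline", 23.0)


@pytest.fixture(scope="session")
def yaae_run():
    """Enlarged root carrying a 29 mm valve (23 mm orifice)."""
    return _scenario("yaae", "yaae", 29.0)


@pytest.fixture(scope="session")
def tavr_run():
    """Funnel insert deployed inside the baseline surgical valve."""
    return _scenario("tavr", "tavr_in_savr", 23.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
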