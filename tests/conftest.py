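"""Shared fixtures: the default scenario and a precomputed performance grid."""

import numpy as np
import pytest

from speedeffort import RunConfig, performance_table


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    """Default scenario configuration."""
    return RunConfig()


@pytest.fixture(scope="session")
def default_env(cfg):
    return cfg.env()


@pytest.fixture(scope="session")
def default_costs(cfg):
    return cfg.costs()


@pytest.fixture(scope="session")
def default_grid(cfg):
    return cfg.grid()


@pytest.fixture(scope="session")
def default_perf(default_env, default_grid):
    """Oracle-mode P_C/DT over the full default grid (cost-independent),
    shared across tests because it is the expensive step."""
    return performance_table(default_env, default_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
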