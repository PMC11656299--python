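"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from ldct_benchmark.sim import SimConfig, simulate_case


@pytest.fixture(scope="session")
def desk_config() -> SimConfig:
    """Minutes-scale simulation configuration shared across the suite."""
    return SimConfig.desk()


@pytest.fixture(scope="session")
def abdomen_pair(desk_config):
    return simulate_case("abdomen", seed=11, config=desk_config)


@pytest.fixture(scope="session")
def chest_pair(desk_config):
    return simulate_case("chest", seed=12, config=desk_config)


@pytest.fixture(scope="session")
def head_pair(desk_config):
    return simulate_case("head", seed=13, config=desk_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
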