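"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import dataclasses

import pytest

from pathsynth import SimulationConfig, simulate_study


SMALL = SimulationConfig(
    n_proteins=40,
    n_kinases=20,
    n_measured=16,
    cascade_size=10,
    cascade_depth=5,
    n_compounds=12,
    seed=7,
)


@pytest.fixture(scope="session")
def small_study():
    """A compact noisy study used by most unit tests."""
    return simulate_study(SMALL)


@pytest.fixture(scope="session")
def noiseless_study():
    """Same layout with zero replicate noise: recovery must be exact."""
    return simulate_study(dataclasses.replace(SMALL, noise_cv=0.0))


@pytest.fixture(scope="session")
def default_study():
    """The full default study conditions."""
    return simulate_study(SimulationConfig(seed=11))
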