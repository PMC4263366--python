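import numpy as np
import pytest

from sugarosp import (
    ThermoConditions,
    ToyEnvironment,
    perturbation_energy_series,
    reference_topology,
    run_sampler,
)


@pytest.fixture(scope="session")
def conditions():
    return ThermoConditions(temperature=300.0)


@pytest.fixture(scope="session")
def ab_reference():
    return reference_topology("ab")


@pytest.fixture(scope="session")
def achiral_env():
    return ToyEnvironment(kind="achiral_bath")


@pytest.fixture(scope="session")
def small_trajectory(ab_reference, achiral_env, conditions):
    """20k-frame achiral reference trajectory shared across unit tests."""
    return run_sampler(ab_reference, achiral_env, 20_000, seed=1234,
                       conditions=conditions)


@pytest.fixture(scope="session")
def long_trajectory(ab_reference, achiral_env, conditions):
    """100k-frame achiral reference trajectory for oracle-agreement checks."""
    return run_sampler(ab_reference, achiral_env, 100_000, seed=20240,
                       conditions=conditions)


@pytest.fixture(scope="session")
def long_perturbation(long_trajectory, ab_reference):
    return perturbation_energy_series(long_trajectory, ab_reference)
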