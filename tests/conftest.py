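import numpy as np
import pytest

from ojip import (
    KineticPreset,
    ScenarioEffect,
    compute_parameter_table,
    default_grid,
    generate_experiment,
)

NEUTRAL3 = {"a": ScenarioEffect(), "b": ScenarioEffect(), "c": ScenarioEffect()}


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def noise_free_preset():
    return KineticPreset(noise_cv=0.0, replicate_sd=0.0)


@pytest.fixture(scope="session")
def small_experiment():
    """2 maturity groups x 3 temperature levels x 5 reps x 2 measurements."""
    scenarios = {
        "26/18": ScenarioEffect(),
        "22/14": ScenarioEffect(d_F0=1.10, d_Fm=0.85, d_IP=0.45),
        "40/32": ScenarioEffect(d_F0=1.20, d_Fm=0.75, d_Kband=0.15),
    }
    return generate_experiment(
        levels=list(scenarios),
        scenarios=scenarios,
        maturity_groups=("0", "X"),
        axis="temperature",
        n_reps=5,
        n_meas=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_params(small_experiment):
    return compute_parameter_table(small_experiment)
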