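import numpy as np
import pytest

from mapk_rewire import HillParams, KineticParams, PopulationSpec, Scenario


@pytest.fixture
def default_params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def functional_scenario() -> Scenario:
    return Scenario()


@pytest.fixture
def hill_truth() -> HillParams:
    return HillParams(A=0.1, B=1.0, C=0.5, n=1.5)


@pytest.fixture
def small_spec() -> PopulationSpec:
    """Fast population spec for tests that do not need 10k events."""
    return PopulationSpec(n_events=2000, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
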