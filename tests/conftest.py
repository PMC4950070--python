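import numpy as np
import pytest

import surrometa as sm


@pytest.fixture(scope="session")
def rrms():
    """Model-ready effect rows for the 13-study RRMS example."""
    return sm.rrms_effects()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def quick_spec(factory, seed=0, iterations=14_000, burn_in=5_000):
    """Reduced-iteration model spec for unit tests."""
    return factory(seed=seed, iterations=iterations, burn_in=burn_in)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small, well-behaved synthetic trivariate meta-analysis."""
    scenario = sm.SimScenario(structure="sequential", family="normal", n_studies=8, seed=42)
    return sm.simulate_dataset(scenario)
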