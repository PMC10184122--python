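"""Shared fixtures: small seeded ensembles and hypothesis settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glueforce.landscape import LandscapeModel
from glueforce.simulate import PullingProtocol, generate_work_ensemble

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model() -> LandscapeModel:
    return LandscapeModel()


@pytest.fixture(scope="session")
def fast_protocol() -> PullingProtocol:
    """A quick pull (2.5 Å/ns) for unit tests; the production rate is 0.5."""
    return PullingProtocol(rate=2.5, n_traj=12, seed=101)


@pytest.fixture(scope="session")
def shielded_ensemble(model, fast_protocol):
    return generate_work_ensemble(model.with_shielding(1.0), fast_protocol)


@pytest.fixture(scope="session")
def unshielded_ensemble(model, fast_protocol):
    return generate_work_ensemble(model.with_shielding(0.0), fast_protocol)


@pytest.fixture(scope="session")
def gaussian_works():
    """Synthetic Gaussian work ensemble with known analytic free energy."""
    rng = np.random.default_rng(42)
    mu, sigma = 5.0, 1.0
    return rng.normal(mu, sigma, size=400), mu, sigma
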