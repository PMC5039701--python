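import numpy as np
import pytest

from tdjgl import (
    MultiPlatformData,
    ObjectiveConfig,
    ScenarioConfig,
    compute_sample_covariances,
    fit_tdjgl,
    sample_scenario,
)


@pytest.fixture(scope="session")
def small_scenario():
    """Scale-free K=3 scenario small enough for repeated fitting."""
    cfg = ScenarioConfig(
        network_type="scale_free", p=20, n=100, K=3, tau=0.2, seed=7
    )
    return sample_scenario(cfg)


@pytest.fixture(scope="session")
def small_fit(small_scenario):
    data, _ = small_scenario
    return fit_tdjgl(
        data,
        cfg=ObjectiveConfig(lambda1=0.1, lambda2=0.05, equal_group_weights=True),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_pd(p, rng, scale=0.3):
    """Random symmetric positive-definite matrix."""
    A = rng.normal(scale=scale, size=(p, p))
    return A @ A.T + np.eye(p)


@pytest.fixture(scope="session")
def tiny_data():
    """K=2 platforms, p=4 genes, n=60 per group of standard normal noise."""
    gen = np.random.default_rng(11)
    X = [[gen.normal(size=(60, 4)) for _ in range(2)] for _ in range(2)]
    return MultiPlatformData(X=X, genes=["a", "b", "c", "d"])


@pytest.fixture(scope="session")
def tiny_cov(tiny_data):
    return compute_sample_covariances(tiny_data)
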