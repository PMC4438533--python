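import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ibcnet import AnalysisConfig, GeneratorParams, generate_truth, simulate_expression

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config():
    return AnalysisConfig(seed=0)


@pytest.fixture
def small_params():
    """A reduced cohort: quick enough for per-test simulation, same structure."""
    return GeneratorParams(
        n_ibc=40, n_nibc=60, n_tfs=6, n_mr=2, regulon_size=10,
        n_background=80, seed=0,
    )


@pytest.fixture
def small_cohort(small_params):
    truth = generate_truth(small_params)
    X, labels = simulate_expression(truth, small_params)
    return truth, X, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
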