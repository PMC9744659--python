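import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by fitting-level tests."""
    from popwarp.config import SimulationConfig
    from popwarp.synthetic import simulate_dataset

    sim = SimulationConfig(n_conditions=2, n_neurons=18, seed=42)
    ds, truth = simulate_dataset(sim)
    return ds, truth, sim


@pytest.fixture(scope="session")
def small_state(small_sim):
    """Initialized fit state on the small dataset (no EM yet)."""
    from popwarp.config import ModelConfig
    from popwarp.fitting import initialize

    ds, truth, sim = small_sim
    return initialize(ds, ModelConfig())


@pytest.fixture(scope="session")
def basis_and_penalty():
    from popwarp.splines import build_basis, build_penalty

    basis = build_basis(T=500.0, n_knots=100, bin_width=2.0)
    return basis, build_penalty(basis)
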