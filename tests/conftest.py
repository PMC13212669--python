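import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with two relevant and three null covariates."""
    from fsrselect.data_model import upper_quartile_libsize
    from fsrselect.simulate import SimConfig, build_scenario, simulate_counts

    master = np.random.default_rng(123)
    cfg = SimConfig(n_genes=400, n_samples=24, n_candidates=5, k_relevant=2)
    sc = build_scenario(cfg, master)
    cm = simulate_counts(sc, master)
    cm = cm.with_libsize(upper_quartile_libsize(cm))
    return sc, cm
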