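import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort for fast unit tests (15 peaks, 450 bins)."""
    from cfcin.simulate import CohortConfig
    return CohortConfig(
        n_patients=12, n_bins=450, n_chromosomes=3,
        reads_per_sample=450 * 800, n_amp_peaks=6, n_del_peaks=9,
        event_width_bins=10, peak_width_bins=4, n_healthy=8,
        n_nucleosomes=800, n_fragments=4000, n_meth_regions=30,
        n_meth_healthy=15, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from cfcin.simulate import simulate_cohort
    return simulate_cohort(small_config)
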