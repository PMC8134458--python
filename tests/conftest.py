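import numpy as np
import pytest

from morphconn import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort exercising all stages quickly."""
    return CohortConfig(
        n_patients=6,
        n_controls=5,
        n_regions=24,
        community_count=4,
        n_voxels_per_region=40,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def gaussian_regions():
    """Region samples with known generating Gaussians (20 regions, n=500)."""
    rng = np.random.default_rng(42)
    mus = np.linspace(0.35, 0.65, 20)
    sigmas = 0.05 * np.exp(rng.normal(0, 0.08, 20))
    samples = rng.normal(mus[:, None], sigmas[:, None], (20, 500))
    return mus, sigmas, samples
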