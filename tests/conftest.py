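import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lpshells as lps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_traj():
    """Four tight waters exactly on the tetrahedral lone-pair axes, no
    loose/bulk waters, no kinetics, no geometric noise."""
    params = lps.chloride_preset(
        n_tight=4,
        n_loose=0,
        n_bulk=0,
        angular_noise_deg=0.0,
        r_tight_sigma=0.0,
        k_TL=0.0,
        k_LT=0.0,
        k_LB=0.0,
        k_BL=0.0,
        n_frames=30,
        seed=7,
    )
    return lps.generate_trajectory(params)


@pytest.fixture(scope="session")
def small_traj():
    """100 frames, 10 waters (4 tight, 3 loose, 3 bulk) with active kinetics."""
    params = lps.chloride_preset(n_loose=3, n_bulk=3, n_frames=100, seed=3)
    return lps.generate_trajectory(params)


@pytest.fixture(scope="session")
def default_traj():
    """300 frames of the full chloride-like preset (30 waters)."""
    params = lps.chloride_preset(n_frames=300, seed=5)
    return lps.generate_trajectory(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
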