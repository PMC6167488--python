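import numpy as np
import pytest

from omega_access import synthetic_data as sd
from omega_access.structures_io import (
    load_packaged_site_config,
    resolve_reactive_center,
    resolve_sites,
)


@pytest.fixture(scope="session")
def site_config():
    return load_packaged_site_config()


@pytest.fixture(scope="session")
def small_spec():
    return sd.vk1_like_spec(n_frames=300, seed=11)


@pytest.fixture(scope="session")
def small_trajectory(small_spec):
    """300 coordinate frames of the synthetic Compound I + tail fragment."""
    trajectory, plans = sd.build_frames(small_spec)
    return trajectory, plans


@pytest.fixture(scope="session")
def resolved(site_config, small_trajectory):
    trajectory, _ = small_trajectory
    center = resolve_reactive_center(site_config, trajectory)
    sites = resolve_sites(site_config, trajectory)
    return center, sites


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
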