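import numpy as np
import pytest
from hypothesis import settings

from gypsospec import SyntheticConfig, simulate_dataset
from gypsospec.spectra_io import default_grid

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def coarse_grid():
    """A 200-point grid spanning the full range, for cheap unit tests."""
    return default_grid(200)


@pytest.fixture(scope="session")
def default_dataset():
    """The 44-sample study-condition dataset at seed 1."""
    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free spectra (band structure only), seed 3."""
    cfg = SyntheticConfig(seed=3, noise_sd=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_dataset(coarse_grid):
    """Small, coarse-grid dataset (4/4/4) for fast plumbing tests."""
    from gypsospec.spectra_io import Group
    cfg = SyntheticConfig(
        group_sizes={Group.GYPSOVAG: 4, Group.NARROW_ENDEMISM: 4,
                     Group.WIDE_GYPSOPHILE: 4},
        seed=5, grid=coarse_grid, overlap_fraction=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def separable_set():
    """Tight within-class clusters (4 per group, 300-point grid): a
    cleanly separable three-class set for classifier oracles."""
    from gypsospec.spectra_io import SpectrumSet
    from gypsospec.synthetic_data import (GroupProfile, default_profiles,
                                          simulate_spectrum)
    grid = default_grid(300)
    cfg = SyntheticConfig(seed=5, grid=grid, noise_sd=0.002)
    rng = np.random.default_rng(5)
    spectra = []
    for g, prof in default_profiles().items():
        tight = GroupProfile(
            g, {k: (m, 0.05) for k, (m, _) in prof.band_amplitudes.items()},
            sample_cv=0.02)
        for i in range(4):
            spectra.append(simulate_spectrum(
                tight, cfg, rng, sample_id=f"{g.value}-{i}"))
    return SpectrumSet(spectra)
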