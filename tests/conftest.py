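import numpy as np
import pytest

from sycbct.phantom import PhantomConfig, generate_phantom
from sycbct.preprocess import PairedStudy, normalize_intensities


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, artifact-free, registered 32-cube phantom pair."""
    cfg = PhantomConfig(
        grid_size=32,
        noise_sigma_mri=0.0,
        noise_sigma_cbct=0.0,
        streak_amplitude=0.0,
        n_hard_structures=5,
        seed=7,
    )
    study, labels = generate_phantom(cfg)
    return cfg, study, labels


@pytest.fixture(scope="session")
def noisy_phantom():
    """Registered 48-cube phantom with noise and streaks."""
    cfg = PhantomConfig(
        grid_size=48,
        noise_sigma_mri=15.0,
        noise_sigma_cbct=30.0,
        streak_amplitude=150.0,
        seed=3,
    )
    study, labels = generate_phantom(cfg)
    return cfg, study, labels


@pytest.fixture(scope="session")
def normalized_clean_pair(clean_phantom):
    """Clean phantom pair min-max normalised to [-1, 1]."""
    _, study, _ = clean_phantom
    mri_n, _ = normalize_intensities(study.mri)
    cbct_n, _ = normalize_intensities(study.cbct)
    return PairedStudy(mri=mri_n, cbct=cbct_n, registered=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
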