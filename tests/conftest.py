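import numpy as np
import pytest

from ivmproc import PhantomSpec, PoissonGaussianModel, make_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Compact three-channel phantom recipe used across modules."""
    return PhantomSpec(
        shape=(1, 12, 3, 96, 96),
        n_filaments=6,
        n_tubes=2,
        n_puncta=8,
        n_fibrils=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def default_noise():
    return PoissonGaussianModel(alpha=4.0, sigma=10.0, mu=0.0)


@pytest.fixture(scope="session")
def textured_frame():
    """Smooth random texture with rich features for registration tests."""
    from scipy import ndimage

    rng = np.random.default_rng(42)
    base = ndimage.gaussian_filter(rng.random((128, 128)), 3.0)
    base = (base - base.min()) / np.ptp(base) * 1000.0
    return base
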