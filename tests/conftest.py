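import numpy as np
import pytest

import dmistroke as dm


@pytest.fixture(scope="session")
def two_shell():
    return dm.preset_scheme("two_shell")


@pytest.fixture(scope="session")
def hex_ball():
    return dm.preset_scheme("hex_ball")


@pytest.fixture(scope="session")
def wm_params():
    """White-matter-like microstructure (prior-admissible)."""
    return dm.MicrostructureParams(0.45, 0.45, 0.10, 2.4, 1.6, 0.35)


@pytest.fixture(scope="session")
def csf_params():
    return dm.MicrostructureParams(0.0, 0.0, 1.0, 2.0, 1.0, 0.4)


@pytest.fixture(scope="session")
def small_phantom_config():
    """A 32³ phantom small enough for fast unit tests."""
    return dm.PhantomConfig(
        seed=42, shape=(32, 32, 32), brain_radius=13.0,
        csf_rim_thickness=1.5, gm_thickness=2.0, ventricle_radius=1.5,
        lesion_offset_x=6.0, lesion_radius=3.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config):
    return dm.generate_phantom(small_phantom_config)


@pytest.fixture(scope="session")
def small_estimator(two_shell):
    """Quickly trained estimator (coarse but functional) for plumbing tests."""
    cfg = dm.PriorConfig(n_samples=3000, seed=123)
    return dm.train_estimator(two_shell, cfg)


def random_rotation(rng):
    """Haar-uniform rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
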