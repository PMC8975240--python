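import numpy as np
import pytest

from thermograd import phantom, radiometry


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Body phantom with the cohort's median core/limb temperatures, no noise."""
    spec = phantom.PhantomSpec(theta_core=33.88, theta_limb_end=30.21,
                               noise_sd_k=0.0, seed=11)
    rgb, frame, truth = phantom.generate_body_phantom(spec)
    return rgb, frame, truth


@pytest.fixture(scope="session")
def noiseless_field(noiseless_phantom):
    _, frame, _ = noiseless_phantom
    return radiometry.frame_to_celsius(frame)


@pytest.fixture(scope="session")
def board_pair():
    return phantom.generate_checkerboard_pair(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_homography(rng, scale=1.0, max_perspective=2e-4):
    """A well-conditioned random projective matrix (bounded perspective)."""
    angle = rng.uniform(-0.4, 0.4)
    c, s = np.cos(angle), np.sin(angle)
    sx, sy = rng.uniform(0.7, 1.4, 2) * scale
    shear = rng.uniform(-0.2, 0.2)
    tx, ty = rng.uniform(-20, 20, 2)
    affine = np.array([[sx * c, -s + shear, tx],
                       [s, sy * c + shear * 0.5, ty],
                       [0, 0, 1.0]])
    persp = np.eye(3)
    persp[2, :2] = rng.uniform(-max_perspective, max_perspective, 2)
    return affine @ persp
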