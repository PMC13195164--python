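import math

import numpy as np
import pytest

from uvcled import imaging, synthetic


@pytest.fixture(scope="session")
def small_noiseless_scene():
    """30 rods, no noise: exact ground truth for oracle tests."""
    spec = synthetic.SceneSpec(
        image_shape=(256, 256),
        n_cells=30,
        kappa=0.0,
        pi_positive_prob=0.0,
        shot_noise=False,
        gaussian_noise_sd=0.0,
        seed=11,
    )
    return synthetic.render_scene(spec)


@pytest.fixture(scope="session")
def default_scene():
    """Realistic noisy field at the default density."""
    spec = synthetic.SceneSpec(n_cells=400, kappa=0.0, pi_positive_prob=0.05, seed=1)
    return synthetic.render_scene(spec)


def capsule_mask(shape, center, theta, length, width):
    """Boolean capsule (rod cross-section) for hand-built segmentation inputs."""
    r = width / 2.0
    seg = (length - width) / 2.0
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    yy = yy - center[0]
    xx = xx - center[1]
    ax, ay = math.cos(theta), math.sin(theta)
    t = np.clip(xx * ax + yy * ay, -seg, seg)
    return (xx - t * ax) ** 2 + (yy - t * ay) ** 2 <= r**2
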