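import numpy as np
import pytest
from skimage import draw

from sporoquant import GrayImage
from sporoquant.synthetic import SceneParams, generate_micro_scene


@pytest.fixture(scope="session")
def disjoint_scene():
    """40 well-separated conidia, no clusters/germ tubes/secondaries."""
    params = SceneParams(n_conidia=40, cluster_fraction=0.0, seed=3)
    img, truth = generate_micro_scene(params)
    return params, img, truth


@pytest.fixture(scope="session")
def clustered_scene():
    """60 conidia, half of them in touching clusters of 2-4."""
    params = SceneParams(n_conidia=60, cluster_fraction=0.5, seed=7)
    img, truth = generate_micro_scene(params)
    return params, img, truth


@pytest.fixture
def dumbbell_mask():
    """Two radius-10 disks with centers 15 px apart: the analytic dumbbell."""
    mask = np.zeros((50, 60), dtype=bool)
    centers = [(25, 20), (25, 35)]
    for c in centers:
        rr, cc = draw.disk(c, 10)
        mask[rr, cc] = True
    return mask, centers


def blurred_disk(center, radius, shape, peak=200.0, sigma=2.0, background=0.0):
    """Gaussian-blurred bright disk as a GrayImage (test helper)."""
    from scipy.ndimage import gaussian_filter

    canvas = np.full(shape, float(background))
    rr, cc = draw.disk(center, radius, shape=shape)
    canvas[rr, cc] = peak
    return GrayImage.from_float(gaussian_filter(canvas, sigma))
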