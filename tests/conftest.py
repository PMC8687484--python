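import numpy as np
import pytest

from perisynmap.synthetic_scenes import gen_sim_scene
from perisynmap.volumetric_segmentation import VolumetricImage


@pytest.fixture(scope="session")
def small_scene():
    """A compact enriched two-channel scene shared by read-only tests."""
    return gen_sim_scene(
        shape=(4, 64, 64), n_markers=5, n_ab=30, enriched_fraction=1.0, seed=11
    )


@pytest.fixture()
def two_blob_image():
    """Noiseless image with two well-separated Gaussian blobs in one slice."""
    shape = (3, 40, 40)
    data = np.zeros(shape)
    yy, xx = np.mgrid[0:40, 0:40]
    for cy, cx in [(12, 12), (12, 28)]:
        data[1] += 10 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2))
    return VolumetricImage(data[None], 32.1, 200.0, ["ab"]), [(12, 12), (12, 28)]
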