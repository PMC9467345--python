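import numpy as np
import pytest
from scipy import stats as sps

from ccflow.images import EnFaceImage
from ccflow.synthetic import AcquisitionParams, generate_scene, render_octa_stack


def clipped_speckle_mean(base: np.ndarray, shape: float) -> np.ndarray:
    """Noise-free expectation of clip(base·g, 0, 1) for unit-mean gamma g.

    Uses x·f_k(x) = f_{k+1}(x) for gamma with mean 1, so
    E[min(l·g, 1)] = l·F_{k+1}(1/l) + (1 − F_k(1/l)).
    """
    out = np.empty_like(base, dtype=float)
    for lvl in np.unique(base):
        c = 1.0 / lvl
        val = lvl * sps.gamma.cdf(c, shape + 1, scale=1 / shape) + \
            sps.gamma.sf(c, shape, scale=1 / shape)
        out[base == lvl] = val
    return out


@pytest.fixture(scope="session")
def small_scene():
    """128 px scene at 10 µm/px with the study's PPE-like void load."""
    return generate_scene(pixel_count=128, pixel_pitch_um=10.0,
                          target_void_fraction=0.13, mean_void_size_um2=790.0,
                          pachyvessel_fraction=0.25, seed=7)


@pytest.fixture(scope="session")
def small_stack(small_scene):
    """Nine-frame acquisition of the small scene at default noise."""
    return render_octa_stack(small_scene, AcquisitionParams(n_frames=9, seed=11))


@pytest.fixture()
def smooth_image():
    """A smooth, feature-rich test image in [0, 1] (not a random texture)."""
    rng = np.random.default_rng(3)
    from scipy.ndimage import gaussian_filter

    arr = gaussian_filter(rng.random((96, 96)), 2.0)
    arr = (arr - arr.min()) / (arr.max() - arr.min())
    return EnFaceImage(arr, 10.0, "octa_scp")
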