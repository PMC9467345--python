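"""Phansalkar local adaptive thresholding and mask inversion.

The Phansalkar threshold generalizes Sauvola's rule for low-contrast
images where the objects of interest are *darker* than their
surroundings (stained nuclei originally; flow voids and choroidal
vessel lumens here).  For every pixel the threshold is computed from
the mean ``m`` and standard deviation ``s`` of the intensities in a
sliding neighborhood:

    T = m * (1 + p * exp(-q * m) + k * ((s / r) - 1))

and the pixel is foreground (bright signal) iff its value is strictly
greater than ``T``.  The ``p * exp(-q * m)`` term raises the threshold
in dark neighborhoods so that uniform dark regions do not fragment,
which is what makes the rule suitable for selecting flow voids on
choriocapillaris angiograms and vessel lumens on en face choroid scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import BinaryMask, EnFaceImage


@dataclass
class PhansalkarParams:
    """Parameters of the Phansalkar threshold on [0, 1] intensities.

    Defaults follow the constants of the standard auto-local-threshold
    implementation: radius 15 px, k=0.25, r=0.5, p=2, q=10, circular
    neighborhood, mirror padding at the borders.
    """

    radius_px: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0
    neighborhood_shape: str = "disk"

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.neighborhood_shape not in ("disk", "square"):
            raise ValueError("neighborhood_shape must be 'disk' or 'square'")

    def footprint(self) -> np.ndarray:
        n = 2 * self.radius_px + 1
        if self.neighborhood_shape == "square":
            return np.ones((n, n), dtype=bool)
        yy, xx = np.mgrid[-self.radius_px:self.radius_px + 1,
                          -self.radius_px:self.radius_px + 1]
        return (yy * yy + xx * xx) <= self.radius_px ** 2


def phansalkar_threshold_map(image: np.ndarray, params: PhansalkarParams | None = None) -> np.ndarray:
    """Per-pixel Phansalkar threshold surface for a [0, 1] image."""
    params = params or PhansalkarParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(img.shape) < 2 * params.radius_px + 1:
        raise ValueError(
            f"radius {params.radius_px} px too large for image of shape {img.shape}"
        )
    if np.nanmin(img) < -1e-9 or np.nanmax(img) > 1 + 1e-9:
        raise ValueError("image must be normalized to [0, 1] before thresholding")

    fp = params.footprint()
    kernel = fp.astype(float)
    n_px = int(fp.sum())
    # mirror padding ('mirror' == np.pad mode 'reflect': edge pixel not repeated)
    m = ndimage.correlate(img, kernel, mode="mirror") / n_px
    ex2 = ndimage.correlate(img * img, kernel, mode="mirror") / n_px
    s = np.sqrt(np.clip(ex2 - m * m, 0.0, None))
    return m * (1.0 + params.p * np.exp(-params.q * m) + params.k * ((s / params.r) - 1.0))


def phansalkar_threshold(image: EnFaceImage, params: PhansalkarParams | None = None) -> BinaryMask:
    """Binarize an en face image; foreground = bright signal (value > T)."""
    t_map = phansalkar_threshold_map(image.intensities, params)
    return BinaryMask(image.intensities > t_map, image.pixel_pitch_um, "bright_signal")


def invert_mask(mask: BinaryMask, new_meaning: str) -> BinaryMask:
    """Logical complement with re-stated foreground semantics.

    Binarizing an angiogram marks perfused (bright) pixels; inversion
    turns the dark remainder into the foreground of interest — flow
    voids for the choriocapillaris slab, vessel lumens for the choroid.
    """
    return BinaryMask(~mask.values, mask.pixel_pitch_um, new_meaning)
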