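"""Ground-truthed synthetic data emulating a pachychoroid OCTA study.

The study imagery this package analyzes — averaged 3 × 3 mm en face
choriocapillaris angiograms, their superficial-capillary-plexus (SCP)
registration references, and structural en face choroid scans — was
never deposited, so every downstream stage is exercised against
synthetic scenes with stored ground truth instead.

The scene model:

* The choriocapillaris is a bright perfused meshwork organized into
  lobules (terminal arteriole feeding a capillary bed drained by a
  venule).  Flow voids are small dark regions preferentially located
  on the inter-lobule boundaries; they cover ~10–15 % of the field
  with a mean size of several hundred µm².
* Pachyvessels are dilated outer choroidal veins: a handful of smooth
  ribbons, 150–400 µm wide, entering the field from the border and
  covering up to ~45 % of it.  On structural en face choroid scans
  their lumens are *dark* against a bright stroma.
* Each repeated OCTA acquisition of the same scene differs by a small
  rigid motion (fixation jitter) and by multiplicative speckle; the
  paired SCP frame shares exactly the motion of its choriocapillaris
  frame, which is the property the registration stage exploits.

The per-eye cohort generator draws summary metrics from the group
distributions of the clinical tables (pachychoroid pigment
epitheliopathy, "PPE", vs healthy controls), truncated to positive
support.  All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .images import EnFaceImage
from .registration import FrameTransform, warp_forward

# Reflectance levels of the rendered rasters (arbitrary units in [0, 1]).
# Choriocapillaris angiograms are deliberately low contrast: flow voids keep
# a substantial signal floor (noise floor plus through-slab projection), the
# regime the Phansalkar rule is suited to.  Structural choroid scans are the
# opposite: large vessel lumens are nearly black against a bright stroma.
CC_BRIGHT = 0.85
CC_DARK = 0.40
CHOROID_BRIGHT = 0.85
CHOROID_DARK = 0.03


@dataclass
class SceneTruth:
    """Ground-truth anatomy of one synthetic 3 × 3 mm field."""

    capillary_mask: np.ndarray  # True = perfused capillary
    void_mask: np.ndarray  # True = flow void (complement of capillary)
    pachyvessel_mask: np.ndarray  # True = large-vessel lumen
    pixel_pitch_um: float
    field_mm: float = 3.0

    def __post_init__(self) -> None:
        if not (self.capillary_mask.shape == self.void_mask.shape == self.pachyvessel_mask.shape):
            raise ValueError("all truth masks must share one grid")
        if np.any(self.void_mask == self.capillary_mask):
            raise ValueError("void_mask must be the exact complement of capillary_mask")
        frac = self.pachyvessel_mask.mean()
        if frac > 0.5:
            raise ValueError("pachyvessel area fraction must lie in [0, 0.5]")

    @property
    def void_fraction(self) -> float:
        return float(self.void_mask.mean())

    @property
    def pachyvessel_fraction(self) -> float:
        return float(self.pachyvessel_mask.mean())

    def base_reflectance(self) -> np.ndarray:
        """Noise-free choriocapillaris reflectance implied by the masks."""
        return np.where(self.capillary_mask, CC_BRIGHT, CC_DARK)


@dataclass
class AcquisitionParams:
    """Repeated-acquisition model: motion jitter and speckle.

    ``speckle_shape`` is the shape parameter of unit-mean gamma
    multiplicative noise (variance 1/shape); 10 corresponds to a
    single-frame SNR of ~3, at which a single frame looks granular but
    nine averaged frames resolve the meshwork.  ``signal_strength_range``
    is the range of the device quality score analog, mapped to [0, 1].
    """

    n_frames: int = 9
    speckle_shape: float = 10.0
    shift_sd_px: float = 2.0
    rotation_sd_deg: float = 0.5
    signal_strength_range: tuple[float, float] = (0.8, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if self.shift_sd_px < 0 or self.rotation_sd_deg < 0:
            raise ValueError("jitter standard deviations must be >= 0")
        lo, hi = self.signal_strength_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("signal_strength_range must be within [0, 1]")


@dataclass
class GroupParams:
    """Per-group cohort distributions, mean ± sd each."""

    n: int
    age_yr: tuple[float, float]
    axial_length_mm: tuple[float, float]
    sfct_um: tuple[float, float]
    n_voids: tuple[float, float]
    total_void_area_mm2: tuple[float, float]
    mean_void_size_um2: tuple[float, float]
    #: (mean, sd) for eyes with / without pachyvessels in the central 3 mm;
    #: None when the distance was not measured in that group
    rpe_vein_distance_um_pachy: tuple[float, float] | None
    rpe_vein_distance_um_nonpachy: tuple[float, float] | None
    male_fraction: float
    pachyvessel_fraction: float


@dataclass
class CohortParams:
    """Two-group cohort model, defaults from the clinical tables.

    PPE eyes: fewer but larger flow voids, more total void area,
    thicker subfoveal choroid, mostly male, pachyvessels usually
    present in the central 3 mm.  Controls: the reverse.  The RPE-to-
    choroidal-vein distance is only defined for eyes in which it was
    measured (PPE); controls carry NaN.
    """

    ppe: GroupParams = field(default_factory=lambda: GroupParams(
        n=32,
        age_yr=(62.5, 8.6),
        axial_length_mm=(23.99, 0.96),
        sfct_um=(374.5, 81.5),
        n_voids=(1483, 154),
        total_void_area_mm2=(1.16, 0.18),
        mean_void_size_um2=(790, 144),
        rpe_vein_distance_um_pachy=(64.0, 19.6),
        rpe_vein_distance_um_nonpachy=(107.2, 25.9),
        male_fraction=25 / 32,
        pachyvessel_fraction=25 / 32,
    ))
    control: GroupParams = field(default_factory=lambda: GroupParams(
        n=30,
        age_yr=(65.2, 9.9),
        axial_length_mm=(24.38, 1.14),
        sfct_um=(248.7, 35.3),
        n_voids=(1826, 319),
        total_void_area_mm2=(0.91, 0.16),
        mean_void_size_um2=(520, 138),
        rpe_vein_distance_um_pachy=None,
        rpe_vein_distance_um_nonpachy=None,
        male_fraction=18 / 30,
        pachyvessel_fraction=0.0,
    ))
    seed: int = 0

    def __post_init__(self) -> None:
        for g in (self.ppe, self.control):
            if g.n < 0 or (g.n > 0 and g.n < 2):
                raise ValueError("each non-empty group needs n >= 2")
            for name in ("age_yr", "axial_length_mm", "sfct_um", "n_voids",
                         "total_void_area_mm2", "mean_void_size_um2"):
                if getattr(g, name)[1] < 0:
                    raise ValueError(f"{name} sd must be >= 0")


# ---------------------------------------------------------------------------
# scene generation


def _lobule_ridge_field(shape: tuple[int, int], lobule_spacing_px: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Distance-to-lobule-boundary field from a jittered-grid tessellation.

    Lobule centers sit on a jittered grid; the difference between the
    distances to the two nearest centers vanishes on the boundary
    between neighbouring lobules, so small values mark the inter-lobule
    meshwork gaps where voids preferentially sit.
    """
    h, w = shape
    step = lobule_spacing_px
    ys = np.arange(step / 2, h, step)
    xs = np.arange(step / 2, w, step)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    jitter = rng.uniform(-0.35 * step, 0.35 * step, size=(2,) + gy.shape)
    seeds = np.column_stack([(gy + jitter[0]).ravel(), (gx + jitter[1]).ravel()])
    tree = cKDTree(seeds)
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    d, _ = tree.query(pts, k=2)
    return (d[:, 1] - d[:, 0]).reshape(shape)


def _stamp_ellipse(mask: np.ndarray, cy: float, cx: float, area_px: float,
                   rng: np.random.Generator) -> None:
    """Stamp one elliptical void of approximately ``area_px`` pixels."""
    aspect = rng.uniform(0.4, 1.0)
    a = np.sqrt(area_px / (np.pi * aspect))  # semi-major (px)
    b = a * aspect
    phi = rng.uniform(0, np.pi)
    r = int(np.ceil(a)) + 1
    y0, y1 = max(0, int(cy) - r), min(mask.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(mask.shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(phi) + dx * np.sin(phi)
    v = -dy * np.sin(phi) + dx * np.cos(phi)
    mask[y0:y1, x0:x1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _stamp_disc(mask: np.ndarray, cy: int, cx: int, radius: float) -> None:
    r = int(np.ceil(radius))
    y0, y1 = max(0, cy - r), min(mask.shape[0], cy + r + 1)
    x0, x1 = max(0, cx - r), min(mask.shape[1], cx + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _grow_ribbon(mask: np.ndarray, pitch_um: float, rng: np.random.Generator) -> None:
    """Grow one smooth pachyvessel ribbon from the field border inward."""
    h, w = mask.shape
    side = rng.integers(4)
    if side == 0:
        y, x, heading = 0.0, rng.uniform(0.1, 0.9) * w, np.pi / 2
    elif side == 1:
        y, x, heading = h - 1.0, rng.uniform(0.1, 0.9) * w, -np.pi / 2
    elif side == 2:
        y, x, heading = rng.uniform(0.1, 0.9) * h, 0.0, 0.0
    else:
        y, x, heading = rng.uniform(0.1, 0.9) * h, w - 1.0, np.pi
    width_um = rng.uniform(150.0, 400.0)
    radius_px = 0.5 * width_um / pitch_um
    step = max(1.0, radius_px / 2)
    n_steps = int(2.2 * max(h, w) / step)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_steps):
        mask |= (yy - y) ** 2 + (xx - x) ** 2 <= radius_px ** 2
        heading += rng.normal(0, 0.22)
        x += step * np.cos(heading)
        y += step * np.sin(heading)
        radius_px = float(np.clip(radius_px * np.exp(rng.normal(0, 0.04)),
                                  0.5 * 150 / pitch_um, 0.5 * 420 / pitch_um))
        if not (-radius_px <= y < h + radius_px and -radius_px <= x < w + radius_px):
            break


def generate_scene(
    pixel_count: int = 300,
    pixel_pitch_um: float = 10.0,
    target_void_fraction: float = 0.13,
    mean_void_size_um2: float = 790.0,
    pachyvessel_fraction: float = 0.25,
    seed: int = 0,
    lobule_diameter_um: float = 400.0,
) -> SceneTruth:
    """Generate one ground-truth scene: capillary meshwork, voids, pachyvessels.

    Elliptical voids with gamma-distributed sizes (mean
    ``mean_void_size_um2``) are stamped preferentially on the
    boundaries of a jittered-grid lobule tessellation until the target
    area fraction is reached, so the realized void fraction tracks
    ``target_void_fraction`` to within one void's area.
    """
    if not 0 < target_void_fraction < 1:
        raise ValueError("target_void_fraction must lie strictly between 0 and 1")
    if pixel_count < 64:
        raise ValueError("pixel_count must be >= 64")
    if mean_void_size_um2 < pixel_pitch_um ** 2:
        raise ValueError("mean_void_size_um2 must cover at least one pixel")
    if not 0 <= pachyvessel_fraction <= 0.5:
        raise ValueError("pachyvessel_fraction must lie in [0, 0.5]")

    rng = np.random.default_rng(seed)
    shape = (pixel_count, pixel_count)
    ridge = _lobule_ridge_field(shape, lobule_diameter_um / pixel_pitch_um, rng)

    # sampling weight biased toward inter-lobule boundaries, with a uniform
    # floor so voids do not chain into one connected gap network
    weight = 0.3 + 0.7 * np.exp(-ridge / (0.15 * lobule_diameter_um / pixel_pitch_um))
    weight /= weight.sum()
    flat_w = weight.ravel()

    void = np.zeros(shape, dtype=bool)
    target_px = target_void_fraction * void.size
    mean_void_px = mean_void_size_um2 / pixel_pitch_um ** 2
    n_expected = max(target_px / mean_void_px, 1.0)
    # blue-noise thinning: exclusion radius sized so distinct voids stay
    # distinct at the expected packing density
    r_min = max(1.5, np.sqrt(0.4 * void.size / (np.pi * n_expected)))
    excluded = np.zeros(shape, dtype=bool)
    max_voids = int(np.ceil(6 * target_px / mean_void_px)) + 10
    centers = rng.choice(void.size, size=max_voids, p=flat_w)
    sizes_px = rng.gamma(4.0, mean_void_px / 4.0, size=max_voids)
    n_placed = 0
    for idx, area_px in zip(centers, sizes_px):
        if void.sum() >= target_px:
            break
        cy, cx = int(idx // pixel_count), int(idx % pixel_count)
        if excluded[cy, cx]:
            continue
        _stamp_ellipse(void, cy, cx, max(area_px, 1.0), rng)
        _stamp_disc(excluded, cy, cx, r_min)
        n_placed += 1

    pachy = np.zeros(shape, dtype=bool)
    if pachyvessel_fraction > 0:
        for _ in range(64):  # a handful of ribbons normally suffices
            if pachy.mean() >= pachyvessel_fraction:
                break
            _grow_ribbon(pachy, pixel_pitch_um, rng)
        pachy = ndimage.binary_closing(pachy, structure=np.ones((3, 3)))
        # on small fields one wide ribbon can overshoot: erode back into range
        while pachy.mean() > 0.5:
            pachy = ndimage.binary_erosion(pachy)

    return SceneTruth(
        capillary_mask=~void,
        void_mask=void,
        pachyvessel_mask=pachy,
        pixel_pitch_um=pixel_pitch_um,
        field_mm=pixel_count * pixel_pitch_um / 1000.0,
    )


# ---------------------------------------------------------------------------
# rendering


def _scp_reference_pattern(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """High-contrast vessel-network pattern standing in for the SCP slab."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), 6.0)
    field /= field.std()
    vessels = np.abs(field) < 0.18  # level-set ridges: curvilinear network
    base = np.where(vessels, 0.9, 0.15)
    return ndimage.gaussian_filter(base, 0.8)


@dataclass
class FramePair:
    """One acquisition: choriocapillaris frame + SCP reference frame."""

    cc: EnFaceImage
    scp: EnFaceImage


@dataclass
class RenderedStack:
    """Rendered acquisition series with its ground truth."""

    frames: list[FramePair]
    true_transforms: list[FrameTransform]
    quality_scores: list[float]
    truth: SceneTruth


def render_octa_stack(truth: SceneTruth, params: AcquisitionParams) -> RenderedStack:
    """Render repeated OCTA acquisitions of one scene.

    Each frame is the base reflectance warped by a per-frame rigid
    motion and multiplied by unit-mean gamma speckle; the SCP reference
    frame of each pair shares exactly the same motion.  True motions
    and quality-score analogs are returned as ground truth.
    """
    rng = np.random.default_rng(params.seed)
    cc_base = truth.base_reflectance()
    scp_base = _scp_reference_pattern(cc_base.shape, rng)

    frames: list[FramePair] = []
    transforms: list[FrameTransform] = []
    scores: list[float] = []
    lo, hi = params.signal_strength_range
    for _ in range(params.n_frames):
        t = FrameTransform(
            dx_px=float(rng.normal(0, params.shift_sd_px)) if params.shift_sd_px else 0.0,
            dy_px=float(rng.normal(0, params.shift_sd_px)) if params.shift_sd_px else 0.0,
            theta_deg=float(rng.normal(0, params.rotation_sd_deg)) if params.rotation_sd_deg else 0.0,
        )
        score = float(rng.uniform(lo, hi))
        cc = warp_forward(cc_base, t, mode="mirror")
        scp = warp_forward(scp_base, t, mode="mirror")
        cc = np.clip(cc * rng.gamma(params.speckle_shape, 1.0 / params.speckle_shape, cc.shape), 0, 1)
        scp = np.clip(scp * rng.gamma(params.speckle_shape, 1.0 / params.speckle_shape, scp.shape), 0, 1)
        frames.append(FramePair(
            cc=EnFaceImage(cc, truth.pixel_pitch_um, "octa_cc"),
            scp=EnFaceImage(scp, truth.pixel_pitch_um, "octa_scp"),
        ))
        transforms.append(t)
        scores.append(score)
    return RenderedStack(frames=frames, true_transforms=transforms,
                         quality_scores=scores, truth=truth)


def render_choroid_oct(truth: SceneTruth, noise_sd: float = 0.05, seed: int = 0) -> EnFaceImage:
    """Render the structural en face choroid scan: dark lumens, bright stroma."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.where(truth.pachyvessel_mask, CHOROID_DARK, CHOROID_BRIGHT).astype(float)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    return EnFaceImage(np.clip(img, 0, 1), truth.pixel_pitch_um, "oct_choroid")


# ---------------------------------------------------------------------------
# cohort generation

COHORT_COLUMNS = [
    "eye_id", "group", "age", "sex", "axial_length_mm", "sfct_um",
    "pachyvessel_in_3mm", "n_voids", "total_void_area_mm2",
    "mean_void_size_um2", "rpe_vein_distance_um",
]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated to positive support (avoids negative areas/ages)."""
    if sd == 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd
    u = rng.random(n)
    lo = stats.norm.cdf(a)
    return stats.norm.ppf(lo + u * (1 - lo)) * sd + mean


def _group_rows(rng: np.random.Generator, g: GroupParams, label: str, start_id: int) -> pd.DataFrame:
    n = g.n
    rows = pd.DataFrame({
        "eye_id": [f"{label}-{start_id + i:03d}" for i in range(n)],
        "group": label,
        "age": _truncated_normal(rng, *g.age_yr, n),
        "sex": np.where(rng.random(n) < g.male_fraction, "M", "F"),
        "axial_length_mm": _truncated_normal(rng, *g.axial_length_mm, n),
        "sfct_um": _truncated_normal(rng, *g.sfct_um, n),
        "pachyvessel_in_3mm": rng.random(n) < g.pachyvessel_fraction,
        "n_voids": np.round(_truncated_normal(rng, *g.n_voids, n)).astype(int),
        "total_void_area_mm2": _truncated_normal(rng, *g.total_void_area_mm2, n),
        "mean_void_size_um2": _truncated_normal(rng, *g.mean_void_size_um2, n),
    })
    dist = np.full(n, np.nan)
    pachy = rows["pachyvessel_in_3mm"].to_numpy()
    if g.rpe_vein_distance_um_pachy is not None:
        dist[pachy] = _truncated_normal(rng, *g.rpe_vein_distance_um_pachy, int(pachy.sum()))
    if g.rpe_vein_distance_um_nonpachy is not None:
        dist[~pachy] = _truncated_normal(rng, *g.rpe_vein_distance_um_nonpachy, int((~pachy).sum()))
    rows["rpe_vein_distance_um"] = dist
    return rows


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw one synthetic per-eye cohort table (PPE + control groups)."""
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    parts = []
    if params.ppe.n:
        parts.append(_group_rows(rng, params.ppe, "PPE", 0))
    if params.control.n:
        parts.append(_group_rows(rng, params.control, "control", 0))
    if not parts:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.concat(parts, ignore_index=True)[COHORT_COLUMNS]
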