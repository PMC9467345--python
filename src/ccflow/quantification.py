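"""Flow-void metrics and pachyvessel co-localization.

From the inverted binarized choriocapillaris image, flow voids are the
connected foreground components; the three reported metrics are their
count, total area (mm²) and mean size (µm²).  Co-localization against
the inverted binarized choroid image yields the pachyvessel area
portion of the field and the proportion of flow-void area overlying
pachyvessels — the statistic distinguishing a flow deficit caused by
vessel compression (high overlap) from a diffuse deficit (overlap near
the vessel area fraction itself).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .binarization import PhansalkarParams, invert_mask, phansalkar_threshold
from .images import BinaryMask, EnFaceImage, read_enface, read_stack, write_enface, write_mask
from .registration import average_stack, estimate_transform

_STRUCTURES = {
    8: np.ones((3, 3), dtype=bool),
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


@dataclass
class FlowVoidMetrics:
    """Count, total area (mm²) and mean size (µm²) of the flow voids."""

    n_voids: int
    total_area_mm2: float
    mean_size_um2: float

    def __post_init__(self) -> None:
        if self.n_voids < 0 or self.total_area_mm2 < 0:
            raise ValueError("metrics must be non-negative")
        # conservation: count × mean size (µm²→mm²) must equal total area
        implied = self.n_voids * self.mean_size_um2 * 1e-6
        if self.n_voids and not np.isclose(implied, self.total_area_mm2, rtol=1e-9, atol=1e-12):
            raise ValueError("n_voids × mean_size_um2 must equal total_area_mm2")


@dataclass
class OverlapMetrics:
    """Pachyvessel field portion and void-over-vessel proportion, both %."""

    pachyvessel_portion_pct: float
    void_over_vessel_pct: float

    def __post_init__(self) -> None:
        for v in (self.pachyvessel_portion_pct, self.void_over_vessel_pct):
            if not 0 <= v <= 100:
                raise ValueError("percentages must lie in [0, 100]")


def extract_flow_voids(
    void_mask: BinaryMask,
    connectivity: int = 8,
    min_void_px: int = 0,
) -> tuple[FlowVoidMetrics, np.ndarray]:
    """Label flow voids and compute the three metrics.

    Components are 8-connected by default; voids touching the field
    edge count with their visible area only, and no minimum-size filter
    is applied unless ``min_void_px`` is set.  Returns the metrics and
    the labeled component map.
    """
    if void_mask.foreground_meaning != "flow_void":
        raise ValueError(
            f"expected a flow_void mask, got foreground={void_mask.foreground_meaning!r}"
        )
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(void_mask.values, structure=_STRUCTURES[connectivity])
    if min_void_px > 0 and n:
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(sizes >= min_void_px) + 1
        relabel = np.zeros(n + 1, dtype=labels.dtype)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
        n = keep.size
    px_area_um2 = void_mask.pixel_pitch_um ** 2
    total_um2 = float(np.count_nonzero(labels) * px_area_um2)
    metrics = FlowVoidMetrics(
        n_voids=int(n),
        total_area_mm2=total_um2 * 1e-6,
        mean_size_um2=total_um2 / n if n else 0.0,
    )
    return metrics, labels


def composite_overlap(
    void_mask: BinaryMask,
    vessel_mask: BinaryMask,
) -> tuple[OverlapMetrics, np.ndarray]:
    """Overlap metrics plus the red/green/yellow composite image.

    Flow void renders red, pachyvessel green; their intersection — the
    flow deficit directly over a pachyvessel — appears yellow.
    """
    if void_mask.shape != vessel_mask.shape:
        raise ValueError("masks must share one grid")
    if void_mask.pixel_pitch_um != vessel_mask.pixel_pitch_um:
        raise ValueError("masks must share one pixel pitch")
    if void_mask.foreground_meaning != "flow_void":
        raise ValueError("first mask must have foreground flow_void")
    if vessel_mask.foreground_meaning != "pachyvessel":
        raise ValueError("second mask must have foreground pachyvessel")
    void = void_mask.values
    vessel = vessel_mask.values
    total_void = int(void.sum())
    if total_void == 0:
        raise ValueError("void_over_vessel_pct undefined: total flow-void area is zero")
    metrics = OverlapMetrics(
        pachyvessel_portion_pct=100.0 * float(vessel.mean()),
        void_over_vessel_pct=100.0 * float((void & vessel).sum()) / total_void,
    )
    rgb = np.zeros(void.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = void * 255  # red; overlap with green gives yellow
    rgb[..., 1] = vessel * 255
    return metrics, rgb


@dataclass
class EyeResult:
    """Full per-eye output of the analysis chain."""

    flow_voids: FlowVoidMetrics
    overlap: OverlapMetrics | None
    n_frames_used: int
    registration_qualities: list[float]

    def to_dict(self) -> dict:
        return {
            "flow_voids": asdict(self.flow_voids),
            "overlap": asdict(self.overlap) if self.overlap else None,
            "n_frames_used": self.n_frames_used,
            "registration_qualities": self.registration_qualities,
        }


def analyze_eye(
    cc_frames: list[EnFaceImage],
    scp_frames: list[EnFaceImage],
    choroid: EnFaceImage | None = None,
    *,
    phansalkar: PhansalkarParams | None = None,
    min_quality: float = 0.5,
    reference_index: int = 0,
    rotation_max_deg: float = 2.0,
    connectivity: int = 8,
    min_void_px: int = 0,
    out_dir: str | Path | None = None,
) -> EyeResult:
    """Run the per-eye chain: register → average → binarize → quantify.

    Transforms are estimated on the SCP reference frames and applied
    unchanged to the paired choriocapillaris frames.  If ``choroid`` is
    given it is binarized the same way (inverted to vessel lumens) and
    the overlap statistics are computed.  With ``out_dir`` set, every
    intermediate raster and a JSON metrics record are persisted.
    """
    if len(cc_frames) != len(scp_frames) or not cc_frames:
        raise ValueError("need equal, non-zero numbers of CC and SCP frames")
    params = phansalkar or PhansalkarParams()
    try:
        ref = scp_frames[reference_index]
        transforms = [
            estimate_transform(ref, mov, rotation_max_deg=rotation_max_deg)
            for mov in scp_frames
        ]
    except ValueError as exc:
        raise RuntimeError(f"registration failed: {exc}") from exc

    try:
        averaged = average_stack(cc_frames, transforms, min_quality=min_quality)
    except ValueError as exc:
        raise RuntimeError(f"averaging failed: {exc}") from exc

    avg_img = averaged.image
    filled = avg_img.intensities
    if np.isnan(filled).any():  # never-covered border pixels: fill with field mean
        filled = np.where(np.isnan(filled), np.nanmean(filled), filled)
        avg_img = EnFaceImage(filled, avg_img.pixel_pitch_um, avg_img.modality)

    try:
        bright = phansalkar_threshold(avg_img, params)
    except ValueError as exc:
        raise RuntimeError(f"binarization failed: {exc}") from exc
    void_mask = invert_mask(bright, "flow_void")
    metrics, labels = extract_flow_voids(void_mask, connectivity=connectivity,
                                         min_void_px=min_void_px)

    overlap = None
    composite = None
    vessel_mask = None
    if choroid is not None:
        try:
            vessel_mask = invert_mask(phansalkar_threshold(choroid, params), "pachyvessel")
            overlap, composite = composite_overlap(void_mask, vessel_mask)
        except ValueError as exc:
            raise RuntimeError(f"co-localization failed: {exc}") from exc

    result = EyeResult(
        flow_voids=metrics,
        overlap=overlap,
        n_frames_used=averaged.n_frames_used,
        registration_qualities=[t.quality for t in transforms],
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_enface(out / "averaged_cc.tiff", avg_img)
        write_mask(out / "flow_void_mask.png", void_mask)
        import imageio.v3 as iio

        u16 = (labels % 65535).astype(np.uint16)
        iio.imwrite(out / "void_labels.png", u16)
        if vessel_mask is not None:
            write_mask(out / "pachyvessel_mask.png", vessel_mask)
        if composite is not None:
            iio.imwrite(out / "composite.png", composite)
        (out / "metrics.json").write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
    return result


def run_eye_pipeline(
    cc_stack_path: str | Path,
    scp_stack_path: str | Path,
    choroid_path: str | Path | None,
    out_dir: str | Path,
    **kwargs,
) -> EyeResult:
    """File-based wrapper around :func:`analyze_eye` (stacks + sidecars)."""
    cc_frames, _ = read_stack(cc_stack_path)
    scp_frames, sidecar = read_stack(scp_stack_path)
    choroid = None
    if choroid_path is not None:
        choroid = read_enface(choroid_path, sidecar["pixel_pitch_um"], "oct_choroid")
    return analyze_eye(cc_frames, scp_frames, choroid, out_dir=out_dir, **kwargs)
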