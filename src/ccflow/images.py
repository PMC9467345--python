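"""Raster currency of the pipeline: en face images and binary masks.

An :class:`EnFaceImage` is a frontal-plane 2-D projection of an OCT/OCTA
depth slab, stored as floats in [0, 1] together with its physical pixel
pitch (micrometres per pixel) and a modality tag.  A :class:`BinaryMask`
is a boolean grid with the same geometry whose foreground semantics are
stated explicitly (bright signal, flow void, or pachyvessel lumen).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

MODALITIES = ("octa_cc", "octa_scp", "oct_choroid")
MASK_MEANINGS = ("bright_signal", "flow_void", "pachyvessel")


@dataclass
class EnFaceImage:
    """A 2-D en face intensity grid with physical pixel pitch.

    Parameters
    ----------
    intensities
        2-D float array, values in [0, 1].
    pixel_pitch_um
        Physical size of one pixel in micrometres (isotropic).
    modality
        One of ``octa_cc`` (choriocapillaris angiography slab),
        ``octa_scp`` (superficial capillary plexus, used as the
        registration reference), ``oct_choroid`` (structural en face
        choroid, dark vessel lumens).
    """

    intensities: np.ndarray
    pixel_pitch_um: float
    modality: str = "octa_cc"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        finite = self.intensities[np.isfinite(self.intensities)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("intensities must be normalized to [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def field_mm(self) -> float:
        """Physical field width in millimetres (columns × pitch)."""
        return self.shape[1] * self.pixel_pitch_um / 1000.0

    def copy(self) -> "EnFaceImage":
        return EnFaceImage(self.intensities.copy(), self.pixel_pitch_um, self.modality)


@dataclass
class BinaryMask:
    """Boolean grid with pixel pitch and explicit foreground semantics."""

    values: np.ndarray
    pixel_pitch_um: float
    foreground_meaning: str = "bright_signal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.foreground_meaning not in MASK_MEANINGS:
            raise ValueError(f"unknown foreground meaning {self.foreground_meaning!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def foreground_fraction(self) -> float:
        return float(self.values.mean())


def normalize_to_unit(raw: np.ndarray) -> np.ndarray:
    """Scale an integer or float raster into [0, 1] by dtype range."""
    raw = np.asarray(raw)
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(float) / np.iinfo(raw.dtype).max
    out = raw.astype(float)
    if out.size and np.nanmax(out) > 1.0:
        out = out / np.nanmax(out)
    return out


def read_enface(path: str | Path, pixel_pitch_um: float, modality: str = "octa_cc") -> EnFaceImage:
    """Read an 8/16-bit grayscale TIFF or PNG as an EnFaceImage."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    if raw.ndim == 3:  # single-page stack or RGB: collapse defensively
        raw = raw[0] if raw.shape[0] < raw.shape[-1] else raw[..., 0]
    return EnFaceImage(normalize_to_unit(raw), pixel_pitch_um, modality)


def write_enface(path: str | Path, image: EnFaceImage) -> None:
    """Write as 16-bit grayscale (TIFF or PNG by extension) + JSON sidecar."""
    path = Path(path)
    arr = np.nan_to_num(image.intensities, nan=0.0)
    u16 = np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, u16)
    else:
        iio.imwrite(path, u16)
    sidecar = {"pixel_pitch_um": image.pixel_pitch_um, "modality": image.modality}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def write_stack(path: str | Path, images: list[EnFaceImage], sidecar_extra: dict | None = None) -> None:
    """Write a frame stack as a multi-page 16-bit TIFF with a JSON sidecar."""
    path = Path(path)
    pages = np.stack(
        [np.round(np.clip(np.nan_to_num(im.intensities), 0, 1) * 65535).astype(np.uint16) for im in images]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "pixel_pitch_um": images[0].pixel_pitch_um,
        "modality": images[0].modality,
        "n_frames": len(images),
    }
    if sidecar_extra:
        sidecar.update(sidecar_extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_stack(path: str | Path) -> tuple[list[EnFaceImage], dict]:
    """Read a multi-page TIFF stack and its JSON sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    images = [
        EnFaceImage(p.astype(float) / 65535.0, sidecar["pixel_pitch_um"], sidecar["modality"])
        for p in pages
    ]
    return images, sidecar


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a binary mask as 8-bit PNG (0/255) with a JSON sidecar."""
    path = Path(path)
    iio.imwrite(path, (mask.values.astype(np.uint8) * 255))
    sidecar = {
        "pixel_pitch_um": mask.pixel_pitch_um,
        "foreground_meaning": mask.foreground_meaning,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_mask(path: str | Path, pixel_pitch_um: float | None = None,
              foreground_meaning: str | None = None) -> BinaryMask:
    """Read a 0/255 PNG mask; sidecar supplies pitch/meaning unless given."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    pitch = pixel_pitch_um if pixel_pitch_um is not None else sidecar.get("pixel_pitch_um")
    meaning = foreground_meaning if foreground_meaning is not None else sidecar.get(
        "foreground_meaning", "bright_signal")
    if pitch is None:
        raise ValueError(f"no pixel pitch for {path}: pass pixel_pitch_um or provide a sidecar")
    raw = iio.imread(path)
    return BinaryMask(raw > 127, pitch, meaning)
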