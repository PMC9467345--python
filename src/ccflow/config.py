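"""Pipeline configuration: one validated text file drives every stage.

The config is a YAML (or JSON) mapping mirroring the pipeline stages.
Unknown keys are rejected by name, out-of-range values raise with the
dotted path of the offending field, and absent keys fall back to the
defaults, so an empty file is a valid full configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .binarization import PhansalkarParams


@dataclass
class RegistrationConfig:
    min_quality: float = 0.5
    reference_index: int = 0
    rotation_max_deg: float = 2.0
    rotation_step_deg: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.min_quality <= 1:
            raise ValueError("min_quality must lie in [0, 1]")
        if self.reference_index < 0:
            raise ValueError("reference_index must be >= 0")
        if self.rotation_max_deg < 0 or self.rotation_step_deg <= 0:
            raise ValueError("rotation search parameters out of range")


@dataclass
class QuantificationConfig:
    connectivity: int = 8
    min_void_px: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_void_px < 0:
            raise ValueError("min_void_px must be >= 0")


@dataclass
class StatsConfig:
    ttest_variant: str = "student"
    adjust_covariates: list[str] = field(default_factory=lambda: ["age", "sex"])

    def __post_init__(self) -> None:
        if self.ttest_variant not in ("student", "welch"):
            raise ValueError("ttest_variant must be 'student' or 'welch'")


@dataclass
class StudyConfig:
    """Synthetic-study scale: cohort sizes and acquisition settings."""

    n_ppe: int = 32
    n_control: int = 30
    n_frames: int = 5
    speckle_shape: float = 10.0
    shift_sd_px: float = 2.0
    rotation_sd_deg: float = 0.5
    choroid_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_ppe < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if min(self.shift_sd_px, self.rotation_sd_deg, self.choroid_noise_sd) < 0:
            raise ValueError("noise/jitter parameters must be >= 0")


@dataclass
class PipelineConfig:
    pixel_pitch_um: float = 10.0
    field_mm: float = 3.0
    seed: int = 0
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    quantification: QuantificationConfig = field(default_factory=QuantificationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    study: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.field_mm <= 0:
            raise ValueError("field_mm must be positive")

    @property
    def pixel_count(self) -> int:
        return int(round(self.field_mm * 1000.0 / self.pixel_pitch_um))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "phansalkar": PhansalkarParams,
    "registration": RegistrationConfig,
    "quantification": QuantificationConfig,
    "stats": StatsConfig,
    "study": StudyConfig,
}


def _build(cls, data: dict, prefix: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        name = sorted(unknown)[0]
        raise ValueError(f"unknown config key: {prefix}{name}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid value in section '{prefix[:-1] or 'top-level'}': {exc}") from exc


def config_from_dict(data: dict | None) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    for key, cls in _SECTIONS.items():
        section = data.pop(key, None)
        if section is not None:
            if not isinstance(section, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            kwargs[key] = _build(cls, section, f"{key}.")
    top_known = {f.name for f in dataclasses.fields(PipelineConfig)} - set(_SECTIONS)
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]}")
    try:
        return PipelineConfig(**data, **kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid top-level config value: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config file; absent keys get defaults."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValueError(f"unreadable config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"config file {path} is not valid YAML/JSON: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping at the top level")
    return config_from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
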