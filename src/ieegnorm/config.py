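"""Pipeline configuration: a validated bundle of every tunable parameter.

Loaded from YAML, overridable from CLI flags, and written (resolved)
next to any output a run produces so results are reproducible from the
artefacts alone.
"""

from __future__ import annotations

from pathlib import Path

import pydantic
import yaml

from .errors import ValidationError
from .spectral import FrequencyBand, bands_from_dicts, bands_to_dicts, canonical_bands


class PipelineConfig(pydantic.BaseModel):
    """All analysis parameters with their defaults.

    Units: sampling rates in Hz, segment times in seconds, the resection
    radius in millimetres, ``resected_fraction`` as a fraction in (0, 1).
    """

    model_config = pydantic.ConfigDict(extra="forbid")

    bands: list[dict] = pydantic.Field(
        default_factory=lambda: bands_to_dicts(canonical_bands()))
    target_fs: float = 200.0
    segment_start: float = 0.0
    segment_duration: float = 70.0
    welch_window_s: float = 2.0
    welch_overlap_s: float = 1.0
    radius_mm: float = 5.0
    resected_fraction: float = 0.25
    min_participants: int = 5
    pooled_t: bool = True
    seed: int = 0

    @pydantic.field_validator("target_fs", "segment_duration",
                              "welch_window_s", "radius_mm")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @pydantic.field_validator("resected_fraction")
    @classmethod
    def _fraction(cls, v):
        if not 0 < v < 1:
            raise ValueError("resected_fraction must be in (0, 1)")
        return v

    def band_objects(self) -> tuple[FrequencyBand, ...]:
        return bands_from_dicts(self.bands)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"invalid configuration {path}: {exc}") from exc


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
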