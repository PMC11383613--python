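"""Schema-validated pipeline configuration.

YAML in, pydantic validation (unknown keys rejected), and a stable config
hash that is stamped into every output artifact so any parameter change is
visible in provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .phantom import PhantomSpec

__all__ = ["PipelineConfig", "PreprocessingParams", "ParcellationParams", "SeedParams"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomParams(_Strict):
    n_vertices_per_hemi: int = 2000
    grid_shape: tuple[int, int, int] = (32, 40, 32)
    voxel_size_mm: float = 2.4
    n_runs: int = 4
    frames_per_run: int = 422
    frames_dropped: int = 12
    tr_s: float = 1.0
    network_count: int = 15
    snr_cortex: float = 1.0
    snr_striatum: float = 0.5
    bleed_fwhm_mm: float = 4.0
    dropout_center: tuple[float, float, float] = (10.0, 14.0, -8.0)
    dropout_radius_mm: float = 6.0
    laterality_plan: dict[str, float] = Field(
        default_factory=lambda: {"LANG": 1.5, "FPN-B": 1.0 / 1.5}
    )
    dilation_level: int = 3
    rng_seed: int = 7

    def to_spec(self, seed: int | None = None) -> PhantomSpec:
        d = self.model_dump()
        if seed is not None:
            d["rng_seed"] = int(seed)
        return PhantomSpec.from_dict(d)


class PreprocessingParams(_Strict):
    band_low_hz: float = 0.01
    band_high_hz: float = 0.10
    fwhm_surface_mm: float = 2.0
    fwhm_volume_mm: float = 4.0

    @model_validator(mode="after")
    def _check_band(self) -> "PreprocessingParams":
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        return self


class ParcellationParams(_Strict):
    k: int = 400
    threshold: float | None = None
    dilation_level: int = 3
    sweep_thresholds: list[float] = Field(
        default_factory=lambda: [0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40]
    )
    threshold_scale: str = "z"  # thresholds interpreted on the Fisher-z scale

    @model_validator(mode="after")
    def _check(self) -> "ParcellationParams":
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.sweep_thresholds != sorted(self.sweep_thresholds):
            raise ValueError("sweep_thresholds must ascend")
        if self.threshold_scale not in ("z", "r"):
            raise ValueError("threshold_scale must be 'z' or 'r'")
        return self


class SeedParams(_Strict):
    volume_radius_mm: float = 4.8  # 2 voxels at 2.4 mm
    surface_hops: int = 2


class PipelineConfig(_Strict):
    """Full study description; ``master_seed`` drives all randomness."""

    phantom: PhantomParams = Field(default_factory=PhantomParams)
    preprocessing: PreprocessingParams = Field(default_factory=PreprocessingParams)
    parcellation: ParcellationParams = Field(default_factory=ParcellationParams)
    seeds: SeedParams = Field(default_factory=SeedParams)
    output_dir: str = "striomap_out"
    master_seed: int | None = None
    log_level: str = "INFO"
    tsnr_sd_ddof: int = 1  # unbiased SD estimator in tSNR

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def resolved_seed(self) -> int:
        return int(self.master_seed if self.master_seed is not None else self.phantom.rng_seed)

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
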