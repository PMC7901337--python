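"""Schema-validated run configuration.

Every default that has an instrument-protocol value keeps it: filter
passbands 442-488 / 480-562 nm, ratio bands 0.2-0.8 (adipose) and 0.8-2
(retained; 1-2 in fibrosis mode), segment sizes of 1000 px (small
samples) to 5000-12000 px (wide local excisions), a minimum of 3 points
per segment, 3.5 s per spectrum within a ~900 s Raman budget, and QC
cutoffs of 3000 counts at 780 cm^-1 and SNR 15.5.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

SCHEMA_VERSION = "1"


class PhantomConfig(BaseModel):
    shape: tuple[int, int] = (200, 200)
    tumour_radius_px: float = 35.0
    stroma_halo_px: float = 18.0
    pixel_size_um: float = 50.0
    af_noise_sd: float = 0.02
    raman_noise_sd: float = 8.0
    cosmic_ray_rate: float = 0.1
    fibrosis: bool = False
    blood_contact_fields: bool = True


class AFConfig(BaseModel):
    filter1_nm: tuple[float, float] = (442.0, 488.0)
    filter2_nm: tuple[float, float] = (480.0, 562.0)
    mask_threshold_counts: float | None = None  # None -> Otsu suggestion
    epsilon_counts: float = 1.0
    adipose_band: tuple[float, float] = (0.2, 0.8)
    retained_band: tuple[float, float] = (0.8, 2.0)
    fibrosis_mode: bool = False
    median_filter_3x3: bool = False


class SamplerConfig(BaseModel):
    target_segment_px: int = Field(5000, ge=1)
    min_points: int = Field(3, ge=1)
    t_acq_s: float = Field(3.5, gt=0)
    budget_s: float = Field(900.0, gt=0)
    features: str = "spatial"


class RamanConfig(BaseModel):
    z_threshold: float = 8.0
    calibration_model: str = "linear"
    background_order: int = Field(5, ge=1)
    smooth_window: int = 9
    smooth_polyorder: int = 3
    max_counts_780: float = 3000.0
    min_snr: float = 15.5
    qc_before_smoothing: bool = False


class ClassifierConfig(BaseModel):
    adipose_ratio_threshold: float = 2.0
    collagen_ratio_threshold: float = 1.0
    band_half_width_cm1: float = 8.0


class RunConfig(BaseModel):
    """Top-level configuration for a full pipeline run."""

    schema_version: str = SCHEMA_VERSION
    seed: int = Field(0, ge=0, lt=2**31)
    phantom: PhantomConfig = PhantomConfig()
    af: AFConfig = AFConfig()
    sampler: SamplerConfig = SamplerConfig()
    raman: RamanConfig = RamanConfig()
    classifier: ClassifierConfig = ClassifierConfig()

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema version {self.schema_version!r}"
            )
        if self.af.fibrosis_mode and self.af.retained_band == (0.8, 2.0):
            self.af.retained_band = (1.0, 2.0)
        return self

    def stage_seed(self, stage_index: int) -> int:
        """Per-stage seed: global seed plus the stage's position in the chain."""
        return (self.seed + stage_index) % 2**31

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n"

    def save(self, path: Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Path) -> "RunConfig":
        try:
            return cls.model_validate(json.loads(Path(path).read_text()))
        except (json.JSONDecodeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""
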