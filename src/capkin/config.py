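"""Run configuration: validated YAML blocks, one source of truth for defaults.

A RunConfig carries the kinetic, imaging, detection, fitting and structural
parameter blocks used by the pipeline commands, plus the seed and output
directory.  Every analysis output is stamped with the configuration hash and
seed so runs are reproducible and self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from . import __version__
from .synthetic import ImagingParams, KineticParams


class KineticsConfig(BaseModel):
    v_bare: float = 0.13
    v_cof: float = 13.0 / 30.0
    v_sat: float = 13.0
    Kd: float = 0.978
    kon_eff: float = 0.512
    koff: float = 2.5
    lambda_sev: float = 0.005
    subunit_rise: float = 2.7

    def to_params(self) -> KineticParams:
        return KineticParams(**self.model_dump())


class ImagingConfig(BaseModel):
    pixel_size: float = 100.0
    frame_interval: float = 1.0
    psf_sigma: float = 130.0
    label_fraction: float = 0.1
    background_mean: float = 100.0
    background_sd: float = 5.0
    signal_amplitude: float = 50.0
    n_frames: int = 100

    def to_params(self) -> ImagingParams:
        return ImagingParams(**self.model_dump())


class DetectionConfig(BaseModel):
    threshold: str | float = "auto"  # "auto" -> background + k*SD
    threshold_k: float = 3.0


class FittingConfig(BaseModel):
    weighted: bool = False
    side: str = "right"


class StructureConfig(BaseModel):
    contact_cutoff: float = 3.0
    probe_radius: float = 1.4
    sasa_points: int = 960
    clash_tolerance: float = 0.4
    equilibration_skip_frames: int = 0


class RunConfig(BaseModel):
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    stream_imaging: ImagingConfig = Field(
        default_factory=lambda: ImagingConfig(frame_interval=0.2, n_frames=60)
    )
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    structure: StructureConfig = Field(default_factory=StructureConfig)
    seed: int = 0
    out_dir: str = "capkin-out"

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {
            "package_version": __version__,
            "config_hash": self.config_hash(),
            "seed": self.seed,
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None gives all defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
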