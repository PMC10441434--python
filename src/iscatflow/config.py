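"""Validated configuration blocks for every pipeline stage.

All tunable parameters live in pydantic models with the instrument's
defaults; a full run is described by a single :class:`RunConfig` loadable
from TOML.  Unknown keys are rejected so configs stay auditable, and a
stable hash of the resolved config is stamped into every output table.
"""

from __future__ import annotations

import hashlib
import json
import math
import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OpticsConfig(_Strict):
    """Imaging geometry of the wide-field common-path microscope.

    The point-spread function is modelled as a Gaussian of width
    ``sigma = 0.21 * wavelength / na_detection`` expressed in sample-plane
    pixels (~1.0 px at the defaults), adequate for diffraction-limited,
    radially symmetric spots.
    """

    pixel_pitch_camera: float = Field(6.5, gt=0, description="camera pixel pitch, um")
    magnification: float = Field(100.0, gt=0)
    wavelength: float = Field(455.0, gt=0, description="illumination wavelength, nm")
    na_detection: float = Field(1.46, gt=0)
    na_illumination: float = Field(0.5, gt=0)
    frame_side: int = Field(1024, ge=16, description="frame side length, px")
    illumination_diameter: float = Field(89.5, gt=0, description="flat-top disc diameter, um")

    @property
    def pixel_pitch_sample(self) -> float:
        """Sample-plane pixel pitch in um."""
        return self.pixel_pitch_camera / self.magnification

    @property
    def fov_side(self) -> float:
        """Field-of-view side length in um."""
        return self.frame_side * self.pixel_pitch_sample

    @property
    def psf_sigma_px(self) -> float:
        sigma_um = 0.21 * self.wavelength * 1e-3 / self.na_detection
        return sigma_um / self.pixel_pitch_sample


class NoiseConfig(_Strict):
    """Camera noise model for time-averaged frames.

    ``photon_budget_per_avg_frame`` is the expected photoelectron count per
    pixel at unit illumination *after* frame averaging; the relative shot
    noise of an averaged frame is ``1/sqrt(budget)``.  ``read_noise`` is the
    residual read noise of an averaged frame, in counts.
    """

    photon_budget_per_avg_frame: float = Field(4.0e6, ge=0)
    read_noise: float = Field(0.0, ge=0, description="counts, per averaged frame")
    camera_offset: float = Field(100.0, ge=0, description="counts")
    frames_averaged: int = Field(100, ge=1)
    frame_rate: float = Field(100.0, gt=0, description="Hz")

    @property
    def effective_timestep(self) -> float:
        """Seconds between saved (averaged) frames."""
        return self.frames_averaged / self.frame_rate


class ScanPlan(_Strict):
    """Raster-scan layout: nominal tile centres plus stage jitter."""

    tile_centers: list[tuple[float, float]] = Field(..., description="(x, y) stage positions, um")
    overlap_fraction: float = Field(0.1, gt=0, le=0.5)
    stage_jitter_sd: float = Field(0.0, ge=0, description="um, isotropic")
    target_area: float = Field(0.2, gt=0, description="mm^2")

    @field_validator("tile_centers")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("scan plan needs at least one tile centre")
        return v


class TransportKineticsConfig(_Strict):
    """Stream-tube model of immunoaffinity capture in a flow channel.

    Bulk analyte at concentration ``c0`` flows at rate ``Q`` through a
    channel of height/width/length ``H``/``W``/``L``; a first-order capture
    velocity ``k_c`` removes particles onto the floor with Langmuir-type
    saturation at ``n_max``.  Depletion along the channel is governed by the
    dimensionless number ``k_c*W*L/Q``.
    """

    c0: float = Field(2.0e10, gt=0, description="bulk concentration, particles/mL")
    Q: float = Field(1.3, ge=0, description="volumetric flow rate, uL/h")
    H: float = Field(0.01, gt=0, description="channel height, mm")
    W: float = Field(0.3, gt=0, description="channel width, mm")
    L: float = Field(3.0, gt=0, description="channel length, mm")
    D: float = Field(3.0, gt=0, description="diffusion coefficient, um^2/s")
    k_c: float = Field(0.5, ge=0, description="capture velocity, um/s")
    n_max: float = Field(2.0, gt=0, description="saturation density, particles/um^2")
    t_grid: list[float] = Field(
        default_factory=lambda: [0.5, 1, 2, 3, 4, 5, 6, 7, 8], description="timepoints, h"
    )

    @field_validator("t_grid")
    @classmethod
    def _increasing(cls, v):
        if len(v) < 1 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("t_grid must be strictly increasing and nonempty")
        if v[0] <= 0:
            raise ValueError("t_grid values must be positive")
        return v

    @property
    def depletion_number(self) -> float:
        """k_c*W*L/Q, dimensionless; >~1 means strong downstream depletion."""
        if self.Q == 0:
            return math.inf
        q_um3_s = self.Q * 1e9 / 3600.0
        return self.k_c * (self.W * 1e3) * (self.L * 1e3) / q_um3_s


class PreprocessParams(_Strict):
    """Flat-fielding and local-background removal parameters."""

    median_kernel: int = Field(17, ge=3, description="square median window side, px")
    normalize_region: Literal["full", "illuminated", "dark-margin"] = "full"
    min_flatfield_frames: int = Field(60, ge=2)

    @field_validator("median_kernel")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("median_kernel must be odd")
        return v


class DetectionParams(_Strict):
    """SNR-thresholded detection and sub-pixel localization parameters."""

    snr_threshold: float = Field(4.0, gt=0)
    min_cluster_pixels: int = Field(3, ge=1)
    cluster_window: int = Field(3, ge=3)
    local_kernel: int = Field(65, ge=3, description="clipped-RMS window side, px")
    clip_factor: float = Field(2.5, gt=0, description="times the global MAD noise")
    noise_floor_factor: float = Field(0.25, gt=0, description="local-noise floor, x global")
    roi_halfwidth: int = Field(5, ge=2)
    dedup_radius: float = Field(2.0, gt=0, description="px")

    @field_validator("cluster_window", "local_kernel")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("window sizes must be odd")
        return v


class QuantifyParams(_Strict):
    """Density and contrast-classification parameters."""

    contrast_cutoff: float = Field(7.5e-3, gt=0, description="|contrast| background/signal split")
    density_unit_area: float = Field(100.0, gt=0, description="um^2")
    scan_area: float = Field(0.2, gt=0, description="mm^2")


class KineticsParams(_Strict):
    """Steady-state, dose-response and transport-diagnostic parameters."""

    rel_slope_tol: float = Field(0.02, gt=0, description="per hour")
    linear_range_tol: float = Field(0.20, gt=0, description="relative deviation from linear fit")
    n_segments: int = Field(10, ge=2, description="intra-channel gradient segments")
    da_eval_fraction: float = Field(0.5, gt=0, le=1, description="x/L where Da is evaluated")


class ChannelSpec(_Strict):
    """Metadata for one microfluidic sensing channel."""

    channel_id: str
    antibody: str = "IgG1"
    concentration: float = Field(2.0e10, ge=0, description="particles/mL")
    flow_rate: float = Field(1.3, ge=0, description="uL/h")
    timepoints: list[float] = Field(default_factory=lambda: [1, 2, 3, 4, 5], description="h")
    capture_multiplier: float = Field(1.0, ge=0, description="relative k_c for this antibody")


class RunConfig(_Strict):
    """Complete, hashable description of one reproducible run."""

    seed: int = Field(..., ge=0, lt=2**31)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    preprocess: PreprocessParams = Field(default_factory=PreprocessParams)
    detection: DetectionParams = Field(default_factory=DetectionParams)
    quantify: QuantifyParams = Field(default_factory=QuantifyParams)
    kinetics: KineticsParams = Field(default_factory=KineticsParams)
    transport: TransportKineticsConfig = Field(default_factory=TransportKineticsConfig)
    channels: list[ChannelSpec] = Field(default_factory=list)
    n_tiles_row: int = Field(2, ge=1, description="tile grid rows per channel scan")
    n_tiles_col: int = Field(3, ge=1, description="tile grid cols per channel scan")
    overlap_fraction: float = Field(0.1, gt=0, le=0.5)
    stage_jitter_um: float = Field(0.02, ge=0)
    output_dir: str = "iscatflow_out"

    @model_validator(mode="after")
    def _unique_channels(self):
        ids = [c.channel_id for c in self.channels]
        if len(ids) != len(set(ids)):
            raise ValueError("channel_id values must be unique")
        return self

    def config_hash(self) -> str:
        """Deterministic short hash of the resolved configuration."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig.model_validate(data)
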