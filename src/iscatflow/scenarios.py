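"""Canonical simulated study conditions.

Builders for the standard synthetic experiments the package is validated
on: substrate/defect scans with a background population below the contrast
cutoff and an analyte population above it, and the imaging + analysis
round trip that recovers class densities from raw tiles.  Tests and the
acceptance script share these so the conditions are stated once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DetectionParams, NoiseConfig, OpticsConfig, QuantifyParams
from .localize import localize_scan
from .preprocess import build_flatfield, normalize_frame, preprocess_frame
from .quantify import density_per_unit
from .simulate import (ContrastLaw, ParticleField, ScanResult, SpeckleField,
                       generate_flatfield_stack, generate_scan, grid_plan,
                       make_illumination, plan_union_extent,
                       sample_particle_field)
from .stitch import assemble_mosaic, build_tile_graph

# study-condition defaults: a sparse analyte population above the 7.5e-3
# contrast cutoff over a substrate-defect background just below it
BACKGROUND_LAW = ContrastLaw("lognormal", mu=float(np.log(5e-3)), sigma=0.15, signed=True)
SIGNAL_LAW = ContrastLaw("lognormal", mu=float(np.log(1.5e-2)), sigma=0.3, signed=True)
SPECKLE_RMS = 3e-4


def mixed_field(width_um: float, height_um: float, background_density: float,
                signal_density: float, seed: int,
                background_law: ContrastLaw = BACKGROUND_LAW,
                signal_law: ContrastLaw = SIGNAL_LAW) -> ParticleField:
    """Background defects plus analyte particles over one area."""
    bg = sample_particle_field(background_density, (width_um, height_um),
                               background_law, seed=seed, label="defect")
    sig = sample_particle_field(signal_density, (width_um, height_um),
                                signal_law, seed=seed + 1, label="analyte")
    return ParticleField(np.vstack([bg.positions, sig.positions]),
                         np.concatenate([bg.contrasts, sig.contrasts]),
                         np.concatenate([bg.labels, sig.labels]),
                         width_um, height_um)


@dataclass
class ChannelScanScenario:
    """A rendered raster scan with its ground truth and imaging configs."""

    scan: ScanResult
    field: ParticleField
    optics: OpticsConfig
    noise: NoiseConfig
    flatfield_frames: list[np.ndarray]
    area_um2: float


def render_channel_scan(field_or_none: ParticleField | None = None,
                        optics: OpticsConfig | None = None,
                        noise: NoiseConfig | None = None,
                        n_rows: int = 3, n_cols: int = 18,
                        overlap_fraction: float = 0.1,
                        stage_jitter_px: float = 0.3,
                        background_density: float = 3.0,
                        signal_density: float = 0.5,
                        shading_amplitude: float = 0.1,
                        n_flatfield: int = 60,
                        seed: int = 0) -> ChannelScanScenario:
    """Simulate a full raster scan of a sensing channel.

    Defaults render ~0.2 mm^2 as 3 x 18 overlapping full-size (1024 px)
    tiles with flat-top illumination, shading, static substrate speckle and
    a flat-field acquisition stack.
    """
    optics = optics or OpticsConfig()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    pitch = optics.pixel_pitch_sample
    plan = grid_plan(n_rows, n_cols, optics, overlap_fraction,
                     stage_jitter_sd=stage_jitter_px * pitch)
    w_um, h_um = plan_union_extent(plan, optics)
    field = field_or_none or mixed_field(w_um, h_um, background_density,
                                         signal_density, seed=int(rng.integers(2**31)))
    illum = make_illumination(optics, shading_amplitude, seed=int(rng.integers(2**31)))
    speckle = SpeckleField(SPECKLE_RMS, w_um + 2 * pitch, h_um + 2 * pitch, pitch,
                           optics.psf_sigma_px, seed=int(rng.integers(2**31)))
    scan = generate_scan(field, plan, illum, optics, noise,
                         background_roughness=speckle, seed=int(rng.integers(2**31)))
    ff_frames = generate_flatfield_stack(illum, optics, noise, n_frames=n_flatfield,
                                         seed=int(rng.integers(2**31)))
    return ChannelScanScenario(scan, field, optics, noise, ff_frames, w_um * h_um)


@dataclass
class ScanAnalysis:
    localizations: pd.DataFrame
    density_signal: float
    density_background: float
    transforms: pd.DataFrame
    area_um2: float


def analyze_channel_scan(sc: ChannelScanScenario,
                         detection: DetectionParams | None = None,
                         quantify: QuantifyParams | None = None,
                         use_true_origins: bool = False) -> ScanAnalysis:
    """Flat-field, stitch, localize and quantify a rendered scan."""
    detection = detection or DetectionParams()
    quantify = quantify or QuantifyParams()
    ff_norm = [normalize_frame(f, camera_offset=sc.noise.camera_offset)
               for f in sc.flatfield_frames]
    ff = build_flatfield(ff_norm)
    residuals = [preprocess_frame(t, ff, sc.optics, sc.noise).residual
                 for t in sc.scan.tiles]
    if use_true_origins:
        origins = sc.scan.true_origins_px
        transforms = pd.DataFrame({"tile_id": np.arange(len(residuals)),
                                   "x0_px": origins[:, 0], "y0_px": origins[:, 1]})
    else:
        graph = build_tile_graph(residuals, sc.scan.nominal_origins_px)
        _, transforms = assemble_mosaic(graph)
        origins = transforms[["x0_px", "y0_px"]].to_numpy()
    locs = localize_scan(residuals, origins, detection,
                         pixel_pitch_um=sc.optics.pixel_pitch_sample)
    rec = density_per_unit(locs, sc.area_um2, quantify)
    return ScanAnalysis(locs, rec.density_signal, rec.density_background,
                        transforms, sc.area_um2)


def match_localizations(locs: pd.DataFrame, truth_xy_px: np.ndarray,
                        radius_px: float = 1.0) -> tuple[int, int, int]:
    """One-to-one greedy match of detections to ground truth.

    Returns (n_matched, n_detections, n_truth).
    """
    from scipy.spatial import cKDTree

    if len(locs) == 0 or len(truth_xy_px) == 0:
        return 0, len(locs), len(truth_xy_px)
    det = locs[["x_px", "y_px"]].to_numpy()
    tree = cKDTree(truth_xy_px)
    dist, idx = tree.query(det, distance_upper_bound=radius_px)
    used: set[int] = set()
    matched = 0
    for d, k in sorted(zip(dist, idx)):
        if np.isinf(d) or k in used:
            continue
        used.add(int(k))
        matched += 1
    return matched, len(det), len(truth_xy_px)
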