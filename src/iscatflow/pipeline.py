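"""End-to-end orchestration of a multi-channel run.

For each channel in the manifest: simulate time-lapse capture, image the
final timepoint as an overlapping raster scan, build a flat field,
preprocess, stitch, localize, quantify, and finally assemble binding
curves and (when several antibodies are present) a marker fingerprint.
Binding curves over time come from the simulator's ground-truth fields;
image-based quantification is performed at the final timepoint, where the
full optical chain is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import RunConfig
from .fingerprint import build_fingerprint, call_positive_markers
from .kinetics import BindingCurve, steady_state
from .localize import localize_scan
from .preprocess import build_flatfield, normalize_frame, preprocess_frame
from .quantify import density_per_unit
from .simulate import (ParticleField, SpeckleField,
                       generate_flatfield_stack, generate_scan, grid_plan,
                       make_illumination, plan_union_extent,
                       simulate_channel_binding)
from .stitch import assemble_mosaic, build_tile_graph

DEFAULT_ROUGHNESS_RMS = 3e-4  # substrate speckle, contrast units


@dataclass
class ChannelResult:
    channel_id: str
    antibody: str
    curve: BindingCurve
    localizations: pd.DataFrame
    density_signal: float
    density_background: float
    scan_area_um2: float


@dataclass
class RunResult:
    channels: list[ChannelResult]
    fingerprint: object | None
    config_hash: str


def _scan_window_field(field: ParticleField, width: float, height: float,
                       x0: float = 0.0, y0: float = 0.0) -> ParticleField:
    """Crop a channel-floor field to the scanned window, re-origined at 0."""
    m = ((field.positions[:, 0] >= x0) & (field.positions[:, 0] < x0 + width)
         & (field.positions[:, 1] >= y0) & (field.positions[:, 1] < y0 + height))
    pos = field.positions[m] - [x0, y0]
    return ParticleField(pos, field.contrasts[m], field.labels[m], width, height)


def run_channel(cfg: RunConfig, channel_idx: int, rng: np.random.Generator
                ) -> ChannelResult:
    """Simulate and analyse one sensing channel end to end."""
    ch = cfg.channels[channel_idx]
    transport = cfg.transport.model_copy(update={
        "c0": ch.concentration, "Q": ch.flow_rate,
        "k_c": cfg.transport.k_c * ch.capture_multiplier,
        "t_grid": sorted(ch.timepoints),
    })
    sim = simulate_channel_binding(transport, seed=int(rng.integers(2**31)))

    # ground-truth binding curve over the whole channel floor
    area = sim.fields[0].area_um2
    dens = [
        (np.abs(f.contrasts) > cfg.quantify.contrast_cutoff).sum() * 100.0 / area
        for f in sim.fields
    ]
    curve = BindingCurve(ch.channel_id, np.asarray(transport.t_grid, float),
                         np.asarray(dens), ch.concentration, ch.flow_rate)
    if len(curve.times_h) >= 3:
        steady_state(curve, cfg.kinetics.rel_slope_tol)

    # image the final timepoint over a raster-scan window of the channel floor
    plan = grid_plan(cfg.n_tiles_row, cfg.n_tiles_col, cfg.optics,
                     cfg.overlap_fraction, cfg.stage_jitter_um)
    w_um, h_um = plan_union_extent(plan, cfg.optics)
    window = _scan_window_field(sim.fields[-1], w_um, h_um)
    illum = make_illumination(cfg.optics, shading_amplitude=0.1,
                              seed=int(rng.integers(2**31)))
    speckle = SpeckleField(DEFAULT_ROUGHNESS_RMS, w_um, h_um,
                           cfg.optics.pixel_pitch_sample, cfg.optics.psf_sigma_px,
                           seed=int(rng.integers(2**31)))
    scan = generate_scan(window, plan, illum, cfg.optics, cfg.noise,
                         background_roughness=speckle,
                         seed=int(rng.integers(2**31)))

    ff_frames = generate_flatfield_stack(illum, cfg.optics, cfg.noise,
                                         n_frames=max(cfg.preprocess.min_flatfield_frames, 60),
                                         seed=int(rng.integers(2**31)))
    ff_norm = [normalize_frame(f, camera_offset=cfg.noise.camera_offset)
               for f in ff_frames]
    ff = build_flatfield(ff_norm, min_frames=cfg.preprocess.min_flatfield_frames)

    residuals = [preprocess_frame(t, ff, cfg.optics, cfg.noise, cfg.preprocess).residual
                 for t in scan.tiles]
    graph = build_tile_graph(residuals, scan.nominal_origins_px)
    _, transforms = assemble_mosaic(graph)
    origins = transforms[["x0_px", "y0_px"]].to_numpy()
    locs = localize_scan(residuals, origins, cfg.detection,
                         pixel_pitch_um=cfg.optics.pixel_pitch_sample)
    scan_area = w_um * h_um
    rec = density_per_unit(locs, scan_area, cfg.quantify, channel_id=ch.channel_id,
                           antibody=ch.antibody)
    return ChannelResult(ch.channel_id, ch.antibody, curve, locs,
                         rec.density_signal, rec.density_background, scan_area)


def run_all(cfg: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Run every channel in the manifest and assemble the fingerprint."""
    if not cfg.channels:
        raise ValueError("run config declares no channels")
    rng = np.random.default_rng(cfg.seed)
    chash = cfg.config_hash()
    results = [run_channel(cfg, i, rng) for i in range(len(cfg.channels))]

    fp = None
    antibodies = {r.antibody for r in results}
    if "IgG1" in antibodies and len(antibodies) >= 2:
        reps: dict[str, dict[str, float]] = {}
        for r in results:
            reps.setdefault("rep0", {})[r.antibody] = r.density_signal
        fp = build_fingerprint(list(reps.values()))
        call_positive_markers(fp)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for r in results:
            _io.write_table(outdir / f"localizations_{r.channel_id}.csv",
                            r.localizations, chash)
            _io.write_table(outdir / f"curve_{r.channel_id}.csv",
                            pd.DataFrame({"t_hours": r.curve.times_h,
                                          "density_signal": r.curve.densities}), chash)
        summary = pd.DataFrame({
            "channel_id": [r.channel_id for r in results],
            "antibody": [r.antibody for r in results],
            "density_signal": [r.density_signal for r in results],
            "density_background": [r.density_background for r in results],
            "t_steady_h": [r.curve.t_steady for r in results],
        })
        _io.write_table(outdir / "summary.csv", summary, chash)
        if fp is not None:
            _io.write_table(outdir / "fingerprint.csv", fp.to_table(), chash)
        _io.write_sidecar(outdir / "run.json",
                          {"config_hash": chash, "n_channels": len(results)})
    return RunResult(results, fp, chash)
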