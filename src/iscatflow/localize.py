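"""Particle detection and sub-pixel localization.

Chain: robust global noise (scaled MAD) -> clipped-RMS local noise map ->
SNR image -> two-criterion candidate detection (pixel SNR threshold plus
3-in-3x3 clustering) -> radial-symmetry sub-pixel centre -> signed contrast
and integrated contrast measurement.  Works per tile; ``localize_scan``
maps tile-local detections into mosaic coordinates and merges duplicates
from overlap regions.

SNR uses |residual| throughout, so bright and dark interferometric spots
are detected alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import DetectionParams

__all__ = [
    "NoiseModel",
    "global_noise",
    "local_noise_map",
    "estimate_noise",
    "CandidateROI",
    "detect_candidates",
    "radial_symmetry_center",
    "measure_contrast",
    "localize_frame",
    "localize_scan",
    "LOCALIZATION_COLUMNS",
]

MAD_TO_SIGMA = 1.4826  # Gaussian-consistent scaling of the median absolute deviation

LOCALIZATION_COLUMNS = ["x_px", "y_px", "snr", "contrast", "integrated_contrast",
                        "cluster_size", "tile_id", "edge_flag"]


@dataclass
class NoiseModel:
    """Global scalar noise plus per-pixel local noise (same shape as frame)."""

    sigma_global: float
    sigma_local: np.ndarray
    floored: np.ndarray | None = None  # pixels where the floor was applied


def global_noise(residual: np.ndarray) -> float:
    """Robust noise scale: 1.4826 x median absolute deviation.

    Insensitive to a small fraction of bright outlier pixels (particles),
    unlike the plain standard deviation.
    """
    v = np.asarray(residual, dtype=float).ravel()
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        raise ValueError("constant frame: noise scale undefined")
    return MAD_TO_SIGMA * mad


def local_noise_map(residual: np.ndarray, sigma_global: float,
                    params: DetectionParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Clipped-RMS local noise.

    At each pixel: RMS over the ``local_kernel`` square window of the
    residual values with ``|v| <= clip_factor * sigma_global`` (windows
    clipped at borders).  Particle pixels exceed the clip and are excluded,
    so the map reflects the background noise even under a spot.  The result
    is floored at ``noise_floor_factor * sigma_global``; returns
    ``(map, floored_mask)``.
    """
    if sigma_global <= 0:
        raise ValueError("sigma_global must be positive")
    params = params or DetectionParams()
    v = np.asarray(residual, dtype=float)
    keep = np.abs(v) <= params.clip_factor * sigma_global
    k = params.local_kernel
    # clipped windows at borders: zero-padded window sums normalized by counts
    sq_sum = ndimage.uniform_filter(np.where(keep, v * v, 0.0), size=k,
                                    mode="constant", cval=0.0) * (k * k)
    cnt = ndimage.uniform_filter(keep.astype(float), size=k,
                                 mode="constant", cval=0.0) * (k * k)
    cnt_int = np.rint(cnt)
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt(np.clip(sq_sum, 0, None) / np.where(cnt_int > 0, cnt_int, 1))
    rms[cnt_int == 0] = 0.0
    floor = params.noise_floor_factor * sigma_global
    floored = rms < floor
    return np.maximum(rms, floor), floored


def estimate_noise(residual: np.ndarray,
                   params: DetectionParams | None = None) -> NoiseModel:
    sg = global_noise(residual)
    sl, floored = local_noise_map(residual, sg, params)
    return NoiseModel(sg, sl, floored)


@dataclass
class CandidateROI:
    """One detected candidate: peak pixel, ROI bounds and cluster size."""

    row: int
    col: int
    slices: tuple[slice, slice]
    cluster_size: int
    snr_peak: float
    edge_flag: bool


def detect_candidates(residual: np.ndarray, noise_map: np.ndarray,
                      params: DetectionParams | None = None) -> list[CandidateROI]:
    """Two-criterion detection.

    A pixel is a seed if ``|residual| / noise >= snr_threshold`` AND at
    least ``min_cluster_pixels`` seed pixels (itself included) lie in its
    ``cluster_window`` square neighbourhood.  Qualifying seeds are merged by
    8-connectivity; each component yields one ROI of side
    ``2*roi_halfwidth + 1`` centred on its maximum-SNR pixel (lowest
    (row, col) on ties).
    """
    params = params or DetectionParams()
    if residual.shape != noise_map.shape:
        raise ValueError("residual and noise map shapes differ")
    snr = np.abs(np.asarray(residual, dtype=float)) / noise_map
    seeds = snr >= params.snr_threshold
    w = params.cluster_window
    neigh = ndimage.uniform_filter(seeds.astype(float), size=w,
                                   mode="constant", cval=0.0) * (w * w)
    clustered = seeds & (np.rint(neigh) >= params.min_cluster_pixels)
    labels, n_comp = ndimage.label(clustered, structure=np.ones((3, 3), dtype=int))
    rois: list[CandidateROI] = []
    h, wd = residual.shape
    hw = params.roi_halfwidth
    for comp in range(1, n_comp + 1):
        mask = labels == comp
        comp_snr = np.where(mask, snr, -np.inf)
        peak = np.unravel_index(np.argmax(comp_snr), comp_snr.shape)  # first = lexicographic min
        r, c = int(peak[0]), int(peak[1])
        r0, r1 = r - hw, r + hw + 1
        c0, c1 = c - hw, c + hw + 1
        edge = r0 < 0 or c0 < 0 or r1 > h or c1 > wd
        sl = (slice(max(r0, 0), min(r1, h)), slice(max(c0, 0), min(c1, wd)))
        rois.append(CandidateROI(r, c, sl, int(mask.sum()), float(snr[r, c]), edge))
    return rois


def radial_symmetry_center(roi: np.ndarray) -> tuple[float, float]:
    """Sub-pixel centre of a radially symmetric spot (gradient line method).

    Cross-differences on the 45-degree-rotated midpoint lattice give local
    gradients; each midpoint defines a line through it along the gradient
    direction, and the centre is the weighted least-squares point minimizing
    the perpendicular distances (weights: squared gradient magnitude over
    distance to the magnitude centroid).  Sign-insensitive through squared
    weights, so dark and bright spots localize identically.

    Returns (dx, dy) relative to the ROI's geometric centre, in px.
    """
    I = np.asarray(roi, dtype=float)
    ny, nx = I.shape
    if ny < 5 or nx < 5:
        raise ValueError("ROI must be at least 5x5")
    if np.ptp(I) == 0:
        raise ValueError("constant ROI: no radial symmetry centre")
    # midpoint-lattice coordinates, origin at the ROI centre
    xm = (np.arange(nx - 1) - (nx - 2) / 2.0)[None, :]
    ym = (np.arange(ny - 1) - (ny - 2) / 2.0)[:, None]
    dIdu = I[:-1, 1:] - I[1:, :-1]
    dIdv = I[:-1, :-1] - I[1:, 1:]
    h = np.ones((3, 3)) / 9.0
    fdu = ndimage.convolve(dIdu, h, mode="constant", cval=0.0)
    fdv = ndimage.convolve(dIdv, h, mode="constant", cval=0.0)
    mag2 = fdu**2 + fdv**2
    with np.errstate(invalid="ignore", divide="ignore"):
        m = -(fdv + fdu) / (fdu - fdv)
    bad = ~np.isfinite(m)
    m = np.where(bad, 0.0, m)
    mag2 = np.where(bad & (fdu**2 + fdv**2 == 0), 0.0, mag2)
    b = ym - m * xm
    s = mag2.sum()
    if s == 0:
        raise ValueError("zero gradient energy: degenerate ROI")
    xc0 = (mag2 * xm).sum() / s
    yc0 = (mag2 * ym).sum() / s
    dist = np.sqrt((xm - xc0) ** 2 + (ym - yc0) ** 2)
    w = mag2 / np.maximum(dist, 1e-9)
    wm2p1 = w / (m * m + 1.0)
    sw = wm2p1.sum()
    smw = (m * wm2p1).sum()
    smmw = (m * m * wm2p1).sum()
    sbw = (b * wm2p1).sum()
    smbw = (m * b * wm2p1).sum()
    det = smw * smw - smmw * sw
    if abs(det) < 1e-12 * max(sw, 1e-30) ** 2:
        raise ValueError("singular system: ROI has no radial symmetry centre")
    xc = (smbw * sw - smw * sbw) / det
    yc = (smbw * smw - smmw * sbw) / det
    return float(xc), float(yc)


def _lagrange3(t: float) -> np.ndarray:
    """Quadratic Lagrange weights for nodes (-1, 0, 1) evaluated at t."""
    return np.array([t * (t - 1) / 2.0, 1.0 - t * t, t * (t + 1) / 2.0])


def _biquadratic_value(patch3: np.ndarray, dx: float, dy: float) -> float:
    """Bi-quadratic (tensor-product) interpolation of a 3x3 patch at (dx, dy).

    A Gaussian peak is exactly quadratic in log magnitude, so when the
    whole patch shares the centre's sign the interpolation runs on
    log|v| and is unbiased for Gaussian spots at any sub-pixel offset;
    otherwise (noise-dominated neighbours) it falls back to the value
    domain.
    """
    wx = _lagrange3(dx)
    wy = _lagrange3(dy)
    centre = patch3[1, 1]
    s = np.sign(centre) or 1.0
    vals = patch3 * s
    if vals.min() > 0.02 * vals[1, 1] and vals[1, 1] > 0:
        return float(s * np.exp(wy @ np.log(vals) @ wx))
    return float(s * (wy @ vals @ wx))


def measure_contrast(residual: np.ndarray, center_xy: tuple[float, float],
                     params: DetectionParams | None = None) -> tuple[float, float, bool]:
    """Signed contrast at a sub-pixel centre, plus the ROI-integrated contrast.

    Contrast is the residual evaluated at the centre via a bi-quadratic fit
    of the 3x3 neighbourhood of the nearest pixel; integrated contrast sums
    the residual over the detection ROI.  Returns
    ``(contrast, integrated, edge_flag)``; near the frame edge the values
    are still reported but flagged.
    """
    params = params or DetectionParams()
    h, w = residual.shape
    x, y = center_xy
    j, i = int(round(x)), int(round(y))
    if not (0 <= i < h and 0 <= j < w):
        raise ValueError("centre outside frame")
    hw = params.roi_halfwidth
    edge = i - hw < 0 or j - hw < 0 or i + hw + 1 > h or j + hw + 1 > w
    if 1 <= i < h - 1 and 1 <= j < w - 1:
        contrast = _biquadratic_value(residual[i - 1:i + 2, j - 1:j + 2], x - j, y - i)
    else:
        contrast = float(residual[i, j])
    sl = (slice(max(i - hw, 0), min(i + hw + 1, h)),
          slice(max(j - hw, 0), min(j + hw + 1, w)))
    integrated = float(residual[sl].sum())
    return float(contrast), integrated, edge


def localize_frame(residual: np.ndarray, params: DetectionParams | None = None,
                   tile_id: int = 0,
                   noise: NoiseModel | None = None) -> pd.DataFrame:
    """Detect and localize all spots in one residual frame.

    Returns a table with tile-local sub-pixel positions (x = column,
    y = row, 0-based pixel-centre convention), SNR at the peak pixel,
    signed contrast, integrated contrast, cluster size and edge flags.
    """
    params = params or DetectionParams()
    nm = noise or estimate_noise(residual, params)
    rois = detect_candidates(residual, nm.sigma_local, params)
    rows = []
    for roi in rois:
        patch = residual[roi.slices]
        try:
            dx, dy = radial_symmetry_center(patch)
        except ValueError:
            continue
        # ROI centre in frame coordinates (may be off-centre when clipped)
        cy = (roi.slices[0].start + roi.slices[0].stop - 1) / 2.0
        cx = (roi.slices[1].start + roi.slices[1].stop - 1) / 2.0
        x, y = cx + dx, cy + dy
        if not (0 <= round(y) < residual.shape[0] and 0 <= round(x) < residual.shape[1]):
            continue
        contrast, integrated, edge = measure_contrast(residual, (x, y), params)
        rows.append((x, y, roi.snr_peak, contrast, integrated, roi.cluster_size,
                     tile_id, bool(edge or roi.edge_flag)))
    return pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)


def _dedup(df: pd.DataFrame, radius: float) -> pd.DataFrame:
    """Greedy duplicate merge: keep the higher-SNR record within ``radius`` px."""
    if len(df) < 2:
        return df.reset_index(drop=True)
    order = np.argsort(-df["snr"].to_numpy())
    pts = df[["x_px", "y_px"]].to_numpy()[order]
    tree = cKDTree(pts)
    keep = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(pts[i], radius):
            if j > i:
                keep[j] = False
    return df.iloc[order[keep]].sort_index().reset_index(drop=True)


def localize_scan(residuals: list[np.ndarray], origins_px: np.ndarray,
                  params: DetectionParams | None = None,
                  pixel_pitch_um: float | None = None) -> pd.DataFrame:
    """Localize every tile of a scan and merge into mosaic coordinates.

    ``origins_px[k]`` is tile k's (x0, y0) placement in global pixels.
    Duplicates from overlap regions (within ``dedup_radius``) are merged,
    keeping the higher-SNR record.  If ``pixel_pitch_um`` is given, columns
    ``x_um``/``y_um`` are added.
    """
    params = params or DetectionParams()
    tables = []
    for tid, res in enumerate(residuals):
        t = localize_frame(res, params, tile_id=tid)
        t["x_px"] += origins_px[tid][0]
        t["y_px"] += origins_px[tid][1]
        tables.append(t)
    df = (pd.concat(tables, ignore_index=True) if tables
          else pd.DataFrame(columns=LOCALIZATION_COLUMNS))
    df = _dedup(df, params.dedup_radius)
    if pixel_pitch_um is not None:
        df["x_um"] = df["x_px"] * pixel_pitch_um
        df["y_um"] = df["y_px"] * pixel_pitch_um
    return df
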