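"""Phase-correlation tile registration and mosaic assembly.

Inter-tile translations are estimated by phase correlation of the
overlapping strips predicted by the stage's nominal offsets, with
sub-pixel refinement by local Fourier upsampling.  Global tile placement
chains pairwise estimates along a spanning tree rooted at tile 0, falling
back to the stage prior wherever the correlation confidence is low.  No
blending by default (overwrite): feathering would alter spot contrast,
which is the measurand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

__all__ = ["phase_correlation_offset", "TileGraph", "build_tile_graph",
           "assemble_mosaic", "mosaic_to_tile", "tile_to_mosaic"]


def phase_correlation_offset(a: np.ndarray, b: np.ndarray,
                             upsample: int = 20) -> tuple[float, float, float]:
    """Translation (dx, dy) such that ``b(x) ~= a(x - offset)``, plus confidence.

    The offset maximizes the inverse transform of the normalized
    cross-power spectrum; ``confidence`` is that correlation surface's peak,
    in [0, 1] (1 for an exact cyclic shift, ~0 for unrelated images).
    Sub-pixel refinement by local upsampling when ``upsample > 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tiles must have the same shape")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance tile: phase correlation undefined")
    F = np.fft.fft2(a)
    G = np.fft.fft2(b)
    cross = F * np.conj(G)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    surface = np.fft.ifft2(cross / mag).real
    confidence = float(np.clip(surface.max(), 0.0, 1.0))
    shift, _, _ = phase_cross_correlation(b, a, upsample_factor=max(int(upsample), 1),
                                          normalization=None)
    dy, dx = float(shift[0]), float(shift[1])
    return dx, dy, confidence


@dataclass
class TileGraph:
    """Registered tile set: pairwise estimates plus chained global placement."""

    residuals: list[np.ndarray]
    nominal_origins_px: np.ndarray  # (n, 2) = (x0, y0) stage prior
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)
    global_origins_px: np.ndarray | None = None


def _overlap_strips(a: np.ndarray, b: np.ndarray, nominal_delta: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Same-shape subwindows of a and b covering their nominal overlap.

    Returns (strip_a, strip_b, base) where ``base = (ax0 - bx0, ay0 - by0)``
    is the integer offset implied by the strip anchors; the true tile offset
    is ``base`` minus the measured inter-strip shift.
    """
    h, w = a.shape
    dx, dy = nominal_delta  # origin_b - origin_a, px
    x0 = max(0.0, dx)
    x1 = min(float(w), dx + w)
    y0 = max(0.0, dy)
    y1 = min(float(h), dy + h)
    if x1 - x0 < 16 or y1 - y0 < 16:
        return None
    ax0 = int(np.floor(x0))
    ay0 = int(np.floor(y0))
    bx0 = int(np.floor(x0 - dx))
    by0 = int(np.floor(y0 - dy))
    hh = min(int(np.floor(y1)) - ay0, h - by0)
    ww = min(int(np.floor(x1)) - ax0, w - bx0)
    sa = a[ay0:ay0 + hh, ax0:ax0 + ww]
    sb = b[by0:by0 + hh, bx0:bx0 + ww]
    if sa.shape != sb.shape or min(sa.shape) < 16:
        return None
    return sa, sb, np.array([ax0 - bx0, ay0 - by0], dtype=float)


def build_tile_graph(residuals: list[np.ndarray], nominal_origins_px: np.ndarray,
                     upsample: int = 50, min_confidence: float = 0.05,
                     max_correction_px: float = 5.0,
                     min_overlap_frac: float = 0.05) -> TileGraph:
    """Estimate pairwise offsets between nominally adjacent tiles.

    Two tiles are adjacent if their nominal footprints overlap by at least
    ``min_overlap_frac`` of the tile area (corner-only overlaps are too
    small to register reliably and are skipped).  For each adjacent pair,
    phase correlation of the overlap strips refines the nominal offset;
    estimates with confidence below ``min_confidence`` or a correction
    larger than ``max_correction_px`` fall back to the stage prior
    (flagged).
    """
    n = len(residuals)
    nominal = np.asarray(nominal_origins_px, dtype=float)
    h, w = residuals[0].shape
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            delta = nominal[j] - nominal[i]
            if abs(delta[0]) >= w or abs(delta[1]) >= h:
                continue
            ov = (w - abs(delta[0])) * (h - abs(delta[1]))
            if ov < min_overlap_frac * w * h:
                continue
            ests, confs = [], []
            for (ti, tj, d, sgn) in ((i, j, delta, 1.0), (j, i, -delta, -1.0)):
                strips = _overlap_strips(residuals[ti], residuals[tj], d)
                if strips is None:
                    continue
                sa, sb, base = strips
                try:
                    ddx, ddy, conf = phase_correlation_offset(sa, sb, upsample)
                except ValueError:
                    continue
                # true offset = integer strip base minus the measured strip shift
                ests.append(sgn * (base - np.array([ddx, ddy])))
                confs.append(conf)
            fallback = False
            if ests:
                est = np.mean(ests, axis=0)
                conf = float(np.mean(confs))
            else:
                est, conf = delta.astype(float), 0.0
            if conf < min_confidence or np.hypot(*(est - delta)) > max_correction_px:
                est = delta.astype(float)
                fallback = True
            rows.append((i, j, est[0], est[1], conf, fallback))
    edges = pd.DataFrame(rows, columns=["i", "j", "dx_px", "dy_px",
                                        "confidence", "fallback"])
    return TileGraph(residuals, nominal, edges)


def _chain_global(graph: TileGraph) -> np.ndarray:
    """Chain pairwise offsets along a max-confidence spanning tree from tile 0."""
    import networkx as nx

    n = len(graph.residuals)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for e in graph.edges.itertuples():
        g.add_edge(int(e.i), int(e.j), weight=1.0 - e.confidence,
                   offset=np.array([e.dx_px, e.dy_px]))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise ValueError(f"disconnected tile graph: components {sorted(map(sorted, comps))}")
    tree = nx.minimum_spanning_tree(g)
    origins = np.zeros((n, 2))
    origins[0] = graph.nominal_origins_px[0]
    for parent, child in nx.bfs_edges(tree, 0):
        off = tree.edges[parent, child]["offset"]
        sign = 1.0 if parent < child else -1.0
        origins[child] = origins[parent] + sign * off
    return origins


def assemble_mosaic(graph: TileGraph, blend: str = "overwrite"
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Place all tiles on a common canvas.

    Returns the mosaic and a transforms table (tile_id, x0_px, y0_px) with
    which any localization can be mapped tile <-> mosaic.  ``blend`` is
    ``overwrite`` (later tiles win; contrast untouched) or ``feather``
    (distance-weighted average in overlaps).
    """
    if blend not in ("overwrite", "feather"):
        raise ValueError("blend must be 'overwrite' or 'feather'")
    if graph.global_origins_px is None:
        graph.global_origins_px = (_chain_global(graph) if len(graph.residuals) > 1
                                   else graph.nominal_origins_px.astype(float).copy())
    origins = graph.global_origins_px
    h, w = graph.residuals[0].shape
    mins = origins.min(axis=0)
    shifted = origins - mins
    W = int(np.ceil(shifted[:, 0].max() + w))
    H = int(np.ceil(shifted[:, 1].max() + h))
    mosaic = np.zeros((H, W))
    if blend == "feather":
        weight = np.zeros((H, W))
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        ramp = np.minimum.reduce([xx + 1, w - xx, yy + 1, h - yy])
    for k, res in enumerate(graph.residuals):
        x0 = int(round(shifted[k, 0]))
        y0 = int(round(shifted[k, 1]))
        if blend == "overwrite":
            mosaic[y0:y0 + h, x0:x0 + w] = res
        else:
            mosaic[y0:y0 + h, x0:x0 + w] += res * ramp
            weight[y0:y0 + h, x0:x0 + w] += ramp
    if blend == "feather":
        mosaic = np.divide(mosaic, weight, out=np.zeros_like(mosaic), where=weight > 0)
    transforms = pd.DataFrame({
        "tile_id": np.arange(len(graph.residuals)),
        "x0_px": shifted[:, 0],
        "y0_px": shifted[:, 1],
    })
    return mosaic, transforms


def tile_to_mosaic(x: float, y: float, transforms: pd.DataFrame, tile_id: int
                   ) -> tuple[float, float]:
    row = transforms.loc[transforms["tile_id"] == tile_id].iloc[0]
    return x + row["x0_px"], y + row["y0_px"]


def mosaic_to_tile(x: float, y: float, transforms: pd.DataFrame, tile_id: int
                   ) -> tuple[float, float]:
    row = transforms.loc[transforms["tile_id"] == tile_id].iloc[0]
    return x - row["x0_px"], y - row["y0_px"]
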