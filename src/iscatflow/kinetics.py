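"""Binding-curve analysis: steady state, dose response, transport diagnostics.

Surface-capture time series are reduced to (i) a steady-state time and
density (earliest time from which the relative slope stays below a
tolerance), (ii) a dose-response line with a linear range and saturation
plateau, (iii) a Damkohler-number diagnostic of reaction- vs
transport-limited capture, and (iv) intra-channel density gradients along
the flow axis, which develop under strong depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import KineticsParams, QuantifyParams
from .quantify import classify_contrast

__all__ = ["BindingCurve", "binding_curve", "steady_state", "DoseResponse",
           "dose_response", "TransportDiagnostic", "damkohler", "spatial_gradient"]


@dataclass
class BindingCurve:
    """Per-channel time series of signal-class density (counts per 100 um^2)."""

    channel_id: str
    times_h: np.ndarray
    densities: np.ndarray
    concentration: float = float("nan")  # particles/mL
    flow_rate: float = float("nan")  # uL/h
    t_steady: float | None = None
    n_steady: float | None = None
    decrease_flagged: bool = False


def binding_curve(tables: list[pd.DataFrame], times_h, area_um2: float,
                  channel_id: str = "", concentration: float = float("nan"),
                  flow_rate: float = float("nan"),
                  params: QuantifyParams | None = None) -> BindingCurve:
    """Signal-region density per timepoint from localization tables.

    Density decreases beyond Poisson noise between consecutive timepoints
    are flagged (possible unbinding) but kept.
    """
    times = np.asarray(times_h, dtype=float)
    if len(tables) != len(times):
        raise ValueError("one localization table per timepoint required")
    if len(times) < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    params = params or QuantifyParams()
    counts = np.array([(classify_contrast(t, params) == "signal").sum() for t in tables],
                      dtype=float)
    dens = counts * params.density_unit_area / area_um2
    drops = counts[1:] < counts[:-1] - 3.0 * np.sqrt(np.maximum(counts[:-1], 1.0))
    return BindingCurve(channel_id, times, dens, concentration, flow_rate,
                        decrease_flagged=bool(drops.any()))


def steady_state(curve: BindingCurve,
                 rel_slope_tol: float = 0.02) -> tuple[float | None, float | None]:
    """Earliest time from which the local relative slope stays below tolerance.

    The relative slope between consecutive points is
    ``(n[k+1] - n[k]) / (dt * n[k])`` in 1/h; steady state starts at the
    first timepoint after which every subsequent slope is below
    ``rel_slope_tol``.  ``n_steady`` is the mean density from there on.
    Returns (None, None) when the curve never settles; the call also
    annotates the curve in place.
    """
    t, n = curve.times_h, curve.densities
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints for a steady-state call")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.diff(n)) / (np.diff(t) * np.where(n[:-1] > 0, n[:-1], np.inf))
    ok = rel < rel_slope_tol
    idx = None
    for k in range(len(ok)):
        if ok[k:].all():
            idx = k
            break
    if idx is None:
        curve.t_steady = curve.n_steady = None
        return None, None
    curve.t_steady = float(t[idx])
    curve.n_steady = float(n[idx:].mean())
    return curve.t_steady, curve.n_steady


@dataclass
class DoseResponse:
    """Dose-response fit: linear low-concentration regime plus saturation."""

    concentrations: np.ndarray
    densities: np.ndarray
    slope: float  # density per (particles/mL)
    linear_range_upper: float | None  # highest concentration still on the line
    saturation_density: float | None  # mean density above the linear range
    linear_range_reached: bool


def dose_response(concentrations, densities,
                  params: KineticsParams | None = None) -> DoseResponse:
    """Fit the low-concentration line through the origin and find its upper end.

    The slope is fit over the growing low-concentration subset; the linear
    range ends at the highest concentration whose density is within
    ``linear_range_tol`` of the line.  Densities above the range average
    into the saturation plateau (None if the range covers all data).
    """
    params = params or KineticsParams()
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(densities, dtype=float)
    order = np.argsort(c)
    c, d = c[order], d[order]
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")

    def slope_of(k):  # origin-constrained least squares on first k points
        cc, dd = c[:k], d[:k]
        return float((cc * dd).sum() / (cc * cc).sum())

    k = 3
    slope = slope_of(k)
    while k < len(c):
        pred = slope_of(k + 1) * c[k]
        if pred <= 0 or abs(d[k] - pred) / pred > params.linear_range_tol:
            break
        k += 1
        slope = slope_of(k)
    in_range = np.abs(d - slope * c) <= params.linear_range_tol * np.abs(slope * c)
    upper = float(c[:k][in_range[:k]].max()) if in_range[:k].any() else None
    above = d[k:]
    saturation = float(above.mean()) if len(above) else None
    return DoseResponse(c, d, slope, upper, saturation, linear_range_reached=k < len(c))


@dataclass
class TransportDiagnostic:
    """Damkohler number and depletion number with a regime label."""

    Da: float
    depletion_number: float
    delta_um: float
    regime: str  # "reaction-limited" | "transport-limited"


def damkohler(k_on_per_M_s: float, b_m_mol_per_cm2: float, H_mm: float, W_mm: float,
              L_mm: float, Q_uL_h: float, D_um2_s: float,
              params: KineticsParams | None = None) -> TransportDiagnostic:
    """Ratio of surface reaction rate to diffusive mass-transport supply.

    ``Da = k_on * b_m * delta / D`` with the Leveque-type depletion-layer
    thickness ``delta = (D x H^2 W / (6 Q))^(1/3)`` evaluated at
    ``x = da_eval_fraction * L`` (default mid-channel).  ``Da > 1`` marks
    transport-limited capture.  Also reports the channel depletion number
    ``k_c W L / Q`` with ``k_c = k_on * b_m``.
    """
    params = params or KineticsParams()
    vals = [k_on_per_M_s, b_m_mol_per_cm2, H_mm, W_mm, L_mm, Q_uL_h, D_um2_s]
    if any(v <= 0 for v in vals):
        raise ValueError("all transport parameters must be positive")
    # k_on [L/mol/s] * b_m [mol/cm^2] = 1000 cm/s per unit product -> um/s
    k_c_um_s = k_on_per_M_s * 1e3 * b_m_mol_per_cm2 * 1e4  # cm/s -> um/s
    H, W, L = H_mm * 1e3, W_mm * 1e3, L_mm * 1e3  # um
    Q = Q_uL_h * 1e9 / 3600.0  # um^3/s
    x = params.da_eval_fraction * L
    delta = (D_um2_s * x * H**2 * W / (6.0 * Q)) ** (1.0 / 3.0)
    Da = k_c_um_s * delta / D_um2_s
    depletion = k_c_um_s * W * L / Q
    regime = "transport-limited" if Da > 1 else "reaction-limited"
    return TransportDiagnostic(float(Da), float(depletion), float(delta), regime)


def spatial_gradient(locs: pd.DataFrame, channel_length_um: float,
                     channel_width_um: float, flow_axis: str = "x_um",
                     n_segments: int = 10,
                     params: QuantifyParams | None = None) -> pd.DataFrame:
    """Signal density in equal-length segments along the flow axis.

    Segment 1 is the channel entrance.  The returned table carries a
    ``spearman_rho`` attribute (density vs segment index): strongly
    negative values indicate a depletion gradient from transport-limited
    capture.  Segments with zero counts are valid.
    """
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    params = params or QuantifyParams()
    sig = locs[classify_contrast(locs, params) == "signal"]
    edges = np.linspace(0, channel_length_um, n_segments + 1)
    seg_area = (channel_length_um / n_segments) * channel_width_um
    x = sig[flow_axis].to_numpy(dtype=float)
    counts = np.histogram(x, bins=edges)[0]
    dens = counts * params.density_unit_area / seg_area
    out = pd.DataFrame({"segment": np.arange(1, n_segments + 1),
                        "x_center_um": 0.5 * (edges[:-1] + edges[1:]),
                        "count": counts, "density": dens})
    if np.ptp(dens) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(out["segment"], dens).statistic)
    out.attrs["spearman_rho"] = rho
    return out
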