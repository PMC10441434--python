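"""Density and contrast-distribution metrics from localization tables.

Localizations are split at a fixed |contrast| cutoff into a ``background``
class (substrate roughness and minute inhomogeneities) and a ``signal``
class (particles of interest); densities are reported as counts per
100 um^2.  Condition groups are compared by one-way ANOVA on per-channel
densities (the replicate unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import QuantifyParams

__all__ = ["DensityRecord", "classify_contrast", "density_per_unit",
           "contrast_histogram", "compare_conditions"]


@dataclass
class DensityRecord:
    """Per-channel background/signal counts and densities (per 100 um^2)."""

    channel_id: str
    area_um2: float
    n_background: int
    n_signal: int
    density_background: float
    density_signal: float
    n_excluded: int = 0
    condition: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_background + self.n_signal


def classify_contrast(locs: pd.DataFrame,
                      params: QuantifyParams | None = None) -> pd.Series:
    """Label each localization ``background`` (|contrast| <= cutoff) or ``signal``.

    The comparison is inclusive on the background side.  Rows with missing
    contrast are labelled ``excluded`` (QC tally; they never enter either
    class).
    """
    params = params or QuantifyParams()
    c = locs["contrast"].to_numpy(dtype=float)
    labels = np.where(np.abs(c) <= params.contrast_cutoff, "background", "signal")
    labels = np.where(np.isfinite(c), labels, "excluded")
    return pd.Series(labels, index=locs.index, name="class")


def density_per_unit(locs: pd.DataFrame, area_um2: float,
                     params: QuantifyParams | None = None,
                     channel_id: str = "", **condition) -> DensityRecord:
    """Background/signal densities in counts per ``density_unit_area`` (100 um^2)."""
    params = params or QuantifyParams()
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    cls = classify_contrast(locs, params)
    nb = int((cls == "background").sum())
    ns = int((cls == "signal").sum())
    nx = int((cls == "excluded").sum())
    scale = params.density_unit_area / area_um2
    return DensityRecord(channel_id, area_um2, nb, ns, nb * scale, ns * scale,
                         n_excluded=nx, condition=condition)


def contrast_histogram(locs: pd.DataFrame, bins=50, log: bool = True,
                       params: QuantifyParams | None = None) -> pd.DataFrame:
    """Histogram of |contrast| with the background/signal cutoff annotated.

    ``bins`` may be an integer (log- or linearly spaced over the data range
    per ``log``) or an explicit edge array.  Returns a table of bin edges,
    counts and an ``above_cutoff`` marker per bin.
    """
    params = params or QuantifyParams()
    if len(locs) == 0:
        raise ValueError("no localizations to histogram")
    mag = np.abs(locs["contrast"].to_numpy(dtype=float))
    mag = mag[np.isfinite(mag)]
    if np.isscalar(bins):
        lo, hi = mag.min(), mag.max()
        if log:
            lo = max(lo, 1e-6)
            edges = np.logspace(np.log10(lo), np.log10(max(hi, lo * 1.001)), int(bins) + 1)
        else:
            edges = np.linspace(lo, max(hi, lo + 1e-12), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(mag, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "bin_center": centers, "count": counts,
                         "above_cutoff": centers > params.contrast_cutoff})


def compare_conditions(groups: dict[str, list[float]]) -> dict:
    """Group means/SDs and one-way ANOVA across condition groups.

    ``groups`` maps a condition label to its per-channel (replicate)
    densities.  Error bars follow the convention of standard deviation over
    the mean.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 records")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    F, P = stats.f_oneway(*arrays)
    summary = pd.DataFrame({
        "group": list(groups),
        "n": [len(a) for a in arrays],
        "mean": [a.mean() for a in arrays],
        "sd": [a.std(ddof=1) for a in arrays],
    })
    return {"summary": summary, "F": float(F), "P": float(P)}
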