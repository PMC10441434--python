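"""Surface-marker fingerprints of nanoparticle populations.

A fingerprint is the vector of steady-state captured-particle densities
across capture-antibody channels, normalized to the mean of the isotype
control (IgG1) over replicates.  Markers are called positive when their
normalized mean exceeds 1 by more than ``k_sd`` pooled control relative
standard deviations.  Only signal-class localizations (|contrast| above
the background cutoff) enter the densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MARKER_ORDER = ["IgG1", "CD9", "CD63", "CD81", "CD326", "HE4", "CA125"]

__all__ = ["Fingerprint", "build_fingerprint", "call_positive_markers",
           "contrast_density_correlation", "MARKER_ORDER"]


@dataclass
class Fingerprint:
    """Per-cell-line marker panel with replicate dispersion."""

    cell_line: str
    markers: list[str]
    raw_mean: np.ndarray  # counts per 100 um^2, replicate mean per marker
    raw_sd: np.ndarray
    normalized: np.ndarray  # raw_mean / grand control mean
    normalized_sd: np.ndarray
    control_label: str
    control_mean: float
    control_rel_sd: float
    n_replicates: dict[str, int] = field(default_factory=dict)
    positive: dict[str, bool] | None = None
    low_confidence: bool = False

    def to_table(self) -> pd.DataFrame:
        t = pd.DataFrame({
            "marker": self.markers,
            "raw_mean": self.raw_mean,
            "raw_sd": self.raw_sd,
            "normalized": self.normalized,
            "normalized_sd": self.normalized_sd,
        })
        if self.positive is not None:
            t["positive"] = [self.positive[m] for m in self.markers]
        return t


def build_fingerprint(replicate_densities: list[dict[str, float]],
                      cell_line: str = "", control_label: str = "IgG1",
                      marker_order: list[str] | None = None) -> Fingerprint:
    """Normalize per-channel steady densities to the control's grand mean.

    ``replicate_densities`` holds one marker->density mapping per replicate;
    the control must be present in every replicate.  Normalization divides
    every marker by the control mean across replicates (so the control
    normalizes to 1 by construction).
    """
    if not replicate_densities:
        raise ValueError("no replicates provided")
    for k, rep in enumerate(replicate_densities):
        if control_label not in rep:
            raise ValueError(f"replicate {k} lacks the control channel {control_label!r}")
    markers = marker_order or [m for m in MARKER_ORDER
                               if any(m in rep for rep in replicate_densities)]
    extra = sorted({m for rep in replicate_densities for m in rep} - set(markers))
    markers = list(markers) + extra
    ctrl_vals = np.array([rep[control_label] for rep in replicate_densities], float)
    ctrl_mean = float(ctrl_vals.mean())
    if ctrl_mean <= 0:
        raise ValueError("control mean density is zero; cannot normalize")
    ctrl_rel_sd = float(ctrl_vals.std(ddof=1) / ctrl_mean) if len(ctrl_vals) > 1 else 0.0
    raw_mean, raw_sd, n_reps = [], [], {}
    for m in markers:
        vals = np.array([rep[m] for rep in replicate_densities if m in rep], float)
        if np.any(vals < 0):
            raise ValueError(f"negative density for marker {m!r}")
        raw_mean.append(vals.mean())
        raw_sd.append(vals.std(ddof=1) if len(vals) > 1 else 0.0)
        n_reps[m] = len(vals)
    raw_mean = np.array(raw_mean)
    raw_sd = np.array(raw_sd)
    return Fingerprint(cell_line, markers, raw_mean, raw_sd,
                       raw_mean / ctrl_mean, raw_sd / ctrl_mean,
                       control_label, ctrl_mean, ctrl_rel_sd, n_reps,
                       low_confidence=len(replicate_densities) < 2)


def call_positive_markers(fp: Fingerprint, k_sd: float = 2.0) -> dict[str, bool]:
    """Positive iff mean normalized density > 1 + k_sd x control relative SD.

    With a single replicate the calls are still emitted but the fingerprint
    is flagged low-confidence.
    """
    thresh = 1.0 + k_sd * fp.control_rel_sd
    calls = {}
    for m, v in zip(fp.markers, fp.normalized):
        calls[m] = bool(v > thresh) and m != fp.control_label
    fp.positive = calls
    return calls


def contrast_density_correlation(median_contrasts: dict[str, float],
                                 densities: dict[str, float]) -> dict:
    """Spearman correlation of per-marker median |contrast| vs capture density.

    A positive correlation links larger particles (higher contrast) with
    higher binding densities.  Degenerate inputs (all medians identical)
    are flagged rather than reported as a number.
    """
    common = [m for m in median_contrasts if m in densities]
    if len(common) < 3:
        raise ValueError("need at least 3 markers")
    c = np.array([median_contrasts[m] for m in common], float)
    d = np.array([densities[m] for m in common], float)
    pairs = pd.DataFrame({"marker": common, "median_contrast": c, "density": d})
    if np.ptp(c) == 0 or np.ptp(d) == 0:
        return {"rho": float("nan"), "p": float("nan"), "degenerate": True, "pairs": pairs}
    res = stats.spearmanr(c, d)
    return {"rho": float(res.statistic), "p": float(res.pvalue),
            "degenerate": False, "pairs": pairs}
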