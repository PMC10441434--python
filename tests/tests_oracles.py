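"""Brute-force reference implementations used as independent oracles.

Deliberately literal (double loops, no vectorized neighbourhood tricks) so
they can be checked by eye against the processing rules they mirror.
"""

import numpy as np


def brute_local_noise(residual, sigma_global, params):
    """Clipped RMS over border-clipped square windows, pixel by pixel."""
    h, w = residual.shape
    r = params.local_kernel // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = residual[max(i - r, 0):i + r + 1, max(j - r, 0):j + r + 1]
            keep = win[np.abs(win) <= params.clip_factor * sigma_global]
            out[i, j] = np.sqrt((keep**2).mean()) if keep.size else 0.0
    return np.maximum(out, params.noise_floor_factor * sigma_global)


def brute_detect(residual, noise_map, params):
    """Two selection criteria applied pixel by pixel.

    A pixel is selected iff its SNR is above threshold and its
    cluster-window neighbourhood (clipped at borders, itself included)
    holds at least ``min_cluster_pixels`` above-threshold pixels.
    """
    h, w = residual.shape
    snr = np.abs(residual) / noise_map
    seeds = snr >= params.snr_threshold
    r = params.cluster_window // 2
    out = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            if not seeds[i, j]:
                continue
            cnt = 0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and seeds[ii, jj]:
                        cnt += 1
            out[i, j] = cnt >= params.min_cluster_pixels
    return out
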