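"""Noise estimation, two-criterion detection, radial-symmetry localization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iscatflow.config import DetectionParams
from iscatflow.localize import (NoiseModel, detect_candidates, global_noise,
                                local_noise_map, localize_frame, localize_scan,
                                measure_contrast, radial_symmetry_center)


def _gauss_spot(n, amp, sigma, cx=0.0, cy=0.0):
    y, x = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2
    return amp * np.exp(-((x - c - cx) ** 2 + (y - c - cy) ** 2) / (2 * sigma**2))


# ------------------------------------------------------------------- global noise

class TestGlobalNoise:
    def test_hand_computed_mad(self):
        # values {1..5}: median 3, MAD 1, sigma = 1.4826
        frame = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 3.0], [3.0, 3.0, 3.0]])
        v = frame.ravel()
        med = np.median(v)
        assert med == 3.0 and np.median(np.abs(v - med)) == 0.0  # guard: adjust frame
        frame = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        assert global_noise(frame) == pytest.approx(1.4826)

    def test_gaussian_consistency_on_large_frame(self):
        v = np.random.default_rng(0).normal(0, 1, (1024, 1024))
        assert 0.99 <= global_noise(v) <= 1.01

    def test_robust_to_bright_outliers(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, (512, 512))
        k = int(0.01 * v.size)
        idx = rng.choice(v.size, k, replace=False)
        v.ravel()[idx] = 100.0
        assert 0.99 <= global_noise(v) <= 1.05
        assert v.std() > 5  # the plain SD fails here

    def test_constant_frame_rejected(self):
        with pytest.raises(ValueError):
            global_noise(np.ones((8, 8)))


# ------------------------------------------------------------------- local noise

def _brute_local_noise(residual, sigma_global, params):
    """Literal reimplementation: clipped RMS over clipped windows."""
    h, w = residual.shape
    r = params.local_kernel // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = residual[max(i - r, 0):i + r + 1, max(j - r, 0):j + r + 1]
            keep = win[np.abs(win) <= params.clip_factor * sigma_global]
            out[i, j] = np.sqrt((keep**2).mean()) if keep.size else 0.0
    return np.maximum(out, params.noise_floor_factor * sigma_global)


CLIPPED_RMS = np.sqrt(1 - 2 * 2.5 * stats.norm.pdf(2.5)
                      / (2 * stats.norm.cdf(2.5) - 1))  # ~0.9546 sigma


class TestLocalNoise:
    def test_homogeneous_noise_matches_clipped_gaussian_rms(self):
        sigma = 1e-3
        v = np.random.default_rng(2).normal(0, sigma, (256, 256))
        m, _ = local_noise_map(v, global_noise(v))
        assert np.median(m) == pytest.approx(CLIPPED_RMS * sigma, rel=0.05)

    def test_two_plateau_frame_transitions_between_levels(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(0, 1e-3, (256, 128)),
                            rng.normal(0, 2e-3, (256, 128))], axis=1)
        sg = global_noise(v)
        m, _ = local_noise_map(v, sg)

        def clipped_rms(sigma, clip):
            a = clip / sigma
            frac = 1 - 2 * a * stats.norm.pdf(a) / (2 * stats.norm.cdf(a) - 1)
            return sigma * np.sqrt(frac)

        clip = 2.5 * sg
        assert m[:, :60].mean() == pytest.approx(clipped_rms(1e-3, clip), rel=0.05)
        assert m[:, -60:].mean() == pytest.approx(clipped_rms(2e-3, clip), rel=0.05)

    def test_bright_spot_excluded_by_clip(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 1e-3, (128, 128))
        ref, _ = local_noise_map(v, 1e-3)
        v_spot = v + _gauss_spot(128, 0.05, 1.5)
        m, _ = local_noise_map(v_spot, 1e-3)
        assert m[63, 63] == pytest.approx(ref[63, 63], rel=0.02)

    def test_matches_brute_force_oracle_exactly(self):
        params = DetectionParams(local_kernel=15)
        rng = np.random.default_rng(5)
        for _ in range(5):
            v = rng.normal(0, 1e-3, (48, 48))
            v[rng.integers(0, 48, 5), rng.integers(0, 48, 5)] += 0.02
            sg = global_noise(v)
            fast, _ = local_noise_map(v, sg, params)
            brute = _brute_local_noise(v, sg, params)
            assert np.allclose(fast, brute, rtol=1e-10, atol=1e-15)

    def test_floor_applied_and_flagged(self):
        v = np.zeros((64, 64))
        v[32, 32] = 1.0  # single huge value, clipped everywhere
        m, floored = local_noise_map(v, 1e-3)
        assert np.all(m >= 0.25e-3)
        assert floored.all()


# --------------------------------------------------------------------- detection

def _brute_detect(residual, noise_map, params):
    """Literal double-loop reimplementation of the two selection criteria."""
    h, w = residual.shape
    snr = np.abs(residual) / noise_map
    seeds = snr >= params.snr_threshold
    r = params.cluster_window // 2
    clustered = np.zeros((h, w), bool)
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
            clustered[i, j] = cnt >= params.min_cluster_pixels
    return clustered


class TestDetectCandidates:
    def test_pixelwise_equivalence_with_brute_force_oracle(self):
        """The vectorized detector selects exactly the oracle's pixels."""
        from scipy import ndimage
        params = DetectionParams()
        rng = np.random.default_rng(0)
        for _ in range(100):
            v = rng.normal(0, 1e-3, (64, 64))
            nspots = rng.integers(0, 4)
            for _ in range(nspots):
                cx, cy = rng.uniform(-20, 20, 2)
                v += _gauss_spot(64, rng.uniform(0.003, 0.02), 1.0, cx, cy)
            nm = np.full((64, 64), 1e-3)
            brute = _brute_detect(v, nm, params)
            snr = np.abs(v) / nm
            seeds = snr >= params.snr_threshold
            neigh = ndimage.uniform_filter(seeds.astype(float), 3,
                                           mode="constant") * 9
            fast = seeds & (np.rint(neigh) >= 3)
            assert np.array_equal(fast, brute)
            # ROI count equals the number of 8-connected components
            rois = detect_candidates(v, nm, params)
            n_comp = ndimage.label(brute, structure=np.ones((3, 3)))[1]
            assert len(rois) == n_comp

    def test_bright_spot_yields_exactly_one_roi(self):
        v = _gauss_spot(64, 10e-3, 1.0)
        rois = detect_candidates(v, np.full((64, 64), 1e-3), DetectionParams())
        assert len(rois) == 1
        assert rois[0].cluster_size >= 3
        assert (rois[0].row, rois[0].col) == (31, 31) or \
               (rois[0].row, rois[0].col) == (32, 32)

    def test_single_pixel_impulse_rejected_by_cluster_rule(self):
        v = np.zeros((64, 64))
        v[30, 30] = 0.1  # 100x noise but no neighbours above threshold
        rois = detect_candidates(v, np.full((64, 64), 1e-3), DetectionParams())
        assert rois == []

    def test_detection_count_weakly_decreases_with_threshold(self):
        rng = np.random.default_rng(7)
        v = rng.normal(0, 1e-3, (128, 128))
        for _ in range(8):
            cx, cy = rng.uniform(-50, 50, 2)
            v += _gauss_spot(128, rng.uniform(0.004, 0.02), 1.0, cx, cy)
        nm = np.full((128, 128), 1e-3)
        counts = [len(detect_candidates(v, nm, DetectionParams(snr_threshold=t)))
                  for t in (3.0, 4.0, 5.0, 8.0, 12.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# ----------------------------------------------------------- radial symmetry centre

class TestRadialSymmetryCenter:
    def test_centred_gaussian_returns_origin(self):
        dx, dy = radial_symmetry_center(_gauss_spot(11, 1.0, 1.2))
        assert abs(dx) < 1e-6 and abs(dy) < 1e-6

    @pytest.mark.parametrize("off", [(0.30, -0.20), (-0.45, 0.10), (0.25, 0.25)])
    def test_subpixel_offset_recovered(self, off):
        dx, dy = radial_symmetry_center(_gauss_spot(11, 1.0, 1.0, off[0], off[1]))
        assert dx == pytest.approx(off[0], abs=0.02)
        assert dy == pytest.approx(off[1], abs=0.02)

    def test_centroid_oracle_is_biased_but_rsc_is_not(self):
        # cross-check: on a truncated ROI the intensity centroid is worse
        off = (0.40, 0.0)
        roi = _gauss_spot(9, 1.0, 1.5, *off)
        y, x = np.mgrid[0:9, 0:9].astype(float) - 4.0
        centroid_dx = (roi * x).sum() / roi.sum()
        dx, _ = radial_symmetry_center(roi)
        assert abs(dx - off[0]) < abs(centroid_dx - off[0])

    def test_dark_spot_localizes_like_bright(self):
        bright = _gauss_spot(11, 1.0, 1.0, 0.3, -0.2)
        bx, by = radial_symmetry_center(bright)
        dx, dy = radial_symmetry_center(-bright)
        assert abs(bx - dx) < 1e-3 and abs(by - dy) < 1e-3

    def test_degenerate_rois_rejected(self):
        with pytest.raises(ValueError):
            radial_symmetry_center(np.ones((7, 7)))
        with pytest.raises(ValueError):
            radial_symmetry_center(np.arange(49, dtype=float).reshape(7, 7))
        with pytest.raises(ValueError):
            radial_symmetry_center(np.ones((3, 3)))


# --------------------------------------------------------------- contrast measurement

class TestMeasureContrast:
    def test_on_pixel_spot_reads_exact_contrast(self):
        v = _gauss_spot(33, 0.010, 1.0)
        c, integ, edge = measure_contrast(v, (16.0, 16.0))
        assert c == pytest.approx(0.0100, abs=2e-4)
        assert not edge

    def test_integrated_contrast_matches_gaussian_integral(self):
        sigma = 1.0
        v = _gauss_spot(33, 0.010, sigma)
        _, integ, _ = measure_contrast(v, (16.0, 16.0),
                                       DetectionParams(roi_halfwidth=5))
        assert integ == pytest.approx(0.010 * 2 * np.pi * sigma**2, rel=0.03)

    def test_edge_proximity_flagged(self):
        v = _gauss_spot(33, 0.010, 1.0)
        _, _, edge = measure_contrast(v, (2.0, 16.0))
        assert edge

    def test_subpixel_spot_unbiased(self):
        for off in [(0.3, -0.4), (0.5, 0.5), (-0.2, 0.1)]:
            v = _gauss_spot(33, 0.010, 1.0, *off)
            c, _, _ = measure_contrast(v, (16 + off[0], 16 + off[1]))
            assert c == pytest.approx(0.0100, abs=2e-4)


# ----------------------------------------------------------------- frame-level chain

class TestLocalizeFrame:
    def test_precision_scales_inversely_with_snr(self):
        """RMS localization error vs 1/SNR is linear with R^2 > 0.9."""
        rng = np.random.default_rng(11)
        snrs = [5, 8, 12, 20, 35, 50]
        rms = []
        sigma_n = 1e-3
        for snr in snrs:
            errs = []
            for k in range(85):
                off = rng.uniform(-0.5, 0.5, 2)
                v = (_gauss_spot(21, snr * sigma_n, 1.0, off[0], off[1])
                     + rng.normal(0, sigma_n, (21, 21)))
                nm = NoiseModel(sigma_n, np.full((21, 21), sigma_n))
                locs = localize_frame(v, noise=nm)
                if len(locs) != 1:
                    continue
                errs.append((locs.x_px[0] - (10 + off[0])) ** 2
                            + (locs.y_px[0] - (10 + off[1])) ** 2)
            rms.append(np.sqrt(np.mean(errs)))
        res = stats.linregress(1.0 / np.asarray(snrs, float), rms)
        assert res.rvalue**2 > 0.9

    def test_contrast_linearity_over_two_decades(self):
        """Measured vs true contrast: slope 1.00 +- 0.03, |intercept| < 2e-4."""
        rng = np.random.default_rng(12)
        true_c, meas_c = [], []
        sigma_n = 2e-4
        for c in np.geomspace(2e-3, 5e-2, 12):
            for _ in range(6):
                off = rng.uniform(-0.5, 0.5, 2)
                v = (_gauss_spot(21, c, 1.0, off[0], off[1])
                     + rng.normal(0, sigma_n, (21, 21)))
                nm = NoiseModel(sigma_n, np.full((21, 21), sigma_n))
                locs = localize_frame(v, noise=nm)
                if len(locs) != 1:
                    continue
                true_c.append(c)
                meas_c.append(locs.contrast[0])
        res = stats.linregress(true_c, meas_c)
        assert res.slope == pytest.approx(1.0, abs=0.03)
        assert abs(res.intercept) < 2e-4

    def test_empty_frame_gives_empty_table_with_schema(self):
        rng = np.random.default_rng(13)
        v = rng.normal(0, 1e-3, (64, 64))
        nm = NoiseModel(1e-3, np.full((64, 64), 1e-3))
        locs = localize_frame(v, noise=nm)
        from iscatflow.localize import LOCALIZATION_COLUMNS
        assert list(locs.columns) == LOCALIZATION_COLUMNS

    def test_tiles_and_single_frame_localizations_match(self):
        """One big frame vs overlapping tiles: >= 99% of spots match within 1 px."""
        rng = np.random.default_rng(14)
        big = rng.normal(0, 1e-3, (256, 384))
        xs = rng.uniform(12, 372, 40)
        ys = rng.uniform(12, 244, 40)
        for x, y in zip(xs, ys):
            yy, xx = np.mgrid[0:256, 0:384].astype(float)
            big += 0.012 * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / 2.0)
        nm_big = NoiseModel(1e-3, np.full(big.shape, 1e-3))
        whole = localize_frame(big, noise=nm_big)
        # four 256x256 tiles with 128 px horizontal overlap
        origins = np.array([[0, 0], [128, 0]], dtype=float)
        tiles = [big[:, 0:256], big[:, 128:384]]
        tiled = localize_scan(tiles, origins)
        from iscatflow.scenarios import match_localizations
        matched, n_det, n_truth = match_localizations(
            tiled, whole[["x_px", "y_px"]].to_numpy(), radius_px=1.0)
        assert matched >= 0.99 * max(n_det, n_truth)
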