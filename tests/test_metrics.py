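"""Calcium-transient metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy import stats

from lfcalcium.metrics import (
    depth_center_of_mass,
    signal_std_map,
    DegenerateBaseline,
    ROI,
    activation_map,
    compare_paired,
    dff,
    depth_profile,
    extract_roi,
    fwhm_linear,
    roi_contour,
    roi_timecourse,
    spatial_profile,
    transient_metrics,
)


class TestDff:
    def test_direct_arithmetic(self):
        f = np.array([105.0, 105.0, 110.0])
        ts = dff(f, slice(0, 2), fd=5.0)
        assert ts.f0 == 105.0
        assert ts.dff_pct[2] == pytest.approx(5.0)  # (110-105)/(105-5) = 5%

    def test_constant_trace_is_zero(self):
        ts = dff(np.full(50, 80.0), slice(0, 20), fd=10.0)
        assert np.allclose(ts.dff_pct, 0.0)

    def test_zero_dark_reduces_to_classical(self, rng):
        f = rng.random(100) + 2.0
        ts = dff(f, slice(0, 20), fd=0.0)
        f0 = f[:20].mean()
        assert np.allclose(ts.dff_pct, (f - f0) / f0 * 100)

    def test_degenerate_baseline_raises(self):
        with pytest.raises(DegenerateBaseline):
            dff(np.full(10, 5.0), slice(0, 3), fd=5.0)


class TestActivationMap:
    def test_constant_series_zero_map(self):
        series = np.full((30, 8, 8), 50.0)
        res = activation_map(series, slice(0, 10), fd=0.0)
        assert np.allclose(res.map, 0.0)

    def test_single_flickering_pixel(self, rng):
        series = np.full((40, 6, 6), 100.0)
        series[:, 2, 3] += rng.normal(0, 5, 40)
        res = activation_map(series, slice(0, 10), fd=0.0)
        nz = res.map > 1e-12
        assert nz[2, 3] and nz.sum() == 1

    def test_matches_two_pass_variance_oracle(self, rng):
        series = rng.random((25, 5, 7)) * 50 + 100
        fd = 10.0
        res = activation_map(series, slice(0, 5), fd)
        for i in range(5):
            for j in range(7):
                f = series[:, i, j]
                f0 = f[:5].mean()
                rel = (f - f0) / (f0 - fd) * 100
                mean = rel.sum() / rel.size
                var = ((rel - mean) ** 2).sum() / rel.size
                assert res.map[i, j] == pytest.approx(var, rel=1e-10)

    def test_invariant_to_static_spatial_pattern(self, rng):
        series = rng.random((30, 6, 6)) * 10 + 100
        static = rng.random((6, 6)) * 0  # additive constant-in-time pattern
        shifted = series + static[None]
        a = activation_map(series, slice(0, 10), 0.0)
        b = activation_map(shifted, slice(0, 10), 0.0)
        assert np.allclose(a.map, b.map)


class TestRoi:
    def test_top_two_of_hundred_distinct(self, rng):
        amap = rng.permutation(100).astype(float).reshape(10, 10)
        roi = extract_roi(amap, 98.0)
        assert roi.size == 2
        assert set(amap[roi.mask]) == {98.0, 99.0}

    def test_rank_invariance_under_constant_offset(self, rng):
        amap = rng.random((12, 12))
        a = extract_roi(amap, 98.0)
        b = extract_roi(amap + 7.5, 98.0)
        assert np.array_equal(a.mask, b.mask)

    def test_matches_sort_and_slice_oracle_with_ties(self, rng):
        for _ in range(100):
            amap = rng.integers(0, 20, size=(8, 8)).astype(float)
            if np.ptp(amap) == 0:
                continue
            roi = extract_roi(amap, 98.0)
            thr = np.percentile(amap, 98.0)  # linear-interpolation percentile
            oracle = amap >= thr
            assert np.array_equal(roi.mask, oracle)
            assert roi.mask[np.unravel_index(np.argmax(amap), amap.shape)]

    def test_degenerate_map_rejected(self):
        with pytest.raises(ValueError):
            extract_roi(np.ones((5, 5)))

    def test_contour_of_single_pixel_is_ring(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        ring = roi_contour(ROI(mask, 98.0))
        assert ring.sum() == 8
        assert not ring[3, 3]

    def test_contour_disjoint_from_mask(self, rng):
        for _ in range(100):
            mask = rng.random((10, 10)) > 0.7
            if not mask.any():
                continue
            outline = roi_contour(mask)
            assert not np.any(outline & mask)

    def test_rectangle_contour_is_frame(self):
        mask = np.zeros((10, 10), bool)
        mask[3:6, 2:7] = True
        from scipy import ndimage

        oracle = ndimage.binary_dilation(
            mask, structure=np.ones((3, 3), bool)
        ) ^ mask
        assert np.array_equal(roi_contour(mask), oracle)
        assert roi_contour(mask).sum() == (5 * 7 - 15)


class TestTransientMetrics:
    def test_tsnr_estimator_calibration(self, rng):
        """Monte-Carlo: peak 10%, baseline sigma 0.5% -> tSNR near 20."""
        estimates = []
        within_band = 0
        for _ in range(500):
            base = rng.normal(0, 0.5, 20)
            trace = np.concatenate([base, [10.0], np.zeros(9)])
            f = 100.0 + trace  # counts with F0-Fd ~ 100 -> dff % ~ trace
            ts = dff(f, slice(0, 20), fd=0.0)
            m = transient_metrics(ts, stim_onset_s=1.0)
            estimates.append(m.tsnr)
            within_band += 20 / 1.4 < m.tsnr < 20 * 1.4
        # a 20-sample std is a noisy estimator: nearly all, not all, repeats
        # land within +/-40%, and the ensemble mean is unbiased within 5%
        assert within_band >= 0.95 * 500
        assert np.mean(estimates) == pytest.approx(20.0, rel=0.05)

    def test_exponential_decay_fwhm(self):
        tau = 0.332
        dt = 0.05
        t = np.arange(200) * dt
        trace = np.zeros(200)
        on = t >= 1.0
        trace[on] = 10.0 * np.exp(-(t[on] - 1.0) / tau)
        trace[:20] += 1e-6 * (-1.0) ** np.arange(20)  # nonzero baseline variance
        f = 100.0 * (1 + trace / 100.0)
        ts = dff(f, slice(0, 20), fd=0.0)
        m = transient_metrics(ts, stim_onset_s=1.0)
        assert m.decay_s == pytest.approx(tau * np.log(2), abs=dt)

    def test_scale_invariance_of_tsnr(self, rng):
        base = rng.normal(0, 0.5, 20)
        base -= base.mean()  # keep F0 identical under trace scaling
        trace = np.concatenate([base, 10.0 + rng.random(20)])
        f1 = 100.0 + trace
        f2 = 100.0 + 2 * trace
        m1 = transient_metrics(dff(f1, slice(0, 20), 0.0), 1.0)
        m2 = transient_metrics(dff(f2, slice(0, 20), 0.0), 1.0)
        assert m2.peak_pct == pytest.approx(2 * m1.peak_pct)
        assert m2.noise_pct == pytest.approx(2 * m1.noise_pct)
        assert m2.tsnr == pytest.approx(m1.tsnr)

    def test_zero_baseline_variance_rejected(self):
        f = np.concatenate([np.full(20, 100.0), [150.0]])
        ts = dff(f, slice(0, 20), fd=0.0)
        with pytest.raises(ZeroDivisionError):
            transient_metrics(ts, 1.0)


class TestRoiTimecourse:
    def test_single_voxel_mask(self, rng):
        series = rng.random((30, 5, 5)) * 10 + 100
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        ts = roi_timecourse(series, mask, slice(0, 10), fd=0.0)
        direct = dff(series[:, 2, 2], slice(0, 10), fd=0.0)
        assert np.allclose(ts.dff_pct, direct.dff_pct)

    def test_matches_loop_mean_oracle(self, rng):
        series = rng.random((20, 6, 6)) * 10 + 100
        mask = rng.random((6, 6)) > 0.5
        mask[0, 0] = True
        ts = roi_timecourse(series, mask, slice(0, 5), fd=2.0)
        f = np.array([series[t][mask].mean() for t in range(20)])
        assert np.allclose(ts.f, f)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            roi_timecourse(np.ones((10, 4, 4)), np.zeros((4, 4), bool), slice(0, 3), 0.0)


class TestFwhm:
    def test_gaussian_closed_form(self):
        sigma = 3.0
        x = np.arange(-20, 21, 1.0)
        prof = np.exp(-(x**2) / (2 * sigma**2))
        w, limited = fwhm_linear(prof, spacing=1.0)
        assert not limited
        assert w == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, abs=0.5)

    def test_refining_pitch_converges(self):
        sigma = 3.0
        for spacing in (1.0, 0.5):
            x = np.arange(-20, 20 + spacing / 2, spacing)
            w, _ = fwhm_linear(np.exp(-(x**2) / (2 * sigma**2)), spacing)
            assert abs(w - 7.0644) < spacing / 2 + 0.05

    def test_delta_profile_one_sample_wide(self):
        prof = np.zeros(11)
        prof[5] = 1.0
        w, limited = fwhm_linear(prof, spacing=2.0)
        assert not limited
        assert w == pytest.approx(2.0)

    def test_field_limited_flagged(self):
        prof = np.linspace(0.9, 1.0, 10)  # never falls below half max
        w, limited = fwhm_linear(prof, 1.0)
        assert limited

    def test_bead_profile_matches_convolution_oracle(self):
        """10-um bead blurred by a Gaussian: FWHM equals the numeric oracle."""
        dx = 0.25
        x = np.arange(-30, 30 + dx / 2, dx)
        bead = (np.abs(x) <= 5.0).astype(float)
        sig = 2.0
        kern = np.exp(-(x**2) / (2 * sig**2))
        prof = np.convolve(bead, kern, mode="same")
        w, _ = fwhm_linear(prof, dx)
        # oracle: dense evaluation of the analytic convolution (erf form)
        from scipy.special import erf

        dense = np.arange(-30, 30, 0.001)
        analytic = erf((dense + 5) / (np.sqrt(2) * sig)) - erf((dense - 5) / (np.sqrt(2) * sig))
        half = analytic.max() / 2
        above = dense[analytic >= half]
        assert w >= 10.0  # convolution cannot shrink the bead
        assert w == pytest.approx(above[-1] - above[0], abs=2 * dx)

    def test_spatial_profile_axes_and_mip(self, rng):
        vol = np.zeros((9, 7, 7))
        vol[4, 3, 3] = 1.0
        vol[5, 3, 3] = 0.6
        prof, w, limited = spatial_profile(vol, "z", through=(4, 3, 3), pitch_um=1.0)
        assert prof.size == 9 and prof[4] == 1.0
        mip_prof, _, _ = spatial_profile(vol, "z", pitch_um=1.0)
        assert np.array_equal(mip_prof, vol.max(axis=(1, 2)))


class TestDepthProfile:
    def test_single_depth_source_peaks_there(self):
        series = np.full((40, 9, 5, 5), 100.0)
        t = np.arange(40)
        series[:, 6, 2, 2] += np.where(t >= 20, 30.0, 0.0)
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        z = np.arange(9) - 4.0
        dtmap, curve, com = depth_profile(series, mask, slice(0, 10), 0.0, z)
        assert np.argmax(curve) == 6
        assert np.allclose(dtmap.sum(axis=1), curve)
        assert com == pytest.approx(2.0, abs=0.5)


class TestDepthLocalization:
    def test_signal_std_subtracts_noise_floor(self, rng):
        """Pure-noise voxels read ~0; a signal voxel reads its signal std."""
        n_t = 400
        series = 1000.0 + rng.normal(0, 10.0, (n_t, 6, 6))
        sig = np.zeros(n_t)
        sig[100:] = 50.0 * np.sin(np.linspace(0, 12 * np.pi, n_t - 100))
        series[:, 2, 2] += sig
        res = signal_std_map(series, slice(0, 100), fd=0.0)
        raw = activation_map(series, slice(0, 100), fd=0.0)
        # the raw variance map has a ~1% noise floor everywhere; the corrected
        # map suppresses it while keeping the signal voxel prominent
        assert np.median(res.map) < 0.2 * np.median(np.sqrt(raw.map))
        assert res.map[2, 2] > 5 * np.median(res.map)
        expected = sig.std() / 1000.0 * 100
        assert res.map[2, 2] == pytest.approx(expected, rel=0.25)

    def test_iterative_com_recovers_truncated_peak(self):
        """Symmetric-window centroiding undoes one-sided window truncation."""
        z = np.arange(-20.0, 21.0)
        prof = np.exp(-((z - 6.0) ** 2) / (2 * 8.0**2))  # broad peak at +6
        plain = (prof * z).sum() / prof.sum()
        robust = depth_center_of_mass(prof, z, window_um=12.0)
        assert abs(robust - 6.0) < abs(plain - 6.0)
        assert robust == pytest.approx(6.0, abs=0.3)

    def test_com_with_uniform_floor(self):
        z = np.arange(-20.0, 21.0)
        prof = 0.5 + np.exp(-((z + 5.0) ** 2) / (2 * 4.0**2))
        assert depth_center_of_mass(prof, z) == pytest.approx(-5.0, abs=0.5)

    def test_empty_profile_is_nan(self):
        z = np.arange(-5.0, 6.0)
        assert np.isnan(depth_center_of_mass(np.zeros(11), z))


class TestPairedStats:
    def test_identical_pairs_null_extreme(self):
        a = [1.0, 2.0, 3.0, 4.0]
        out = compare_paired(a, a, test="wilcoxon")
        assert out["p_value"] == 1.0

    def test_all_positive_differences_exact_p(self):
        """n=9, every difference positive: one-sided exact p = 1/2**9."""
        a = np.arange(1.0, 10.0) + 1.0
        b = np.arange(1.0, 10.0)
        res = stats.wilcoxon(a, b, alternative="greater", method="exact")
        assert res.pvalue == pytest.approx(1.0 / 2**9)
        out = compare_paired(a, b, test="wilcoxon")  # two-sided in the wrapper
        assert out["p_value"] == pytest.approx(2.0 / 2**9)

    def test_wilcoxon_exact_matches_enumeration(self, rng):
        """Exact one-sided p equals full enumeration of sign patterns, n <= 10."""
        for n in (5, 8, 10):
            for _ in range(10):
                a = rng.normal(0, 1, n)
                b = rng.normal(0.3, 1, n)
                d = a - b
                if np.any(d == 0) or len(set(np.abs(d))) < n:
                    continue
                ranks = stats.rankdata(np.abs(d))
                w_obs = ranks[d > 0].sum()
                total = 0
                count = 0
                for bits in range(2**n):
                    signs = [(bits >> i) & 1 for i in range(n)]
                    w = sum(r for r, s in zip(ranks, signs) if s)
                    total += 1
                    if w >= w_obs:
                        count += 1
                p_enum = count / total
                res = stats.wilcoxon(a, b, alternative="greater", method="exact")
                assert res.pvalue == pytest.approx(p_enum, rel=1e-10)

    def test_friedman_identical_conditions(self):
        a = [1.0, 2.0, 3.0]
        out = compare_paired(a, a, a, test="friedman")
        assert out["statistic"] == 0.0
        assert out["p_value"] == 1.0

    def test_friedman_through_scipy(self, rng):
        a, b, c = rng.random(8), rng.random(8) + 1, rng.random(8) + 2
        out = compare_paired(a, b, c, test="friedman")
        ref = stats.friedmanchisquare(a, b, c)
        assert out["statistic"] == pytest.approx(ref.statistic)

    def test_summaries_median_iqr(self):
        a = [1.0, 2.0, 3.0, 4.0, 100.0]
        out = compare_paired(a, list(reversed(a)), test="wilcoxon")
        assert out["summaries"][0]["median"] == 3.0
        assert out["summaries"][0]["iqr"] == [2.0, 4.0]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1.0, 2.0, 3.0], [1.0, 2.0], test="wilcoxon")
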