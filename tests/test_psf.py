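"""Wave-optics PSF patterns and the forward/adjoint projection operators."""

import numpy as np
import pytest

from lfcalcium.lfio import LightField, aperture_mask
from lfcalcium.phantoms import SYNTH_CONFIG
from lfcalcium.psf import (
    LFPSF,
    adjoint_project,
    build_psf,
    dipole_psf,
    forward_project,
    hamming_weights,
    load_psf,
    lowres_psf,
    save_psf,
)
from conftest import random_psf


class TestOperators:
    """Linear-operator contracts, exercised on random kernel sets."""

    @pytest.mark.parametrize("shape", [(3, 5, 4, 4, 3), (2, 5, 6, 5, 5), (4, 9, 8, 8, 7)])
    def test_adjoint_identity(self, rng, shape):
        nz, nu, nx, ny, k = shape
        kernels = rng.random((nz, nu, nu, k, k)) * aperture_mask(nu)[None, :, :, None, None]
        psf = LFPSF(kernels, np.arange(nz, dtype=float), lateral_pitch_um=1.0)
        for _ in range(20):
            x = rng.random((nz, nx, ny))
            y = LightField(rng.random((nu, nu, nx, ny)))
            lhs = float((forward_project(x, psf).data * y.data).sum())
            rhs = float((x * adjoint_project(y, psf)).sum())
            assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_impulse_response_is_shifted_kernel(self, rng):
        psf = random_psf(rng, nz=3, nu=5, k=5)
        nx = ny = 9
        vol = np.zeros((3, nx, ny))
        vol[1, 6, 3] = 1.0
        y = forward_project(vol, psf).data
        expected = np.zeros_like(y)
        o = 2  # kernel half-width
        for du in range(5):
            for dv in range(5):
                xi, yi = 6 + du - o, 3 + dv - o
                if 0 <= xi < nx and 0 <= yi < ny:
                    expected[:, :, xi, yi] = psf.kernels[1, :, :, du, dv]
        assert np.allclose(y, expected, atol=1e-12)

    def test_superposition(self, rng):
        psf = random_psf(rng)
        a = np.zeros((3, 7, 7))
        b = np.zeros((3, 7, 7))
        a[0, 2, 2] = 1.5
        b[2, 5, 1] = 0.7
        ya = forward_project(a, psf).data
        yb = forward_project(b, psf).data
        yab = forward_project(a + b, psf).data
        assert np.allclose(yab, ya + yb, atol=1e-12)

    def test_zero_maps_to_zero(self, rng):
        psf = random_psf(rng)
        assert forward_project(np.zeros((3, 6, 6)), psf).total() == 0
        zero_lf = LightField(np.zeros((5, 5, 6, 6)))
        assert np.all(adjoint_project(zero_lf, psf) == 0)

    def test_nonnegativity_preserved(self, rng):
        psf = random_psf(rng)
        x = rng.random((3, 6, 6))
        y = forward_project(x, psf)
        assert np.all(y.data >= 0)
        assert np.all(adjoint_project(y, psf) >= 0)

    def test_sensitivity_is_adjoint_of_ones(self, rng):
        psf = random_psf(rng)
        ones = LightField(np.ones((5, 5, 6, 6)))
        assert np.allclose(psf.sensitivity(6, 6), adjoint_project(ones, psf))
        assert np.all(psf.sensitivity(6, 6) > 0)

    def test_depth_mismatch_rejected(self, rng):
        psf = random_psf(rng, nz=3)
        with pytest.raises(ValueError):
            forward_project(np.ones((4, 6, 6)), psf)

    def test_angular_mismatch_rejected(self, rng):
        psf = random_psf(rng, nu=5)
        with pytest.raises(ValueError):
            adjoint_project(LightField(np.ones((7, 7, 6, 6))), psf)


class TestHammingReduction:
    def test_weights_normalized_and_peaked_centrally(self):
        w = hamming_weights()
        assert w.sum() == pytest.approx(1.0)
        assert w[2, 2] == w.max()

    def test_identical_responses_unchanged(self, rng):
        resp = rng.random((3, 3, 7, 7))
        grid = np.broadcast_to(resp, (5, 5) + resp.shape)
        assert np.allclose(lowres_psf(grid), resp)

    def test_matches_direct_weighted_sum(self, rng):
        grid = rng.random((5, 5, 3, 3, 7, 7))
        w1 = np.hamming(5)
        w2d = np.outer(w1, w1)
        w2d = w2d / w2d.sum()
        expected = np.zeros((3, 3, 7, 7))
        for i in range(5):
            for j in range(5):
                expected += w2d[i, j] * grid[i, j]
        assert np.allclose(lowres_psf(grid), expected)

    def test_incomplete_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            lowres_psf(rng.random((3, 3, 2, 2, 5, 5)))
        bad = rng.random((5, 5, 2, 2, 5, 5))
        bad[0, 0, 0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            lowres_psf(bad)


class TestWaveModel:
    """Physical behaviour of the computed light-field PSF."""

    CFG = SYNTH_CONFIG
    NU = 9
    _cache: dict = {}

    def pattern(self, z, offset=(2, 2), model="scalar"):
        key = (z, offset, model)
        if key not in self._cache:
            self._cache[key] = dipole_psf(
                z, offset, self.CFG, self.NU, model=model, support=9, supersample=3
            )
        return self._cache[key]

    def test_infocus_pattern_concentrated_and_symmetric(self):
        pat = self.pattern(0.0)
        # energy concentrated in the source lenslet
        per_lenslet = pat.sum(axis=(0, 1))
        assert per_lenslet[4, 4] > 0.5 * per_lenslet.sum()
        # 4-fold symmetry in (u, v) up to discretization
        uv = pat.sum(axis=(2, 3))
        assert np.allclose(uv, uv[::-1, :], rtol=0.05, atol=0.05 * uv.max())
        assert np.allclose(uv, uv.T, rtol=0.05, atol=0.05 * uv.max())

    def test_energy_symmetric_in_defocus_sign(self):
        e_pos = self.pattern(+6.0).sum()
        e_neg = self.pattern(-6.0).sum()
        assert e_pos == pytest.approx(e_neg, rel=0.02)

    def test_lateral_extent_grows_with_defocus(self):
        def rms_lenslets(pat):
            lat = pat.sum(axis=(0, 1))
            idx = np.arange(lat.shape[0]) - (lat.shape[0] - 1) / 2
            xx, yy = np.meshgrid(idx, idx, indexing="ij")
            return np.sqrt(((xx**2 + yy**2) * lat).sum() / lat.sum())

        widths = [rms_lenslets(self.pattern(z)) for z in (0.0, 5.0, 10.0)]
        assert widths[0] < widths[1] < widths[2]

    def test_view_shifts_follow_plenoptic_slope(self):
        """Defocus displaces view (u, v) by c*z*(u, v) lenslets."""
        from lfcalcium.optics import refocus_shift_slope

        z = 8.0
        pat = self.pattern(z, model="scalar")
        c = refocus_shift_slope(self.CFG, self.NU)
        idx = np.arange(pat.shape[2]) - (pat.shape[2] - 1) / 2
        for iu, u in [(1, -3.0), (7, 3.0)]:
            sl = pat[iu, 4]
            centroid = (sl.sum(axis=1) * idx).sum() / sl.sum()
            assert centroid == pytest.approx(c * z * u, abs=0.15)

    def test_dipole3_differs_from_scalar_but_similar_shape(self):
        a = self.pattern(4.0, model="scalar")
        b = self.pattern(4.0, model="dipole3")
        assert not np.allclose(a / a.sum(), b / b.sum())
        # same coarse footprint: normalized patterns correlate strongly
        na, nb = a.ravel() / a.sum(), b.ravel() / b.sum()
        corr = np.corrcoef(na, nb)[0, 1]
        assert corr > 0.9

    def test_off_grid_offset_rejected(self):
        with pytest.raises(ValueError):
            dipole_psf(0.0, (5, 0), self.CFG, self.NU)

    def test_bad_model_rejected(self):
        with pytest.raises(ValueError):
            dipole_psf(0.0, (2, 2), self.CFG, self.NU, model="vectorial")


class TestBuildPsf:
    def test_build_normalizes_and_masks(self, cfg, nu):
        psf = build_psf(cfg, [-4.0, 0.0, 4.0], nu, model="scalar", support=9, supersample=1)
        assert psf.kernels.shape == (3, nu, nu, 9, 9)
        assert np.allclose(psf.kernels.sum(axis=(1, 2, 3, 4)), 1.0)
        assert np.all(psf.kernels[:, ~aperture_mask(nu)] == 0)
        assert np.all(psf.kernels >= 0)

    def test_defocused_kernel_energy_balance(self, desk_psf):
        """Kernels at +/-z have equal energy (both normalized) and growing extent."""
        ks = desk_psf.kernels
        z = desk_psf.z_um

        def extent(kernel):
            lat = kernel.sum(axis=(0, 1))
            idx = np.arange(lat.shape[0]) - (lat.shape[0] - 1) / 2
            xx, yy = np.meshgrid(idx, idx, indexing="ij")
            return np.sqrt(((xx**2 + yy**2) * lat).sum() / lat.sum())

        e0 = extent(ks[int(np.argmin(np.abs(z)))])
        e10 = extent(ks[int(np.argmin(np.abs(z - 10)))])
        e20 = extent(ks[int(np.argmin(np.abs(z - 20)))])
        assert e0 < e10 < e20

    def test_save_load_round_trip(self, tmp_path, cfg, nu):
        psf = build_psf(cfg, [0.0, 4.0], nu, model="scalar", support=9, supersample=1)
        path = tmp_path / "psf.h5"
        save_psf(psf, path)
        back = load_psf(path)
        assert np.array_equal(back.kernels, psf.kernels)
        assert np.array_equal(back.z_um, psf.z_um)
        assert back.meta["model"] == "scalar"
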