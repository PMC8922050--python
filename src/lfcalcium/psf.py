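"""Wave-optics light-field PSF and linear forward/adjoint projection operators.

The 3D light-field PSF describes the pattern a unit point emitter at depth
``z`` produces on the sensor behind the microlens array.  It is computed with
scalar Fourier optics:

1. the defocused amplitude at the native image plane is the inverse Fourier
   transform of the objective pupil with the high-NA defocus phase
   ``exp(i k0 n z cos(theta_s))`` (sample-side angles, aplanatic
   ``sqrt(cos theta)`` apodization);
2. the field is multiplied by the periodic quadratic phase of the microlens
   array and Fresnel/angular-spectrum propagated one lenslet focal length to
   the sensor, where the intensity is taken;
3. emitter orientation: either a single scalar pattern (``model="scalar"``)
   or the incoherent, equally weighted sum of three patterns for dipoles
   along x, y and z, each entering through an orientation-dependent pupil
   apodization (``model="dipole3"``).

Because the response depends on where the emitter sits *within* a lenslet,
patterns are evaluated on a 5x5 grid of sub-lenslet offsets and reduced to a
single lenslet-periodic kernel by averaging with a 2D Hamming window of width
one pitch, centred on the lenslet axis.  The reduced kernel set
``H(z)[u, v, dx, dy]`` (angular sample, lenslet offset) defines a
shift-invariant-per-lenslet linear operator: forward projection is a per-depth
2D convolution over the lenslet lattice summed over depths, and the adjoint
is the matching correlation.  The per-voxel sensitivity ``a`` is the adjoint
applied to an all-ones light field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import h5py

from .lfio import LightField, aperture_mask
from .optics import LFMConfig, native_lateral_resolution

__all__ = [
    "LFPSF",
    "dipole_psf",
    "lowres_psf",
    "build_psf",
    "forward_project",
    "adjoint_project",
    "save_psf",
    "load_psf",
]

#: Sub-lenslet offset grid (fractions of one pitch) on which PSF patterns are
#: evaluated before the Hamming-window reduction.
OFFSET_GRID = 5


@dataclass
class LFPSF:
    """Per-depth light-field projection kernels with cached FFT operators.

    ``kernels`` has shape ``(nz, nu, nu, k, k)``: the light-field response of
    a unit emitter at depth ``z_um[i]`` in angular sample ``(u, v)`` at
    lenslet offset ``(dx, dy)`` from the emitter's lenslet (``k`` odd,
    centred).  Kernels are non-negative, zero outside the angular aperture,
    and normalized to unit total energy per depth.
    """

    kernels: np.ndarray
    z_um: np.ndarray
    lateral_pitch_um: float
    meta: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        self.z_um = np.atleast_1d(np.asarray(self.z_um, dtype=float))
        if self.kernels.ndim != 5 or self.kernels.shape[1] != self.kernels.shape[2]:
            raise ValueError("kernels must have shape (nz, nu, nu, k, k)")
        if self.kernels.shape[0] != self.z_um.size:
            raise ValueError("kernel depth axis does not match z grid")
        if np.any(self.kernels < 0):
            raise ValueError("kernels must be non-negative")

    @property
    def nz(self) -> int:
        return self.kernels.shape[0]

    @property
    def nu(self) -> int:
        return self.kernels.shape[1]

    @property
    def ksize(self) -> int:
        return self.kernels.shape[3]

    def _ops(self, nx: int, ny: int):
        """Cached rFFTs of the kernels for a (nx, ny) lenslet field."""
        key = (nx, ny)
        if key not in self._cache:
            k = self.ksize
            P, Q = nx + k - 1, ny + k - 1
            kf = np.fft.rfft2(self.kernels, s=(P, Q))
            self._cache[key] = (P, Q, kf)
        return self._cache[key]

    def sensitivity(self, nx: int, ny: int) -> np.ndarray:
        """Per-voxel sensitivity ``a = H^T(1)`` for an (nx, ny) lenslet field."""
        key = ("a", nx, ny)
        if key not in self._cache:
            ones = LightField(
                np.ones((self.nu, self.nu, nx, ny)), aperture_mask(self.nu)
            )
            self._cache[key] = adjoint_project(ones, self)
        return self._cache[key]


# ---------------------------------------------------------------------------
# Wave-optics pattern computation


class _WaveModel:
    """Precomputed pupil/MLA/propagation arrays for one optical configuration."""

    def __init__(
        self,
        cfg: LFMConfig,
        nu: int,
        support: int,
        supersample: int,
        wavelength_um: float,
    ):
        if support % 2 == 0:
            raise ValueError("kernel support (lenslets) must be odd")
        if supersample % 2 == 0 or supersample < 1:
            raise ValueError("supersample must be a positive odd integer")
        if nu % 2 == 0:
            raise ValueError("angular sampling nu must be odd")
        self.cfg = cfg
        self.nu = nu
        self.support = support
        self.ss = supersample
        self.lam = wavelength_um
        p = cfg.mla_pitch_um
        self.N = support * nu * supersample  # odd
        self.delta = p / (nu * supersample)  # image-plane sampling, um
        # centred spatial grid; the FFT works in unshifted layout, so phase
        # masks are stored ifftshifted and only the final intensity is shifted
        x = (np.arange(self.N) - self.N // 2) * self.delta
        self.x = x
        # frequency grids (cycles / um)
        f = np.fft.fftfreq(self.N, d=self.delta)
        self.fx = f[:, None]
        self.fy = f[None, :]
        f2 = self.fx**2 + self.fy**2
        na_img = cfg.na / cfg.magnification
        with np.errstate(invalid="ignore"):
            rho = np.sqrt(f2) * self.lam / na_img  # normalized pupil radius
        self.in_pupil = rho <= 1.0
        sin_s = np.clip(rho * cfg.na / cfg.n_immersion, 0.0, 1.0)
        self.cos_s = np.sqrt(1.0 - sin_s**2)
        self.sin_s = sin_s
        phi = np.arctan2(self.fy, self.fx)
        apod = np.where(self.in_pupil, np.sqrt(self.cos_s), 0.0)
        self.pupils = {
            "scalar": apod,
            "x": apod * np.sqrt(self.cos_s**2 * np.cos(phi) ** 2 + np.sin(phi) ** 2),
            "y": apod * np.sqrt(self.cos_s**2 * np.sin(phi) ** 2 + np.cos(phi) ** 2),
            "z": apod * sin_s,
        }
        # MLA quadratic phase, periodic in the lenslet lattice
        xl = x - p * np.round(x / p)
        f_mla = cfg.mla_focal_um
        lens1d = np.fft.ifftshift(np.exp(-1j * np.pi * xl**2 / (self.lam * f_mla)))
        self.mla = lens1d[:, None] * lens1d[None, :]
        # angular-spectrum transfer over one lenslet focal length (in air)
        arg = 1.0 / self.lam**2 - f2
        self.prop = np.where(arg > 0, np.exp(2j * np.pi * f_mla * np.sqrt(np.abs(arg))), 0.0)

    def pattern(self, z_um: float, offset_um: tuple[float, float], model: str) -> np.ndarray:
        """Sensor intensity pattern binned to (nu, nu, support, support).

        ``offset_um`` is the emitter's lateral offset from the central lenslet
        axis, expressed at the image plane.
        """
        k0n = 2.0 * np.pi * self.cfg.n_immersion / self.lam
        defocus = np.where(self.in_pupil, np.exp(1j * k0n * z_um * self.cos_s), 0.0)
        tilt = np.exp(-2j * np.pi * (self.fx * offset_um[0] + self.fy * offset_um[1]))
        orients = ["scalar"] if model == "scalar" else ["x", "y", "z"]
        spectra = np.stack([self.pupils[o] * defocus * tilt for o in orients])
        u_img = np.fft.ifft2(spectra, axes=(-2, -1))
        u_mla = u_img * self.mla
        u_sens = np.fft.ifft2(np.fft.fft2(u_mla, axes=(-2, -1)) * self.prop, axes=(-2, -1))
        intensity = np.fft.fftshift(np.abs(u_sens) ** 2, axes=(-2, -1))
        intensity = intensity.sum(axis=0)
        L, nu, ss = self.support, self.nu, self.ss
        binned = intensity.reshape(L, nu, ss, L, nu, ss).sum(axis=(2, 5))
        # (lenslet_x, u, lenslet_y, v) -> (u, v, lenslet_x, lenslet_y)
        return binned.transpose(1, 3, 0, 2)


def _offset_um(index: tuple[int, int], pitch_um: float) -> tuple[float, float]:
    i, j = index
    if not (0 <= i < OFFSET_GRID and 0 <= j < OFFSET_GRID):
        raise ValueError(f"sub-lenslet offset index {index} is off the 5x5 grid")
    half = (OFFSET_GRID - 1) // 2
    return ((i - half) / OFFSET_GRID * pitch_um, (j - half) / OFFSET_GRID * pitch_um)


def dipole_psf(
    z_um: float,
    offset: tuple[int, int],
    cfg: LFMConfig,
    nu: int,
    *,
    model: str = "dipole3",
    support: int = 15,
    supersample: int = 3,
    wavelength_um: float | None = None,
) -> np.ndarray:
    """Light-field response pattern of a point emitter at depth ``z_um``.

    ``offset`` indexes the 5x5 sub-lenslet grid.  Returns a non-negative
    array of shape ``(nu, nu, support, support)``: angular sample by lenslet
    offset from the emitter's lenslet.
    """
    if model not in ("scalar", "dipole3"):
        raise ValueError(f"unknown PSF model {model!r}")
    lam = wavelength_um if wavelength_um is not None else cfg.lambda_em_um
    wm = _WaveModel(cfg, nu, support, supersample, lam)
    return wm.pattern(z_um, _offset_um(offset, cfg.mla_pitch_um), model)


def hamming_weights(n: int = OFFSET_GRID) -> np.ndarray:
    """2D outer-product Hamming window over the sub-lenslet grid, unit sum."""
    w1 = np.hamming(n)
    w = np.outer(w1, w1)
    return w / w.sum()


def lowres_psf(patterns: np.ndarray) -> np.ndarray:
    """Reduce a fully populated 5x5 offset grid of patterns to one kernel.

    ``patterns`` has shape ``(5, 5, nu, nu, k, k)``; the result is the
    average weighted by a 2D Hamming window of width one pitch centred on the
    lenslet axis (weights normalized to unit sum).
    """
    patterns = np.asarray(patterns)
    if patterns.ndim != 6 or patterns.shape[:2] != (OFFSET_GRID, OFFSET_GRID):
        raise ValueError("expected a fully populated (5, 5, nu, nu, k, k) pattern grid")
    if not np.all(np.isfinite(patterns)):
        raise ValueError("incomplete PSF: non-finite pattern values")
    w = hamming_weights(OFFSET_GRID)
    return np.tensordot(w, patterns, axes=([0, 1], [0, 1]))


def build_psf(
    cfg: LFMConfig,
    z_um: Sequence[float],
    nu: int,
    *,
    model: str = "dipole3",
    support: int = 15,
    supersample: int = 3,
    wavelength_um: float | None = None,
    truncate: float = 1e-4,
) -> LFPSF:
    """Compute the low-resolution light-field PSF over a depth grid.

    For each depth, patterns are evaluated on the 5x5 sub-lenslet offset grid,
    Hamming-averaged into one lenslet-periodic kernel, masked to the circular
    angular aperture, truncated where values fall below ``truncate`` times the
    kernel peak, and normalized to unit total energy.
    """
    if model not in ("scalar", "dipole3"):
        raise ValueError(f"unknown PSF model {model!r}")
    lam = wavelength_um if wavelength_um is not None else cfg.lambda_em_um
    z = np.atleast_1d(np.asarray(z_um, dtype=float))
    wm = _WaveModel(cfg, nu, support, supersample, lam)
    mask = aperture_mask(nu)
    kernels = np.empty((z.size, nu, nu, support, support))
    offs = [_offset_um((i, j), cfg.mla_pitch_um) for i in range(OFFSET_GRID) for j in range(OFFSET_GRID)]
    w = hamming_weights(OFFSET_GRID).ravel()
    for iz, zi in enumerate(z):
        acc = np.zeros((nu, nu, support, support))
        for wk, off in zip(w, offs):
            acc += wk * wm.pattern(zi, off, model)
        acc = np.where(mask[:, :, None, None], acc, 0.0)
        if truncate > 0:
            acc[acc < truncate * acc.max()] = 0.0
        s = acc.sum()
        if not s > 0:
            raise ValueError(f"kernel at z={zi} um has no energy inside the aperture")
        kernels[iz] = acc / s
    return LFPSF(
        kernels,
        z,
        lateral_pitch_um=native_lateral_resolution(cfg),
        meta={
            "model": model,
            "wavelength_um": lam,
            "support": support,
            "supersample": supersample,
            "truncate": truncate,
            "nu": nu,
        },
    )


# ---------------------------------------------------------------------------
# Linear operators


def forward_project(volume: np.ndarray, psf: LFPSF) -> LightField:
    """Project a (nz, nx, ny) volume to its light field ``y = H x``.

    Each depth plane is convolved ('same', zero padded) with its kernel for
    every angular sample and the contributions are summed over depth.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must have axes (z, x, y)")
    if volume.shape[0] != psf.nz:
        raise ValueError(
            f"volume depth axis ({volume.shape[0]}) does not match PSF depth grid ({psf.nz})"
        )
    nz, nx, ny = volume.shape
    P, Q, kf = psf._ops(nx, ny)
    vf = np.fft.rfft2(volume, s=(P, Q))
    yf = np.einsum("zpq,zuvpq->uvpq", vf, kf)
    y_full = np.fft.irfft2(yf, s=(P, Q))
    o = (psf.ksize - 1) // 2
    y = y_full[:, :, o : o + nx, o : o + ny]
    return LightField(np.clip(y, 0.0, None), aperture_mask(psf.nu))


def adjoint_project(lf: LightField, psf: LFPSF) -> np.ndarray:
    """Apply the adjoint ``H^T y``: per-depth 'same' correlation, shape (nz, nx, ny).

    Satisfies ``<H x, y> == <x, H^T y>`` exactly (up to float rounding).
    """
    if lf.nu != psf.nu:
        raise ValueError("light-field angular geometry does not match the PSF")
    nx, ny = lf.spatial_shape
    P, Q, kf = psf._ops(nx, ny)
    o = (psf.ksize - 1) // 2
    emb = np.zeros((psf.nu, psf.nu, P, Q))
    emb[:, :, o : o + nx, o : o + ny] = lf.data
    yf = np.fft.rfft2(emb)
    xf = np.einsum("uvpq,zuvpq->zpq", yf, np.conj(kf))
    x_full = np.fft.irfft2(xf, s=(P, Q))
    return np.ascontiguousarray(x_full[:, :nx, :ny])


def save_psf(psf: LFPSF, path: str | Path) -> None:
    """Cache an :class:`LFPSF` in HDF5 (kernels, depth grid, build attributes)."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("psf/kernels", data=psf.kernels)
        fh.create_dataset("psf/z_um", data=psf.z_um)
        ds.attrs["lateral_pitch_um"] = psf.lateral_pitch_um
        for k, v in psf.meta.items():
            ds.attrs[k] = v


def load_psf(path: str | Path) -> LFPSF:
    with h5py.File(path, "r") as fh:
        ds = fh["psf/kernels"]
        meta = {k: v for k, v in ds.attrs.items() if k != "lateral_pitch_um"}
        return LFPSF(
            ds[()],
            fh["psf/z_um"][()],
            lateral_pitch_um=float(ds.attrs["lateral_pitch_um"]),
            meta=dict(meta),
        )
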