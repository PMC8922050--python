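"""Synthetic phantoms and simulated acquisitions.

Three scene families emulate the preparations the analysis is designed for:

* ``bead`` — a single 10-um fluorescent bead in a clear medium (resolution
  target for spatial-confinement measurements);
* ``single_cell`` — one dye-filled neuron: a 10-um soma plus thin dendrites,
  with backpropagating-action-potential calcium transients (large dendritic
  dF/F, smaller somatic dF/F);
* ``bulk`` — several somata at distinct depths over a high, smooth
  background, as produced by bath application of an AM-ester dye.

Dynamics: each stimulus pulse triggers an instantaneous-rise,
single-exponential-decay transient, ``F(t) = F0 * (1 + a * sum_i
exp(-(t - t_i)/tau) * step(t - t_i))``; the default decay constant
``tau = 0.23 / ln 2`` s makes the transient FWHM 0.23 s.  Default stimulus:
5 pulses at 0.5 Hz starting 1 s into a 10-s record at 20 frames/s
(200 frames).

The camera model applies Poisson shot noise to the expected counts, adds
Gaussian read noise and a constant dark offset, and clips at zero.  All
randomness flows from an explicit seed recorded in the outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .lfio import LightField, aperture_mask
from .optics import LFMConfig
from .psf import LFPSF, forward_project

__all__ = [
    "Sphere",
    "Cylinder",
    "PhantomSpec",
    "TransientModel",
    "NoiseModel",
    "SYNTH_CONFIG",
    "render_volume",
    "render_components",
    "simulate_timeseries",
    "simulate_lightfield_series",
    "simulate_widefield_series",
    "bead_spec",
    "single_cell_spec",
    "bulk_spec",
]

#: Desk-scale optical configuration used by the synthetic scenes: 25x / NA 0.8
#: water-immersion objective, 90-um-pitch f/16 MLA (f-number matched to the
#: image-side cone), 10-um camera pixels, 664-nm emission, 20 frames/s.
#: Gives Nu = 9 resolvable spots per lenslet and a 3.6-um native resolution.
SYNTH_CONFIG = LFMConfig(
    magnification=25.0,
    na=0.8,
    n_immersion=1.33,
    mla_pitch_um=90.0,
    mla_fnumber=16.0,
    pixel_size_um=10.0,
    lambda_em_um=0.664,
    frame_rate_hz=20.0,
)


@dataclass(frozen=True)
class Sphere:
    """A fluorescent sphere: centre (z, x, y) in um, diameter in um, brightness
    in counts per voxel at unit voxel volume."""

    center_um: tuple[float, float, float]
    diameter_um: float
    brightness: float


@dataclass(frozen=True)
class Cylinder:
    """A dendrite-like cylinder between two (z, x, y) endpoints (um)."""

    p0_um: tuple[float, float, float]
    p1_um: tuple[float, float, float]
    radius_um: float
    brightness: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling of a synthetic scene.

    ``shape`` is (nz, nx, ny) voxels; ``z_um`` the depth grid (1-um spacing
    by default); ``lateral_pitch_um`` the voxel pitch in x and y (the native
    LFM resolution); ``background`` a constant background brightness (counts
    per voxel; for bulk scenes at least half the soma brightness).
    """

    scene: str
    structures: tuple
    shape: tuple[int, int, int]
    lateral_pitch_um: float
    z_um: tuple[float, ...]
    background: float = 0.0

    def __post_init__(self) -> None:
        if len(self.z_um) != self.shape[0]:
            raise ValueError("z grid does not match the volume depth axis")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        nz, nx, ny = self.shape
        z0, z1 = min(self.z_um), max(self.z_um)
        hx = (nx - 1) / 2.0 * self.lateral_pitch_um
        for s in self.structures:
            pts = [s.center_um] if isinstance(s, Sphere) else [s.p0_um, s.p1_um]
            r = s.diameter_um / 2.0 if isinstance(s, Sphere) else s.radius_um
            for (z, x, y) in pts:
                if not (z0 - 1 <= z <= z1 + 1 and abs(x) <= hx + 1 and abs(y) <= hx + 1):
                    raise ValueError(f"structure at {(z, x, y)} falls outside the field")
                if not r > 0:
                    raise ValueError("structure radius must be positive")

    def axes_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nz, nx, ny = self.shape
        z = np.asarray(self.z_um, dtype=float)
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.lateral_pitch_um
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.lateral_pitch_um
        return z, x, y


@dataclass(frozen=True)
class TransientModel:
    """Stimulus-locked calcium dynamics per compartment.

    ``onsets_s``: stimulus times (default 5 pulses at 0.5 Hz from t = 1 s);
    ``amplitudes``: peak dF/F fraction per structure (defaults: soma 0.11,
    dendrite 0.2, matching the regime the analysis targets); ``tau_s``: decay
    constant, default 0.23 / ln 2 so the transient FWHM is 0.23 s.
    """

    onsets_s: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 9.0)
    amplitudes: tuple[float, ...] = (0.11,)
    tau_s: float = 0.23 / math.log(2.0)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if not self.tau_s > 0:
            raise ValueError("decay constant must be positive")

    def waveform(self, t_s: np.ndarray, amplitude: float) -> np.ndarray:
        """Multiplicative modulation ``1 + a * sum_i exp(-(t-t_i)/tau)``."""
        t_s = np.asarray(t_s, dtype=float)
        mod = np.ones_like(t_s)
        for t0 in self.onsets_s:
            on = t_s >= t0
            mod[on] += amplitude * np.exp(-(t_s[on] - t0) / self.tau_s)
        return mod


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: Poisson shot noise, Gaussian read noise, dark offset."""

    read_sigma: float = 2.0
    dark: float = 100.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.read_sigma < 0 or self.dark < 0:
            raise ValueError("noise parameters must be non-negative")

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = rng.poisson(expected).astype(float) if self.poisson else expected.copy()
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return np.clip(out + self.dark, 0.0, None)


# ---------------------------------------------------------------------------
# Rasterization

_SUPERSAMPLE = 3


def _coverage_sphere(spec: PhantomSpec, s: Sphere) -> np.ndarray:
    """Partial-volume coverage of a sphere, supersampled 3x per axis."""
    z, x, y = spec.axes_um()
    dz = float(np.diff(z).mean()) if z.size > 1 else 1.0
    n = _SUPERSAMPLE
    sub = (np.arange(n) - (n - 1) / 2.0) / n
    zz = z[:, None] + sub[None, :] * dz
    xx = x[:, None] + sub[None, :] * spec.lateral_pitch_um
    yy = y[:, None] + sub[None, :] * spec.lateral_pitch_um
    r2 = (s.diameter_um / 2.0) ** 2
    az = (zz - s.center_um[0]) ** 2
    ax = (xx - s.center_um[1]) ** 2
    ay = (yy - s.center_um[2]) ** 2
    inside = (
        az[:, None, None, :, None, None]
        + ax[None, :, None, None, :, None]
        + ay[None, None, :, None, None, :]
    ) <= r2
    return inside.mean(axis=(3, 4, 5))


def _coverage_cylinder(spec: PhantomSpec, c: Cylinder) -> np.ndarray:
    z, x, y = spec.axes_um()
    dz = float(np.diff(z).mean()) if z.size > 1 else 1.0
    n = _SUPERSAMPLE
    sub = (np.arange(n) - (n - 1) / 2.0) / n
    zz = (z[:, None] + sub[None, :] * dz).ravel()
    xx = (x[:, None] + sub[None, :] * spec.lateral_pitch_um).ravel()
    yy = (y[:, None] + sub[None, :] * spec.lateral_pitch_um).ravel()
    p0 = np.asarray(c.p0_um)
    d = np.asarray(c.p1_um) - p0
    L2 = float(d @ d)
    P = np.stack(np.meshgrid(zz, xx, yy, indexing="ij"), axis=-1) - p0
    t = np.clip(np.tensordot(P, d, axes=([-1], [0])) / max(L2, 1e-12), 0.0, 1.0)
    closest = t[..., None] * d
    dist2 = ((P - closest) ** 2).sum(axis=-1)
    inside = dist2 <= c.radius_um**2
    nz, nx, ny = spec.shape
    inside = inside.reshape(nz, n, nx, n, ny, n)
    return inside.mean(axis=(1, 3, 5))


def render_components(spec: PhantomSpec) -> list[np.ndarray]:
    """Per-structure antialiased rasterizations (brightness-scaled volumes)."""
    out = []
    for s in spec.structures:
        cov = _coverage_sphere(spec, s) if isinstance(s, Sphere) else _coverage_cylinder(spec, s)
        out.append(s.brightness * cov)
    return out


def render_volume(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth static volume: structures plus constant background."""
    vol = np.full(spec.shape, float(spec.background))
    for comp in render_components(spec):
        vol += comp
    return vol


def simulate_timeseries(
    spec: PhantomSpec,
    transients: TransientModel,
    t_s: np.ndarray,
) -> np.ndarray:
    """Noiseless ground-truth 4D series (t, z, x, y).

    Structure ``i`` is modulated by the transient waveform with amplitude
    ``transients.amplitudes[i]`` (the last amplitude is reused when fewer
    amplitudes than structures are given); geometry and background are static.
    """
    t_s = np.asarray(t_s, dtype=float)
    if t_s.size > 1:
        steps = np.diff(t_s)
        if not np.allclose(steps, steps[0]):
            raise ValueError("time grid must be uniform")
    if (
        transients.onsets_s
        and max(transients.amplitudes, default=0.0) > 0
        and max(transients.onsets_s) > (t_s[-1] if t_s.size else 0)
    ):
        raise ValueError("stimulus onsets must fall within the record")
    comps = render_components(spec)
    series = np.broadcast_to(
        np.full(spec.shape, float(spec.background)), (t_s.size,) + spec.shape
    ).copy()
    for i, comp in enumerate(comps):
        a = transients.amplitudes[min(i, len(transients.amplitudes) - 1)]
        mod = transients.waveform(t_s, a)
        series += mod[:, None, None, None] * comp[None]
    return series


def simulate_lightfield_series(
    series: np.ndarray,
    psf: LFPSF,
    noise: NoiseModel,
    seed: int,
) -> list[LightField]:
    """Project a ground-truth series through the LFM and apply the camera model.

    ``y_t = clip(Poisson(H x_t) + N(0, sigma) + dark, 0)``; deterministic for
    a given seed.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must have axes (t, z, x, y)")
    rng = np.random.default_rng(seed)
    mask = aperture_mask(psf.nu)
    out = []
    for frame in series:
        expected = forward_project(frame, psf).data
        noisy = noise.apply(expected, rng)
        noisy = np.where(mask[:, :, None, None], noisy, 0.0)
        out.append(LightField(noisy, mask))
    return out


def widefield_sigma_um(cfg: LFMConfig, dz_um: float) -> float:
    """Gaussian blur width of a plane defocused by ``dz`` in a widefield image.

    In focus the width is the diffraction-limited Sparrow radius; defocus
    adds the geometric blur cone ``|dz| * NA / n`` (radius), combined in
    quadrature... widths in sample-plane um.
    """
    sigma0 = 0.47 * cfg.lambda_em_um / cfg.na / 2.355
    geo = abs(dz_um) * cfg.na / cfg.n_immersion / 2.0
    return math.hypot(sigma0, geo)


def simulate_widefield_series(
    series: np.ndarray,
    cfg: LFMConfig,
    z_um: np.ndarray,
    z_focus_um: float,
    noise: NoiseModel,
    seed: int,
    lateral_pitch_um: float | None = None,
) -> np.ndarray:
    """Widefield camera series of the same ground truth, focused at ``z_focus``.

    Each plane is blurred with a Gaussian defocus kernel whose width grows
    linearly with ``|z - z_focus|`` and all planes are summed, then the
    camera noise model is applied.  Returns a (t, x, y) array.
    """
    series = np.asarray(series, dtype=float)
    z_um = np.asarray(z_um, dtype=float)
    if not (z_um.min() - 1e-9 <= z_focus_um <= z_um.max() + 1e-9):
        raise ValueError("z_focus must lie within the volume")
    if lateral_pitch_um is None:
        lateral_pitch_um = cfg.mla_pitch_um / cfg.magnification
    sig_px = np.array(
        [widefield_sigma_um(cfg, z - z_focus_um) / lateral_pitch_um for z in z_um]
    )
    rng = np.random.default_rng(seed)
    out = np.empty((series.shape[0],) + series.shape[2:])
    for t, frame in enumerate(series):
        img = np.zeros(series.shape[2:])
        for iz in range(z_um.size):
            img += ndimage.gaussian_filter(frame[iz], sig_px[iz], mode="constant")
        out[t] = noise.apply(img, rng)
    return out


# ---------------------------------------------------------------------------
# Preset scenes (desk scale: 15x15 lenslets, 41 planes at 1 um)


def _default_grid(
    n_lenslets: int = 15, nz: int = 41, pitch: float | None = None
) -> tuple[tuple[int, int, int], float, tuple[float, ...]]:
    if pitch is None:
        pitch = SYNTH_CONFIG.mla_pitch_um / SYNTH_CONFIG.magnification
    z = tuple(np.arange(nz, dtype=float) - (nz - 1) / 2.0)
    return (nz, n_lenslets, n_lenslets), pitch, z


def bead_spec(brightness: float = 3000.0, z_center: float = 0.0) -> PhantomSpec:
    """A single 10-um bead in a clear medium."""
    shape, pitch, z = _default_grid()
    return PhantomSpec(
        "bead",
        (Sphere((z_center, 0.0, 0.0), 10.0, brightness),),
        shape,
        pitch,
        z,
        background=0.0,
    )


def single_cell_spec(
    soma_brightness: float = 3000.0,
    soma_z: float = 0.0,
    dendrite_z: float = 6.0,
) -> PhantomSpec:
    """A dye-filled neuron: 10-um soma plus a thin dendrite running off-axis.

    The dendrite leaves the soma laterally and climbs to ``dendrite_z`` um,
    emulating a process crossing depth planes.
    """
    shape, pitch, z = _default_grid()
    soma = Sphere((soma_z, 0.0, 0.0), 10.0, soma_brightness)
    dend = Cylinder(
        (soma_z, 4.0, 0.0),
        (dendrite_z, 22.0, 7.0),
        radius_um=1.5,
        brightness=soma_brightness * 0.6,
    )
    return PhantomSpec("single_cell", (soma, dend), shape, pitch, z, background=0.0)


def bulk_spec(
    soma_brightness: float = 3000.0,
    depths_um: Sequence[float] = (-5.0, 4.0),
    background_frac: float = 0.5,
) -> PhantomSpec:
    """Several somata at distinct depths over a high, smooth background.

    The constant background is ``background_frac`` (>= 0.5) of the soma
    brightness, emulating bulk AM-ester labeling where raw-image contrast is
    too low to segment cells and the activation map is required.
    """
    if background_frac < 0.5:
        raise ValueError("bulk scenes require background >= 50% of soma brightness")
    shape, pitch, z = _default_grid()
    lateral = [(-9.0, -9.0), (11.0, 9.0), (-11.0, 13.0), (13.0, -11.0)]
    somata = tuple(
        Sphere((zc, lx, ly), 10.0, soma_brightness)
        for zc, (lx, ly) in zip(depths_um, lateral)
    )
    return PhantomSpec(
        "bulk", somata, shape, pitch, z, background=background_frac * soma_brightness
    )
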