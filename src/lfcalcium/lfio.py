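"""Light-field containers, sensor-frame rectification, and file I/O.

The raw LFM sensor frame is a mosaic of circular lenslet subimages.
Rectification resamples it onto the 4D light field ``L(u, v, x, y)``:
``(x, y)`` index lenslets (lateral sample position, one sample per native
resolution unit) and ``(u, v)`` index positions within a subimage (ray
angle).  Angular indices are signed offsets centred on the lenslet axis,
and samples outside the circular subimage aperture (a disk of diameter
``Nu`` samples) are zero.

Coordinate conventions shared by all modules:

* ``(x, y)``: 0-based lenslet indices;
* ``(u, v)``: signed angular offsets, ``u = index - (Nu - 1) / 2``;
* ``z``: signed um relative to the native focal plane.

Raw frames and reconstructed stacks travel as multi-page 16-bit TIFF;
4D light fields and volume series travel as HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile
import h5py
from scipy import ndimage

__all__ = [
    "CalibrationError",
    "LensletGrid",
    "LightField",
    "aperture_mask",
    "angular_offsets",
    "rectify",
    "views",
    "load_series",
    "save_series",
    "save_lightfield",
    "load_lightfield",
]


class CalibrationError(ValueError):
    """Raised when a lenslet grid is inconsistent with the sensor frame."""


def angular_offsets(nu: int) -> np.ndarray:
    """Signed angular sample offsets for an ``nu``-sample subimage axis."""
    return np.arange(nu) - (nu - 1) / 2.0


def aperture_mask(nu: int) -> np.ndarray:
    """Boolean disk of diameter ``nu`` samples on the square (u, v) grid.

    Lenslet subimages are circular; the corner samples of the square angular
    grid receive no light and are masked out.
    """
    off = angular_offsets(nu)
    uu, vv = np.meshgrid(off, off, indexing="ij")
    return uu**2 + vv**2 <= (nu / 2.0) ** 2


@dataclass(frozen=True)
class LensletGrid:
    """Sub-pixel calibration of the lenslet lattice on the sensor.

    ``center_x_px, center_y_px`` locate lenslet (0, 0); ``pitch_px`` is the
    lenslet spacing in pixels (may be fractional, e.g. 125 um / 6.5 um =
    19.23 px); ``rotation_rad`` a small in-plane rotation; ``nx, ny`` the
    grid extent in lenslets.  Axis 0 of the pixel array is "x".
    """

    center_x_px: float
    center_y_px: float
    pitch_px: float
    nx: int
    ny: int
    rotation_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.pitch_px > 2:
            raise CalibrationError(f"pitch_px must exceed 2, got {self.pitch_px}")
        if abs(self.rotation_rad) > np.deg2rad(5):
            raise CalibrationError("grid rotation must be below 5 degrees")
        if self.nx < 1 or self.ny < 1:
            raise CalibrationError("grid extent must be at least 1x1 lenslets")

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates of all lenslet centres, arrays of shape (nx, ny)."""
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        gx = ix * self.pitch_px
        gy = iy * self.pitch_px
        return (
            self.center_x_px + c * gx - s * gy,
            self.center_y_px + s * gx + c * gy,
        )


@dataclass
class LightField:
    """The 4D light field ``L(u, v, x, y)`` with its angular aperture mask.

    ``data`` has shape ``(nu, nu, nx, ny)`` with non-negative values (counts);
    entries outside the circular aperture are zero.
    """

    data: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("light-field data must have shape (nu, nu, nx, ny)")
        if self.mask is None:
            self.mask = aperture_mask(self.nu)
        self.data = np.where(self.mask[:, :, None, None], self.data, 0.0)
        if np.any(self.data < 0):
            raise ValueError("light-field samples must be non-negative")

    @property
    def nu(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def view(self, u: float, v: float) -> np.ndarray:
        """The 2D angular view ``L(u, v, ., .)`` for a signed in-aperture offset."""
        off = angular_offsets(self.nu)
        iu = np.where(np.isclose(off, u))[0]
        iv = np.where(np.isclose(off, v))[0]
        if len(iu) != 1 or len(iv) != 1 or not self.mask[iu[0], iv[0]]:
            raise KeyError(f"(u, v) = ({u}, {v}) is not an in-aperture angular sample")
        return self.data[iu[0], iv[0]]

    def total(self) -> float:
        return float(self.data.sum())


def views(lf: LightField) -> Mapping[tuple[float, float], np.ndarray]:
    """Mapping from each in-aperture signed ``(u, v)`` to its 2D view."""
    off = angular_offsets(lf.nu)
    out: dict[tuple[float, float], np.ndarray] = {}
    for i, u in enumerate(off):
        for j, v in enumerate(off):
            if lf.mask[i, j]:
                out[(float(u), float(v))] = lf.data[i, j]
    return out


def rectify(raw: np.ndarray, grid: LensletGrid, nu: int) -> LightField:
    """Resample a raw sensor frame onto the 4D light field ``L(u, v, x, y)``.

    For lenslet ``(x, y)`` and signed angular offset ``(u, v)`` the sample is
    the bilinear interpolation of the frame at the lenslet centre displaced by
    ``(u, v) * pitch_px / nu`` (rotated with the grid).  Samples outside the
    circular aperture are zeroed.

    Raises
    ------
    CalibrationError
        If any requested sample falls outside the sensor frame.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw frame must be 2D")
    if nu < 2:
        raise ValueError("nu must be >= 2")
    cx, cy = grid.centers()  # (nx, ny)
    off = angular_offsets(nu) * grid.pitch_px / nu
    c, s = np.cos(grid.rotation_rad), np.sin(grid.rotation_rad)
    du = (c * off[:, None, None, None] - s * off[None, :, None, None])
    dv = (s * off[:, None, None, None] + c * off[None, :, None, None])
    px = cx[None, None] + du  # (nu, nu, nx, ny)
    py = cy[None, None] + dv
    mask = aperture_mask(nu)
    sel = mask[:, :, None, None] & np.ones(px.shape, bool)
    if (px[sel].min() < 0 or py[sel].min() < 0
            or px[sel].max() > raw.shape[0] - 1 or py[sel].max() > raw.shape[1] - 1):
        raise CalibrationError("lenslet grid samples extend beyond the sensor frame")
    vals = ndimage.map_coordinates(raw, [px.ravel(), py.ravel()], order=1, mode="constant")
    data = vals.reshape(px.shape)
    data = np.where(mask[:, :, None, None], data, 0.0)
    return LightField(np.clip(data, 0.0, None), mask)


# ---------------------------------------------------------------------------
# File I/O


def load_series(path: str | Path) -> np.ndarray:
    """Load a multi-page TIFF as a float array of frames, shape (t, px, py).

    Pages must share a single 2D shape; values are returned as floats on the
    raw count scale.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"could not read TIFF {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2D pages in {path}, got shape {pages.shape}")
    return pages.astype(float)


def save_series(frames: np.ndarray, path: str | Path) -> None:
    """Write a (t, px, py) array as a 16-bit multi-page TIFF."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    out = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(Path(path), out)


def save_lightfield(lf: LightField, path: str | Path, **attrs) -> None:
    """Store a light field in HDF5 under ``/lightfield`` with its mask."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("lightfield", data=lf.data)
        fh.create_dataset("aperture_mask", data=lf.mask)
        ds.attrs["nu"] = lf.nu
        for k, v in attrs.items():
            ds.attrs[k] = v


def load_lightfield(path: str | Path) -> LightField:
    with h5py.File(path, "r") as fh:
        data = fh["lightfield"][()]
        mask = fh["aperture_mask"][()].astype(bool)
    return LightField(data, mask)
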