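"""Optical configuration and closed-form design arithmetic for an MLA-based LFM.

A light-field microscope (LFM) places a microlens array (MLA) at the native
image plane of a widefield fluorescence microscope.  The camera then records,
behind each lenslet, a circular subimage encoding the angular distribution of
the light arriving at that lateral position.  Three numbers govern the design:

* the **native lateral resolution**, the microlens pitch referred to the
  sample, ``p / M``;
* ``Nu``, the number of diffraction-limited (Sparrow) spots resolvable across
  one lenslet subimage, which sets the number of usable angular samples; and
* the synthetic-refocusing **depth of field**, ``D = (2 + Nu) * lambda * n /
  (2 * NA**2)``, which grows linearly with ``Nu`` (a conventional widefield
  microscope is the ``Nu = 0`` case).

All lengths are micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = [
    "LFMConfig",
    "PAPER_CONFIG",
    "InvalidConfiguration",
    "depth_of_field",
    "sparrow_spot_size_camera",
    "resolvable_spots_per_lenslet",
    "native_lateral_resolution",
    "refocus_shift_slope",
    "load_config",
    "save_config",
]

#: Sparrow two-point resolution prefactor for incoherent imaging.
SPARROW_PREFACTOR = 0.47


class InvalidConfiguration(ValueError):
    """Raised when an optical configuration violates a physical invariant."""


@dataclass(frozen=True)
class LFMConfig:
    """Optical configuration of a microlens-array light-field microscope.

    Parameters
    ----------
    magnification
        Objective (plus tube lens) magnification ``M``.
    na
        Objective numerical aperture.
    n_immersion
        Immersion-medium refractive index (1.33 for water immersion).
    mla_pitch_um
        Microlens pitch ``p`` at the image plane, in um.
    mla_fnumber
        MLA f-number (focal length / pitch).
    pixel_size_um
        Camera pixel size at the sensor plane, in um.
    lambda_em_um
        Peak emission wavelength, in um.
    frame_rate_hz
        Acquisition frame rate, in Hz.
    """

    magnification: float
    na: float
    n_immersion: float
    mla_pitch_um: float
    mla_fnumber: float
    pixel_size_um: float
    lambda_em_um: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise InvalidConfiguration(f"{name} must be strictly positive, got {value!r}")
        if self.na > self.n_immersion:
            raise InvalidConfiguration(
                f"NA ({self.na}) cannot exceed the immersion index ({self.n_immersion})"
            )
        if self.mla_pitch_um / self.pixel_size_um < 2:
            raise InvalidConfiguration("need at least 2 camera pixels per lenslet pitch")

    @property
    def pitch_px(self) -> float:
        """Lenslet pitch in camera pixels."""
        return self.mla_pitch_um / self.pixel_size_um

    @property
    def mla_focal_um(self) -> float:
        """Lenslet focal length in um (f-number times pitch)."""
        return self.mla_fnumber * self.mla_pitch_um


#: Configuration of the reference instrument: 25x / NA 1.0 water-immersion
#: objective, 125-um-pitch f/10 MLA, 6.5-um sCMOS pixels, CaSiR-1 emission
#: (664 nm peak), 20 frames/s.
PAPER_CONFIG = LFMConfig(
    magnification=25.0,
    na=1.0,
    n_immersion=1.33,
    mla_pitch_um=125.0,
    mla_fnumber=10.0,
    pixel_size_um=6.5,
    lambda_em_um=0.664,
    frame_rate_hz=20.0,
)


def depth_of_field(cfg: LFMConfig, nu: int) -> float:
    """Synthetic-refocusing depth of field ``(2 + Nu) * lambda * n / (2 NA^2)`` in um.

    ``nu`` is the number of resolvable spots per lenslet; ``nu = 0`` recovers
    the conventional widefield depth of field.
    """
    if nu < 0 or int(nu) != nu:
        raise ValueError(f"Nu must be a non-negative integer, got {nu!r}")
    if not cfg.na > 0:
        raise InvalidConfiguration("NA must be positive")
    return (2 + nu) * cfg.lambda_em_um * cfg.n_immersion / (2.0 * cfg.na**2)


def sparrow_spot_size_camera(cfg: LFMConfig) -> float:
    """Sparrow-criterion diffraction-limited spot diameter at the camera plane, um.

    The sample-side Sparrow distance ``0.47 * lambda / NA`` magnified by ``M``.
    """
    return SPARROW_PREFACTOR * cfg.lambda_em_um / cfg.na * cfg.magnification


def resolvable_spots_per_lenslet(cfg: LFMConfig) -> int:
    """Number of resolvable spots ``Nu`` behind each microlens.

    The pitch budget divided by the camera-plane Sparrow spot, floored:
    partially resolvable spots do not count.
    """
    return int(math.floor(cfg.mla_pitch_um / sparrow_spot_size_camera(cfg)))


def native_lateral_resolution(cfg: LFMConfig) -> float:
    """Native LFM lateral resolution: microlens pitch / magnification, um."""
    return cfg.mla_pitch_um / cfg.magnification


def refocus_shift_slope(cfg: LFMConfig, nu: int) -> float:
    """Shift-and-add calibration constant ``c`` such that ``1 - 1/alpha = c * z``.

    A sensor pixel at angular index ``u`` (offset from the subimage centre)
    sits ``u * p / Nu`` from the lenslet axis and therefore collects rays at
    image-side angle ``tan(theta') = u * p / (Nu * f_mla)``.  Referred to the
    sample (angles scale by ``M``, transverse lengths by ``1/M``, axial by the
    immersion index), a source defocused by ``z`` um appears in view ``u``
    shifted by ``c * z * u`` lenslets with::

        c = M**2 / (n * Nu * N_mla * p)      [1/um]

    where ``N_mla`` is the MLA f-number and ``p`` the pitch in um.  Refocusing
    at depth ``z`` applies the opposite shift, so ``alpha(z) = 1 / (1 - c z)``;
    the mapping is valid for ``|z| < 1 / c``.
    """
    if nu < 1:
        raise ValueError("Nu must be >= 1")
    return cfg.magnification**2 / (cfg.n_immersion * nu * cfg.mla_fnumber * cfg.mla_pitch_um)


def load_config(path: str | Path) -> LFMConfig:
    """Load an :class:`LFMConfig` from a flat YAML key/value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return LFMConfig(**{k: float(v) for k, v in data.items()})


def save_config(cfg: LFMConfig, path: str | Path) -> None:
    """Write an :class:`LFMConfig` as a flat YAML key/value file."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
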