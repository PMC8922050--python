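"""Shared fixtures: desk-scale PSF, simulated scenes, reconstruction sweeps.

Everything is generated programmatically at test time; the expensive pieces
(wave-optics PSF, 200-frame simulations, iteration sweeps) are session-scoped
and shared between the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lfcalcium.deconv import DeconvParams, deconvolve_series
from lfcalcium.lfio import LightField, aperture_mask
from lfcalcium.optics import resolvable_spots_per_lenslet
from lfcalcium.phantoms import (
    NoiseModel,
    SYNTH_CONFIG,
    TransientModel,
    bead_spec,
    bulk_spec,
    simulate_lightfield_series,
    simulate_timeseries,
    single_cell_spec,
)
from lfcalcium.psf import LFPSF, build_psf
from lfcalcium.refocus import refocus_series, refocus_stack

Z_GRID = np.arange(-20.0, 21.0)
DT = 1.0 / SYNTH_CONFIG.frame_rate_hz
N_FRAMES = 200
STIM_ONSETS = (1.0, 3.0, 5.0, 7.0, 9.0)
BASELINE = slice(0, 20)
SEED = 20260926


@pytest.fixture(scope="session")
def cfg():
    return SYNTH_CONFIG


@pytest.fixture(scope="session")
def nu(cfg):
    return resolvable_spots_per_lenslet(cfg)


@pytest.fixture(scope="session")
def desk_psf(cfg, nu) -> LFPSF:
    """Scalar-model light-field PSF on the desk-scale depth grid (41 planes)."""
    return build_psf(cfg, Z_GRID, nu, model="scalar", support=15, supersample=3)


def random_psf(rng: np.random.Generator, nz=3, nu=5, k=5) -> LFPSF:
    """A random non-negative aperture-masked kernel set, for operator tests."""
    kernels = rng.random((nz, nu, nu, k, k))
    kernels *= aperture_mask(nu)[None, :, :, None, None]
    kernels /= kernels.sum(axis=(1, 2, 3, 4), keepdims=True)
    return LFPSF(kernels, np.arange(nz, dtype=float), lateral_pitch_um=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def single_cell_truth():
    spec = single_cell_spec()
    t = np.arange(N_FRAMES) * DT
    model = TransientModel(STIM_ONSETS, amplitudes=(0.11, 0.2))
    return spec, simulate_timeseries(spec, model, t)


@pytest.fixture(scope="session")
def single_cell_lfs(single_cell_truth, desk_psf):
    _, truth = single_cell_truth
    return simulate_lightfield_series(truth, desk_psf, NoiseModel(), SEED)


@pytest.fixture(scope="session")
def single_cell_refocused(single_cell_lfs, cfg, nu):
    return refocus_series(single_cell_lfs, Z_GRID, cfg, nu)


@pytest.fixture(scope="session")
def single_cell_sweep(single_cell_lfs, desk_psf):
    """RL-deconvolved series snapshots at 1, 3, 8, 13 and 21 iterations."""
    params = DeconvParams(iterations=21, snapshots=(1, 3, 8, 13, 21))
    _, snaps = deconvolve_series(single_cell_lfs, desk_psf, params, dt_s=DT)
    return snaps


@pytest.fixture(scope="session")
def bead_recons(desk_psf, cfg, nu):
    """Single noisy bead frame reconstructed by refocusing and RL at 3/10/21."""
    from lfcalcium.deconv import deconvolve
    from lfcalcium.psf import forward_project

    spec = bead_spec()
    truth = simulate_timeseries(spec, TransientModel(amplitudes=(0.0,)), np.array([0.0]))
    lfs = simulate_lightfield_series(truth, desk_psf, NoiseModel(), SEED + 1)
    lf = lfs[0]
    refocused = refocus_stack(lf, Z_GRID, cfg, nu)
    params = DeconvParams(iterations=21, snapshots=(3, 10, 21))
    vol, log = deconvolve(lf, desk_psf, params, dt_s=DT)
    return {"truth": truth[0], "refocused": refocused.data[0], **{
        f"deconvolved_{k}": v for k, v in log["snapshots"].items()
    }}


@pytest.fixture(scope="session")
def bulk_sim(desk_psf):
    """Bulk-labeled scene: two active somata at -5 and +4 um, high background."""
    spec = bulk_spec(depths_um=(-5.0, 4.0))
    t = np.arange(N_FRAMES) * DT
    truth = simulate_timeseries(spec, TransientModel(STIM_ONSETS, (0.11,)), t)
    lfs = simulate_lightfield_series(truth, desk_psf, NoiseModel(), SEED + 2)
    return spec, truth, lfs


@pytest.fixture(scope="session")
def bulk_recons(bulk_sim, desk_psf, cfg, nu):
    _, _, lfs = bulk_sim
    refocused = refocus_series(lfs, Z_GRID, cfg, nu)
    deconvolved = deconvolve_series(lfs, desk_psf, DeconvParams(iterations=3), dt_s=DT)
    return {"refocused": refocused, "deconvolved_3": deconvolved}
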