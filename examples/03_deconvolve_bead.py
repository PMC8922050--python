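"""Richardson-Lucy deconvolution sharpens the bead reconstruction.

Reconstructs the same bead light field with RL deconvolution at 3, 10 and
21 iterations and compares axial/lateral FWHMs against synthetic refocusing.
More iterations confine the signal better, at a growing computational (and,
for time series, noise) cost.
"""

import numpy as np

from lfcalcium import SYNTH_CONFIG, build_psf, spatial_profile
from lfcalcium.deconv import DeconvParams, deconvolve
from lfcalcium.optics import resolvable_spots_per_lenslet
from lfcalcium.phantoms import NoiseModel, TransientModel, bead_spec, simulate_lightfield_series, simulate_timeseries
from lfcalcium.refocus import refocus_stack

cfg = SYNTH_CONFIG
nu = resolvable_spots_per_lenslet(cfg)
z = np.arange(-20.0, 21.0)
psf = build_psf(cfg, z, nu, model="scalar")

spec = bead_spec()
truth = simulate_timeseries(spec, TransientModel(amplitudes=(0.0,)), np.array([0.0]))
lf = simulate_lightfield_series(truth, psf, NoiseModel(), seed=7)[0]


def report(vol, label):
    iz, ix, iy = np.unravel_index(np.argmax(vol), vol.shape)
    _, wx, _ = spatial_profile(vol, "x", through=(iz, ix, iy), pitch_um=3.6)
    _, wz, _ = spatial_profile(vol, "z", through=(iz, ix, iy), pitch_um=1.0)
    print(f"{label:<22s} lateral {wx:5.1f} um   axial {wz:5.1f} um")


report(refocus_stack(lf, z, cfg, nu).data[0], "refocused")
_, log = deconvolve(lf, psf, DeconvParams(iterations=21, snapshots=(3, 10, 21)))
for k in (3, 10, 21):
    report(log["snapshots"][k], f"deconvolved ({k} it.)")
print()
print("Axial confinement keeps improving with iterations; the lateral")
print("improvement saturates by ~10 iterations.")
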