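"""Synthetic refocusing of a simulated 10-um fluorescent bead.

Builds the wave-optics light-field PSF for the desk-scale instrument,
projects a bead phantom into a (noisy) light field, refocuses a z-stack
and reports the bead's lateral and axial spread (FWHM).  Refocusing has no
optical sectioning, so the axial width far exceeds the bead diameter.
"""

import numpy as np

from lfcalcium import SYNTH_CONFIG, build_psf, spatial_profile
from lfcalcium.optics import resolvable_spots_per_lenslet
from lfcalcium.phantoms import NoiseModel, TransientModel, bead_spec, simulate_lightfield_series, simulate_timeseries
from lfcalcium.refocus import refocus_stack

cfg = SYNTH_CONFIG
nu = resolvable_spots_per_lenslet(cfg)
z = np.arange(-20.0, 21.0)

print("building light-field PSF (41 depth planes) ...")
psf = build_psf(cfg, z, nu, model="scalar")

spec = bead_spec()
truth = simulate_timeseries(spec, TransientModel(amplitudes=(0.0,)), np.array([0.0]))
lf = simulate_lightfield_series(truth, psf, NoiseModel(), seed=7)[0]

stack = refocus_stack(lf, z, cfg, nu)
vol = stack.data[0]
iz, ix, iy = np.unravel_index(np.argmax(vol), vol.shape)
_, wx, _ = spatial_profile(vol, "x", through=(iz, ix, iy), pitch_um=stack.lateral_pitch_um)
_, wz, _ = spatial_profile(vol, "z", through=(iz, ix, iy), pitch_um=1.0)

print(f"brightest plane              : z = {z[iz]:+.0f} um (bead at 0)")
print(f"lateral FWHM                 : {wx:.1f} um (10-um bead)")
print(f"axial FWHM                   : {wz:.1f} um")
print()
print("The axial FWHM is several times the bead diameter: shift-and-add")
print("refocusing, like widefield, does not reject out-of-focus light.")
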