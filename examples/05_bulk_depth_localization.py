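"""Depth localization of active somata in a bulk-labeled scene.

Simulates two somata at -5 and +4 um under high background (bulk AM-ester
labeling), reconstructs the movie, segments active cells on the
noise-corrected activation map, and recovers each soma's depth as the
centre of mass of its axial activation profile.
"""

import numpy as np
from scipy import ndimage

from lfcalcium import SYNTH_CONFIG, build_psf
from lfcalcium.deconv import DeconvParams, deconvolve_series
from lfcalcium.metrics import depth_center_of_mass, signal_std_map
from lfcalcium.optics import resolvable_spots_per_lenslet
from lfcalcium.phantoms import NoiseModel, TransientModel, bulk_spec, simulate_lightfield_series, simulate_timeseries
from lfcalcium.refocus import refocus_series

cfg = SYNTH_CONFIG
nu = resolvable_spots_per_lenslet(cfg)
z = np.arange(-20.0, 21.0)
dt = 1.0 / cfg.frame_rate_hz

print("simulating bulk-labeled scene (somata at -5 and +4 um) ...")
psf = build_psf(cfg, z, nu, model="scalar")
spec = bulk_spec(depths_um=(-5.0, 4.0))
truth = simulate_timeseries(
    spec, TransientModel((1.0, 3.0, 5.0, 7.0, 9.0), (0.11,)), np.arange(200) * dt
)
lfs = simulate_lightfield_series(truth, psf, NoiseModel(), seed=7)

conditions = {
    "refocused": refocus_series(lfs, z, cfg, nu),
    "deconvolved(3)": deconvolve_series(lfs, psf, DeconvParams(iterations=3), dt_s=dt),
}
for name, series in conditions.items():
    sig = signal_std_map(series.data, slice(0, 20), fd=0.0)
    mip = sig.map.max(axis=0)
    labels, n = ndimage.label(mip >= np.percentile(mip, 92))
    print(f"{name}:")
    for comp in range(1, n + 1):
        mask = labels == comp
        if mask.sum() < 3:
            continue
        cx, cy = ndimage.center_of_mass(mip * mask)
        profile = sig.map[:, mask].sum(axis=1)
        com = depth_center_of_mass(profile, z)
        print(
            f"  soma at lateral ({(cx - 7) * 3.6:+5.1f}, {(cy - 7) * 3.6:+5.1f}) um"
            f" -> depth CoM {com:+.1f} um"
        )
print()
print("Both reconstructions separate the two cells axially; a single-plane")
print("widefield image could not assign depths at all.")
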