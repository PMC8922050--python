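"""Calcium-transient quantification on a simulated dye-filled neuron.

Simulates a 10-s light-field movie (20 frames/s) of a single neuron with
stimulus-locked calcium transients (5 pulses at 0.5 Hz), reconstructs it by
synthetic refocusing and 3-iteration RL deconvolution, and extracts matched
ROI metrics: peak dF/F, baseline noise, tSNR and decay time.
"""

import numpy as np

from lfcalcium import SYNTH_CONFIG, build_psf
from lfcalcium.deconv import DeconvParams, deconvolve_series
from lfcalcium.metrics import activation_map, extract_roi, roi_timecourse, transient_metrics
from lfcalcium.optics import resolvable_spots_per_lenslet
from lfcalcium.phantoms import NoiseModel, TransientModel, simulate_lightfield_series, simulate_timeseries, single_cell_spec
from lfcalcium.refocus import refocus_series

cfg = SYNTH_CONFIG
nu = resolvable_spots_per_lenslet(cfg)
z = np.arange(-20.0, 21.0)
dt = 1.0 / cfg.frame_rate_hz
onsets = (1.0, 3.0, 5.0, 7.0, 9.0)

print("building PSF and simulating 200 frames ...")
psf = build_psf(cfg, z, nu, model="scalar")
spec = single_cell_spec()
truth = simulate_timeseries(spec, TransientModel(onsets, (0.11, 0.2)), np.arange(200) * dt)
lfs = simulate_lightfield_series(truth, psf, NoiseModel(), seed=7)

print("reconstructing (refocusing + 3-iteration RL) ...")
refoc = refocus_series(lfs, z, cfg, nu)
decon = deconvolve_series(lfs, psf, DeconvParams(iterations=3), dt_s=dt)

baseline = slice(0, 20)  # 1 s before the first pulse
amap = activation_map(decon.data, baseline, fd=0.0)
iz = int(np.argmax(amap.map.sum(axis=(1, 2))))
roi = extract_roi(amap.map[iz], 98.0)
print(f"ROI: top-2% activation pixels at plane z = {z[iz]:+.0f} um ({roi.size} px)")

for label, series in (("refocused", refoc), ("deconvolved(3)", decon)):
    ts = roi_timecourse(series.data[:, iz], roi, baseline, fd=0.0, dt_s=dt)
    m = transient_metrics(ts, onsets)
    print(
        f"{label:<15s} peak {m.peak_pct:5.1f}%  noise {m.noise_pct:.2f}%  "
        f"tSNR {m.tsnr:5.1f}  decay {m.decay_s * 1e3:.0f} ms"
    )
print()
print("Deconvolution concentrates the transient light (higher peak dF/F) but")
print("also amplifies noise; the transient decay time is unchanged.")
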