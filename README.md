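# lfcalcium

Volume reconstruction and calcium-transient quantification for microlens-array
light-field microscopy (LFM).

## The problem

A light-field microscope places a microlens array (MLA) at the native image
plane of a widefield fluorescence microscope. Each lenslet forms a circular
subimage on the camera whose pixels encode the *angular* distribution of light
at that lateral position, so a single 2D frame carries the 4D light field
`L(u, v, x, y)` — `(x, y)` indexing lenslets and `(u, v)` ray angle. From one
frame a whole volume can be reconstructed computationally, which makes LFM
attractive for imaging fast neuronal calcium dynamics in 3D: somata and
dendrites at different depths are captured simultaneously at full camera frame
rate, with no scanning and no focal sweep.

The catch is the choice of reconstruction algorithm. **Synthetic refocusing**
(shift-and-add) is fast and linear but has no optical sectioning, so
out-of-focus light dilutes the in-focus signal. **Richardson–Lucy (RL) 3D
deconvolution** against a wave-optics light-field PSF confines signals much
better in x, y and especially z, but amplifies noise as iterations grow. For
calcium imaging this trades temporal signal-to-noise ratio (tSNR) against
spatial signal confinement, and the right operating point depends on the
experiment. This package implements both reconstructions, the quantification
pipeline that measures the trade-off, and synthetic phantoms that stand in
for brain-slice data so every stage is testable end to end.

## Methods at a glance

* Design arithmetic: Sparrow spot `0.47 λ/NA · M`, angular budget
  `Nu = floor(p / spot)`, native resolution `p/M`, refocusable depth of field
  `D = (2 + Nu) λ n / (2 NA²)`.
* Synthetic refocusing at a plane `f' = α f₀`:
  `I(x, y) = Σ_{u,v} L(x + u(1−1/α), y + v(1−1/α), u, v)`,
  with the depth calibration `1 − 1/α(z) = c·z`, `c = M² / (n · Nu · N_mla · p)`
  derived from the lenslet pixel↔angle mapping.
* Wave-optics light-field PSF: scalar Debye-type defocused amplitude at the
  image plane, modulated by the MLA phase, propagated to the sensor;
  optionally the incoherent sum of x/y/z dipole orientations; evaluated on a
  5×5 sub-lenslet grid and reduced with a pitch-wide 2D Hamming window to a
  lenslet-periodic kernel `H(z)`.
* RL deconvolution `x_{k+1} = (x_k / a) ⊙ Hᵀ(y ⊘ H x_k)` with `a = Hᵀ1`, and
  the multiplicative total-variation variant
  `x_{k+1} = x_k ⊘ (a − λ div(∇x_k/|∇x_k|)) ⊙ Hᵀ(y ⊘ H x_k)` (λ = 0.01).
* Quantification: `ΔF/F = (F − F₀)/(F₀ − F_d)`; activation maps (temporal
  variance of ΔF/F); top-2-percentile ROIs with dilation-XOR contours;
  `tSNR = peak ΔF/F / baseline σ`; decay times and spatial confinement as
  FWHM with interpolated half-maximum crossings; Wilcoxon / Friedman paired
  statistics with median [IQR] summaries.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

`examples/04_single_cell_transients.py` simulates a 10-s, 20-frames/s
light-field movie of a dye-filled neuron (10-µm soma plus dendrite, five
stimulus pulses at 0.5 Hz, Poisson + read noise, constant dark signal),
reconstructs it both ways and extracts matched-ROI transient metrics:

```
building PSF and simulating 200 frames ...
reconstructing (refocusing + 3-iteration RL) ...
ROI: top-2% activation pixels at plane z = +0 um (5 px)
refocused       peak   8.4%  noise 0.25%  tSNR  33.1  decay 223 ms
deconvolved(3)  peak  12.3%  noise 0.56%  tSNR  21.9  decay 220 ms

Deconvolution concentrates the transient light (higher peak dF/F) but
also amplifies noise; the transient decay time is unchanged.
```

The other examples cover the design arithmetic (`01`), bead refocusing and
deconvolution FWHMs (`02`, `03`) and depth localization of bulk-labeled
somata (`05`). A thin CLI wraps the same functions:
`lfcalcium simulate | psf | refocus | deconv | analyze | compare`.

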