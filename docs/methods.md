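# Methods

This note records the models implemented in `lfcalcium`, their assumptions,
the parameter defaults and why they were chosen, and the numerical decisions
that affect results.

## Optical model and coordinate conventions

The instrument model is a widefield epifluorescence microscope (magnification
`M`, numerical aperture `NA`, immersion index `n`) with a microlens array
(pitch `p`, f-number `N_mla`) at the native image plane and the MLA focal
plane relayed 1:1 onto the camera. Two configurations are bundled:

* `PAPER_CONFIG` — 25×/NA 1.0 water immersion (`n = 1.33`), 125-µm f/10 MLA,
  6.5-µm pixels, 664-nm emission, 20 frames/s. Gives Nu = 16 and 5-µm native
  resolution. The immersion index is not adjustable by the vendor data we
  model, so `n = 1.33` (water) is fixed as a config field.
* `SYNTH_CONFIG` — the desk-scale instrument used by the phantoms:
  25×/NA 0.8, 90-µm f/16 MLA, 10-µm pixels. Gives Nu = 9, 3.6-µm native
  resolution, and an f-number-matched MLA (image-side working f-number
  `M/2NA ≈ 15.6`), so subimages fill the pitch.

Conventions shared by all modules: `(x, y)` are 0-based lenslet indices;
`(u, v)` are signed angular offsets centred on the lenslet axis (in-aperture
samples form a disk of diameter Nu); `z` is signed µm relative to the native
focal plane. The Sparrow prefactor is 0.47 (incoherent two-point criterion),
and Nu uses `floor` — a partially resolvable spot does not add a usable
angular sample.

## Depth calibration of synthetic refocusing

Shift-and-add refocusing needs a mapping between the refocus parameter α and
physical depth. We derive it from the lenslet geometry rather than from a
bead calibration run: a sensor pixel at angular index `u` sits `u·p/Nu` from
the lenslet axis and therefore collects rays at image-side angle
`tan θ' = u·p/(Nu·f_mla)`. Referring angles and lengths to the sample (angles
scale by `M`, transverse lengths by `1/M`, axial distances by `n`), a source
defocused by `z` µm appears in view `u` displaced by `c·z·u` lenslets with

    c = M² / (n · Nu · N_mla · p)     [1/µm],

so `1 − 1/α(z) = c·z`, valid for `|z| < 1/c` (≈ 27.6 µm for `SYNTH_CONFIG`,
≈ 42.5 µm for `PAPER_CONFIG`). The same constant falls out of the wave-optics
PSF: computed pattern centroids follow `c·z·u` to within half a percent,
which makes refocusing and deconvolution mutually consistent without any
fitted constant. The slope is exposed through the config so other hardware
calibrations can override it.

Fractional view shifts use bilinear interpolation with true zero padding
(`grid-constant`); an α ≤ 0 or out-of-range depth is a hard error rather than
an extrapolation.

## Light-field PSF

The PSF of a point emitter at depth `z` is computed with scalar Fourier
optics: pupil field with aplanatic `sqrt(cos θ)` apodization and the sample-
side defocus phase `exp(i k₀ n z cos θ_s)`; inverse FFT to the image plane;
multiplication by the periodic quadratic phase of the MLA; angular-spectrum
propagation over one lenslet focal length; squared modulus at the sensor.
Emitter orientation enters as a pupil apodization per dipole axis
(`x/y`: `sqrt(cos²θ cos²φ + sin²φ)` and its rotation, `z`: `sin θ`), summed
incoherently with equal weights (`model="dipole3"`); `model="scalar"` skips
the orientation sum and is the default for the heavy simulation studies,
where the two models differ only in fine pattern weighting (normalized
patterns correlate > 0.9) and none of the reported trends depend on the
choice.

Because the response depends on the emitter's position within a lenslet,
patterns are evaluated on a 5×5 grid of sub-lenslet offsets and reduced to a
single kernel per depth by averaging with a 2D Hamming window exactly one
pitch wide, centred on the lenslet axis (weights normalized to 1). The
reduced kernel set `H(z)[u, v, dx, dy]` is treated as periodic in the lenslet
lattice, so forward projection is a per-depth 2D convolution summed over
depth and the adjoint is the matching correlation — both implemented with
zero-padded FFTs and verified against the inner-product identity
`⟨Hx, y⟩ = ⟨x, Hᵀy⟩` to machine precision.

Numerical settings: lateral sampling one voxel per lenslet (native
resolution; lateral oversampling is a config extension we do not enable);
wave-model oversampling 3× the angular pixel pitch (odd, so lenslet blocks
bin exactly); kernel support 15 lenslets (covers the largest view shift on
the ±20-µm grid with margin); kernel values below `1e-4` of the per-depth
peak truncated; each depth kernel normalized to unit total energy inside the
angular aperture, which makes the RL sensitivity `a = Hᵀ1 ≈ 1` for interior
voxels. The default depth grid is −20…+20 µm in 1-µm steps (41 planes),
inside the refocusable range of the desk configuration.

## Deconvolution

Richardson–Lucy is implemented in its multiplicative form
`x_{k+1} = (x_k / a) ⊙ Hᵀ(y ⊘ H x_k)`, where `a` is read as the per-voxel
sensitivity `Hᵀ1` — the only dimensionally consistent interpretation of the
update — and the elementwise quotient is guarded by `ε = 1e−12·max(y)`.
Initialization is a uniform positive volume at the mean in-aperture count
(the RL convention; it also keeps the zero-stays-zero multiplicative
invariant inert). Deconvolution is deliberately stopped early: iteration
number is the effective regularizer, with 3 iterations the working default
(best lateral confinement at high tSNR) and 21 the upper end of the sweep.

The TV-regularized variant uses the standard multiplicative form
`x_{k+1} = x_k ⊘ (a − λ·div(∇x_k/|∇x_k|)) ⊙ Hᵀ(y ⊘ H x_k)` with λ = 0.01,
forward-difference gradient, backward-difference divergence (an exact
negative-adjoint pair, unit-tested), gradient magnitudes floored at `1e−8`,
and a hard error if the regularized denominator goes non-positive. At
λ = 0.01 the prior is weak by design: it lowers the total variation of the
reconstructions while changing extracted transient metrics by well under 5%.

## Quantification

`ΔF/F = (F − F₀)/(F₀ − F_d)`, reported in percent, with `F₀` the mean over a
20-sample (1-s) pre-stimulus window and `F_d` the constant camera dark
signal. Activation maps are per-voxel temporal variances of ΔF/F
(population variance — the map only ranks voxels); baseline noise is the
sample standard deviation (ddof = 1) of baseline ΔF/F; `tSNR = peak/noise`,
with the peak searched from the first stimulus onset to the end of the
record. ROIs are the voxels at or above the linear-interpolation 98th
percentile of the map (ties included), per plane by default; display
contours are `dilate(mask) XOR mask` with a 3×3 structuring element. The
"plane of best focus" is defined operationally as the z-plane with the
largest total activation. All FWHMs (transient decay, spatial profiles) use
linear interpolation of the half-maximum crossings walking outward from the
peak, with a `field_limited` flag when a profile never falls below half
maximum inside the field.

Depth localization uses two additions on top of the plain activation map,
both of which matter at desk scale:

* `signal_std_map` subtracts the baseline-window variance (an unbiased
  estimate of the shot/read-noise floor of ΔF/F) before taking the square
  root. Without this, the uniform noise floor across all z-planes drags any
  centre-of-mass estimate toward the middle of the reconstructed range.
* `depth_center_of_mass` computes the CoM iteratively over a window
  (half-width 12 µm) centred on the running estimate, subtracting the
  in-window minimum. This is standard iterative centroiding from particle
  localization; it removes the skew caused by truncating the broad axial
  response (refocused axial FWHM ≈ 28 µm) at the edges of a ±20-µm grid.

Paired statistics go through scipy (`wilcoxon` with the exact small-sample
null for n ≤ 25, `friedmanchisquare`), with median [IQR] summaries; the
degenerate all-differences-zero and all-ranks-tied cases return the
null-extreme statistic with p = 1 instead of raising.

## Synthetic scenes

The generator produces three scene families on a 15×15-lenslet, 41-plane,
1-µm-z grid: a 10-µm bead in clear medium; a single dye-filled neuron (10-µm
soma plus a 1.5-µm-radius dendrite climbing from the soma to +6 µm); and a
bulk-labeled field of 10-µm somata at distinct depths over a constant
background of at least 50% of soma brightness (bulk labeling produces raw
images too flat to segment, which is exactly why the activation-map path
exists). Geometry is rasterized with 3× supersampled partial-volume weights
(sphere mass accurate to 2%).

Calcium dynamics are instantaneous-rise, single-exponential-decay transients
multiplying each structure's brightness:
`F(t) = F₀·(1 + a·Σᵢ exp(−(t−tᵢ)/τ)·step(t−tᵢ))`, five pulses at 0.5 Hz from
t = 1 s, 200 frames at 20 Hz, `τ = 0.23/ln 2 ≈ 0.33 s` so the transient FWHM
is 0.23 s. Default amplitudes are 0.11 (soma) and 0.20 (dendrite,
backpropagating-AP regime). Structure brightness (3000 counts/voxel) was set
so that the refocused single-cell pipeline lands in a realistic operating
regime — baseline noise a few tenths of a percent and tSNR of a few tens.
The camera model applies Poisson shot noise to the expected counts, adds
Gaussian read noise (σ = 2) and a constant dark offset (100 counts), and
clips at zero; every stochastic step is driven by an explicit seed. The
matched widefield simulator blurs each plane with a Gaussian whose width
grows linearly with defocus (`σ(z) = hypot(σ_Sparrow, |z − z_focus|·NA/2n)`)
and sums planes, enabling like-for-like tSNR comparisons.

What the phantoms do **not** emulate: scattering (reconstruction assumes
ballistic photons), photobleaching, motion, dye-loading gradients, spatially
varying background, and camera fixed-pattern noise. Passing tests therefore
demonstrate correctness of the algorithms and the direction/shape of the
reconstruction trade-offs, not performance in scattering tissue.

## Problem sizes

The simulation studies run at desk scale, chosen so the full suite completes
in minutes on one CPU: 15×15 lenslets, Nu = 9, 41 depth planes, 200-frame
movies, scalar PSF model. The iteration sweep evaluates RL snapshots at
{1, 3, 8, 13, 21}; the confinement study at {3, 10, 21} on a single bead
frame. At this scale the *trends* — signal and noise ratios rising with
iteration number, tSNR falling below the refocused baseline, axial FWHM
shrinking monotonically, lateral FWHM plateauing by ~10 iterations, TV
changing metrics by < 5% — are stable across seeds, while the absolute
ratios depend on scene brightness and geometry and are smaller than on a
full-scale instrument (fewer angular samples and voxels mean less contrast
gain to realize).

## Known limitations

* Depth estimates of sources within ≈ 5 µm of the native plane are biased
  toward it: sub-lenslet view shifts at small defocus are barely resolvable
  at native sampling, and both reconstructions pile such sources' energy at
  z = 0. Iterative centroiding reduces but does not remove the residual
  (~1 µm noiseless, larger under noise).
* The refocusable range `|z| < 1/c` is a hard limit of the α-parameterized
  shift-and-add; deconvolution has no such limit but its kernels are only
  computed on the configured grid.
* The dipole PSF is a scalar-per-orientation approximation, not a full
  vectorial Debye–Wolf integral; aberrations and index mismatch are not
  modeled.
* Lenslet-grid rectification assumes a rigid lattice with small rotation;
  there is no per-lenslet distortion model.
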