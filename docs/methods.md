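# Methods

This note documents the models and numerical choices behind `algascan`: what
the forward simulator emulates, how the reconstruction is defined, and where
the design was genuinely open.

## Instrument forward model

A linear variable spectral bandpass filter (LVSBPF) is swept across the
intermediate image plane of an RGB video camera. The filter's passband is
modeled as a Gaussian in wavelength whose center wavelength (CWL) and FWHM
vary linearly with the fractional position `p ∈ [0, 1]` along the filter:
CWL from 400 to 700 nm, FWHM from 3 to 9 nm by default. A Gaussian is the
conventional smooth profile that is fully determined by a CWL and a FWHM;
thin-film filters have steeper skirts, but nothing downstream depends on the
skirt shape.

During a scan of `n` frames, image row `y` at frame `f` sees the filter
position `(f + s·y)/(n − 1)` clipped to [0, 1], where `s` is the row shift in
frames per row (default 0.2). The divisor `n − 1` makes a "full sweep" exact:
frame 0 sees one end of the filter and the last frame the other. The
per-pixel linear signal is a 1 nm-step quadrature of
illumination × reflectance × filter transmission × channel sensitivity,
scaled by a fixed exposure gain, plus additive Gaussian noise (default
sd 0.005 on the [0, 1] linear scale — a few percent of the grey-plate
signal), then encoded through the camera's forward gamma curve and quantized
to 8 bits. Shot noise and intra-frame motion blur are omitted by default
(an `exposure_blur` flag averages the filter position over one frame's
travel); noise is additive because no photon-budget data exists to fit a
shot-noise model.

**Channel sensitivities.** Consumer cameras do not publish their RGB
response curves, so the simulator uses two-sided generalized Gaussians
`S = 10^(−|Δλ/w₁₀|^q)` parameterized by the half-width `w₁₀` at which the
response falls to 10% of peak and a shape exponent `q` per side. The
defaults place the 10% crossings at the edges of each channel's usable
window — in particular the blue channel rises through 10% of its peak at
436 nm and the red channel falls through 10% at 642 nm, which are exactly
the two wavelength anchors the reconstruction's onset detector relies on.
The red channel's long side uses `q = 1.32` (a heavier shoulder than a
Gaussian) so its response only reaches the ~2.5% noise floor at the 660 nm
trim edge; with a pure Gaussian tail the last reconstructed bands would sit
below the sensor noise and the zero-clipping of noise would bias the grey
reference upward there.

**Exposure.** The gain is a fixed camera property (`auto_gain` sets it once
so a reflectance-0.5 target peaks at 95% of full scale under flat
illumination). It is deliberately *not* recomputed per scene, so doubling
the illumination doubles the linear signal — a property the tests check.

**Reference spectra.** The four built-in macroalgae classes are smooth
analytic reflectances: a sigmoidal red-rising baseline minus Gaussian
pigment-absorption dips. Brown classes dip at 445 and 641 nm
(chlorophyll-a) with lesser dips at 496 and 603 nm; red classes dip at 440
and 639 nm with species-shifted lesser dips (481–491, 598–603 nm), are
brighter overall, and are brightest in the red. Dip centers are placed
~1–2 nm red-ward of the target minima because a rising baseline shifts the
realized local minimum blue-ward; the shipped constants were verified
numerically to put the minima at the stated wavelengths. The two brown
classes differ only by a small overall level change concentrated in the red
(the realistic near-degenerate pair); class separability in the benchmark is
therefore dominated by that contrast.

**What the simulator does not emulate.** Spatial texture within an alga,
mixed pixels at patch borders, epiphyte contamination, water-column
attenuation, specular glints, lens aberrations, autofluorescence, and
stage-speed jitter. Passing tests show the *pipeline* is correct and the
classifier can exploit spectral shape at realistic noise; they do not show
field robustness to the effects above.

## Reconstruction

All steps run on the gamma-linearized stack.

1. **Gamma.** Measured (power, count) pairs per channel are projected onto
   the nearest non-decreasing sequence (isotonic regression) and
   interpolated with a monotone piecewise cubic (PCHIP); the inverse is
   tabulated numerically, with plateau counts inverted to the lowest power
   reaching them. Counts at the curve's ceiling are clipped to 1.0 and
   flagged in a saturation mask that propagates through de-shearing,
   summation (only over *active* channels) and band interpolation, and is
   excluded from the calibration reference. The simulated characterization
   ladder follows Malus's law (`power = sin²θ` for evenly spaced polarizer
   angles), which concentrates samples near extinction where a power-law
   tone curve is steepest; a linearly spaced ladder leaves the first knot
   interval so wide that inversion errors at low counts visibly bias the
   calibrated reflectance at the band edges.
2. **Shear.** The temporal traces of two grey-plate pixels in the same
   column are compared by *normalized* cross-correlation: the Pearson
   coefficient over the overlapping segment at every candidate integer lag,
   refined by a parabolic fit through the peak. (An unnormalized
   cross-correlation of mean-subtracted traces is biased toward zero lag:
   the subtracted baselines add a triangular term that tilts the flat-topped
   peak.) Lags from several columns are pooled into a least-squares line
   through the origin; the slope is the shear in frames/row.
3. **De-shearing.** Output frame `f'` at row `y` takes source frame
   `f' − round(slope·(y − reference_row))` — lower rows reach any filter
   position earlier, so their source frames lie earlier. Output frames whose
   sources fall outside the scan are dropped. Nearest-frame rounding keeps
   the data untouched (no temporal resampling).
4. **Onsets and wavelength map.** On the grey region of the de-sheared
   stack, the blue onset is the first frame whose blue-channel mean exceeds
   θ = 0.1 of that channel's maximum and the red onset the last frame above
   the same fraction of the red maximum (θ configurable; the choice of a
   threshold rule, and its value, are this package's decisions). The linear
   map λ = m·f + b is anchored at 436 nm (blue onset) and 642 nm (red
   onset) and reproduces both anchors exactly. The filter's finite bandwidth
   broadens the trace edges slightly outward, which stretches the fitted
   dispersion by ~1%; the resulting wavelength error stays below one output
   band spacing across the retained range.
5. **Trim, sum, interpolate.** The map is estimated *before* nm-trimming
   (the trim windows are expressed in nm, so the narrative order
   trim-then-map would be circular). Each de-sheared frame is monochromatic,
   so trimming reduces to a per-frame channel weight: a channel contributes
   only to frames whose wavelength lies in its window (R: 510–660,
   G: 465–620, B: 430–566 nm). The summed single-channel stack is linearly
   interpolated onto a uniform grid of 225 points on 435–659 nm (1 nm
   spacing). 435 and 699 nm are the hard validity limits for any
   user-supplied grid, but the *default* grid stops at 659 nm: the red trim
   window ends at 660 nm and the green at 620 nm, so no channel carries
   signal beyond 660 and bands there would be identically zero. 225 points
   are chosen so that factor-5 binning yields exactly 45 output bands.
6. **Calibration, denoising, binning.** Reflectance is
   `R = 0.1 · I / Ī_grey(b)` with the band-wise mean over an unsaturated
   grey-plate region; the grey region then reads 0.1 exactly by
   construction, and any positive illumination spectrum cancels. A
   Savitzky–Golay filter (order 2, window 9) runs along the band axis only —
   it preserves constants and quadratics exactly — and factor-5 binning
   averages valid members per group (a binned band is valid if at least one
   member is).

## Classifier

Per-pixel 45-band reflectance vectors feed a 1-D CNN:
conv(32, k3, s1, p1) → ReLU → maxpool(2,2) → dropout 0.25 →
conv(64, k3, s1, p1) → ReLU → maxpool(2,2) → dropout 0.25 → flatten(704) →
dense(128) → ReLU → dense(128) → ReLU → linear(5). ReLU between the dense
layers is an assumption (a linear cascade of two dense layers would be
redundant). Training uses softmax cross-entropy, Adam at its standard
defaults (lr 10⁻³), batch size 256, a stratified 90/10 train/validation
split, equal class weights, and a fixed epoch count with exported loss
curves (no early stopping). The implementation is a small NumPy engine
(im2col convolution, argmax-tracked pooling, inverted dropout); weight
initialization, shuffling, and dropout masks all draw from one seeded
generator, so training is bit-reproducible, and backpropagation is verified
against central finite differences in the tests.

Evaluation counts per-class precision, recall, and F1 over annotated pixels
only; the macro average runs over the four macroalgae classes, excluding the
background, with classes absent from the ground truth reported as NA and
skipped.

## Problem sizes

The default simulated sensor is 128×160 px with 240 frames per sweep —
desk-scale while keeping the channel count inside the instrument's 70–350
range. The end-to-end benchmark uses 208×256 px scenes so each macroalgae
patch contributes ≈4,900 labeled pixels, and trains for 50 epochs; on these
noise-free-separable-but-for-the-brown-pair scenes the validation loss is
flat well before that, and the macro-F1 on a held-out scene is ≈0.99 with
the residual confusion confined to the two nearly identical brown classes.

## Known limitations

- The wavelength scale is anchored only at 436/642 nm; curvature in the
  stage speed or filter gradient would go undetected.
- Bands near the grid edges (below ~445 and above ~650 nm) have the lowest
  SNR; per-pixel reflectance there is noticeably noisier than mid-band.
- The annotation model is axis-aligned boxes with first-wins overlap
  resolution; no sub-pixel or polygon support.
- `estimate_row_shift` assumes the two probe pixels sit on the grey plate;
  a probe on a colored target biases the lag through its different spectral
  trace shape.
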