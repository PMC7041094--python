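# Methods

## Signal model

Chemiluminescent detection on membrane antibody arrays uses horseradish
peroxidase (HRP) bound, via the detection antibody, to the captured target
protein. HRP catalyzes the oxidation of luminol by H₂O₂; the emitted light
is proportional to the reaction rate. With H₂O₂ in excess the rate is first
order in luminol, so the luminol pool decays exponentially with rate
`a = k_r · C_E`, where `C_E` is the concentration of bound enzyme at a spot
and `k_r` the apparent rate constant of the simplified law
(default `1.4×10⁶ (M·s)⁻¹`). A CCD integrates the light over the exposure
time `t`; the reaction has already been running for the preparation time
`t₀` (reagent pipetted → first frame) when acquisition starts. The
cumulative flux of one spot is therefore

    L(t) = κ · exp(−a·t₀) · (1 − exp(−a·t)),      a = k_r · C_E

evaluated with `expm1` for numerical stability. `κ` bundles the initial
luminol concentration, photon yield, optics and detector gain; it is a
property of the image set, not of a spot. `t₀` (default 60 s) is a
user-supplied constant, not a fit parameter: it is known to the
experimenter far more precisely than the data could estimate it.

Two consequences of this law shape everything downstream:

* `L` is *not* monotone in `C_E` at fixed `t`: spots with very high enzyme
  load burn their luminol during `t₀` and appear *dimmer* at long exposures
  (amplitude turnover at `a ≈ 1/t₀`). High-`C_E` reference spots are
  brightest on early frames and may vanish from late ones.
* At fixed `κ`, the least-squares loss in `a` is multimodal: beyond the
  turnover a second, high-rate branch produces small flat flux curves that
  can mimic noisy near-zero traces.

## Pipeline

`quantify()` (wrapped by `MembraneArrayModel.fit()`) runs:

1. **Alignment.** Iso-contours are extracted per frame at 60% of the frame
   maximum (marching squares; the frame is padded with its minimum so
   border-touching contours close). Contour-vertex centroids are candidate
   landmarks; initial guesses are the componentwise extremes
   G1=(min x, min y), G2=(min x, max y), G3=(max x, min y); the nearest
   candidate to each guess becomes an anchor. The triple is validated
   against the layout (side ratios relative to the longest side, within
   ±15%; corner angle, within ±10°; guess–anchor distance ≤ 10% of the
   image diagonal — all configurable per layout). The affine map taking the
   anchors to their canonical positions is applied with bilinear
   interpolation and the frame trimmed so every spot is centered in its
   `spot_box` square (default 30 px).

   Two guards supplement the three checks, which cannot detect an anchor
   that slipped by exactly one grid pitch (that changes the triangle by
   only a few percent): frames whose anchors deviate from the across-frame
   median anchor position by more than `spot_box/3` are discarded, as are
   frames whose contour level does not clear the background distribution
   (median + 10·MAD). Discarded frames borrow the anchors of the nearest
   valid exposure — early frames are typically too dim, late frames can
   lose fast reference spots to luminol depletion.

2. **Background.** Each frame's pixels are histogrammed into 2048 equal
   bins over [0, 1]; the highest bin (excluding the top bin, which collects
   saturated pixels — reaction light by definition) gives the first guess
   `b_G`; values above `2·b_G` are discarded; a normal distribution fitted
   to the retained sample gives the background level `b` and spread `σ_b`.
   The normal fit is a least-squares Gaussian fit to the retained histogram
   bins rather than the plain sample mean/SD: spot skirts below the cutoff
   form a small right tail that biases the mean by ~1% of `b` on densely
   spotted membranes, while the histogram peak is barely moved. Degenerate
   histograms (fewer than four occupied bins, or over half the retained
   mass in one bin) fall back to sample moments. Across the exposure series
   both `b(t)` and `σ_b(t)` grow linearly; `background_series` fits both
   lines by ordinary least squares. Background estimation runs on the
   *unaligned* frames — it is a histogram-only statistic and warping would
   only add interpolation bias.

3. **Traces.** For every grid spot and frame, the mean gray value over its
   spot square minus that frame's `b`. Negative values are kept so noise
   stays zero-mean. A spot-frame is excluded from fitting once any pixel of
   the box sits at the sensor ceiling (threshold 0.1% of box pixels ≥
   1 − 10⁻⁴): clipping biases the cumulative signal from the first clipped
   pixel onward.

4. **Shared prefactor.** The ten brightest spots (by final-exposure trace
   value) enter a joint bounded nonlinear least-squares fit over
   (κ, a₁…a₁₀), equal frame weights, κ > 0, aᵢ ≥ 0. Start values come from
   per-trace scans (below); `scipy.optimize.least_squares` (trf) with tight
   tolerances does the minimization.

5. **Per-spot concentration.** With κ fixed, each spot's rate is fitted by
   scanning a dense logarithmic grid of candidate rates (320 points,
   10⁻⁸–10 s⁻¹), refining every local minimum of the scanned loss, and
   selecting among branch minima: candidates whose cost lies within a
   3σ χ²-scale band of the best are considered indistinguishable and the
   *smallest* rate is reported, with the zero-rate model always a
   candidate. This prevents blank or noise-only traces from landing on the
   spurious high-rate branch. `C_E = a / k_r`, reported in mol/L —
   semiquantitative (κ absorbs unknown gains) but comparable within and
   across membranes sharing a setup.

6. **Self-referencing background refinement.** `b` is subtracted
   frame-wide, so any residual error in it appears identically in every
   spot's trace. After each fit pass the across-spot *median* of the model
   residuals per frame estimates that common mode; traces are corrected and
   the fit repeated (≤ 8 iterations, stopping when the correction falls
   below 5×10⁻⁷ gray). On densely spotted synthetic membranes this removes
   a κ bias of several percent that the histogram estimator's residual
   skirt sensitivity would otherwise cause; on dark membranes the first
   correction is negligible and the loop exits immediately.
   `refine_iters=0` disables the refinement.

   The refinement matters because κ and the bright-set rates are nearly
   collinear (the ten brightest spots cluster near the turnover), so a
   frame-common trace tilt of 1% of `b` moves κ by ~2.7% and post-turnover
   `C_E` values by up to ~7× the κ error.

Analyte values are means over duplicate spots. Reports (json/csv lossless;
xlsx/LaTeX at 3 significant digits with a top-signal chart and the aligned
membrane image as an alignment check) carry dataset/membrane names and the
package version. Fallback modes for stacks without exposure metadata: raw
per-frame spot averages (with `b` exported alongside), local-background
ratios against a grayscale opening with a disc of 1.5·`spot_box` diameter,
and the OLS slope of spot average against `b` ("correlation" mode; the
Pearson r is reported alongside, but the slope is used for ranking because
a magnitude, not a goodness measure, is needed).

## Synthetic data generator

`generate_stack` is the forward model used by the whole test suite:

* **Spots**: isotropic Gaussians truncated at their spot box, normalized so
  the box mean equals `L(t)` exactly — recovery targets are then
  profile-independent. Default width σ = 4.2 px (FWHM ≈ 10 px on a 30 px
  pitch, typical dot-blot geometry). Reference spots get the largest
  `C_E` (2×10⁻⁸ M); analytes are log-spaced over 10⁻¹⁰–10⁻⁸ M and assigned
  to spots in seeded random order.
* **Background**: `b(t) = 0.01 + 10⁻⁴·t`, `σ_b(t) = 0.002 + 1.33×10⁻⁵·t`
  gray units — additive Gaussian pixel noise whose spread reaches 1% of
  the dynamic range at the longest default exposure (600 s). No Poisson
  shot noise or fixed-pattern effects.
* **Geometry**: the membrane canvas carries a 120 px dark margin (the
  recording tray visible in real acquisitions; it anchors the histogram
  background estimate), and is misaligned by default by a 2° rotation plus
  a (4, 7) px translation, applied to the signal in the membrane frame;
  background light and sensor noise live in the camera frame and are added
  afterwards. Frames are clipped to [0, 1]; saturation is thereby realistic
  (with κ = 1 the mid-range spots clip at long exposures) and exercises the
  saturated-frame exclusion.
* **Exposures**: 20 geometric times from 5 to 600 s — dense early frames
  resolve fast-decaying spots, late frames pin the asymptote.

Same seed → bit-identical stack. What the generator does *not* emulate —
spatially varying background surfaces, non-Gaussian spot shapes, bleed
between neighboring spots, camera PSF tails, drift during one exposure —
bounds what passing tests show about real data: they validate the
estimation machinery under the stated model, not the model's fidelity to
any particular imager.

## Verification conditions

The acceptance checks (tests and `scripts/acceptance.py`) use these
constructions, chosen once on physical grounds:

* **Recovery** runs the defaults above with no misalignment (geometric
  robustness is a separate check) over seeded replicates (100 in the test
  suite, 40 in the acceptance script) and reports 95th-percentile errors
  over analyte spots with best-frame trace SNR ≥ 10; reference landmarks
  are controls, not analytes, and their `C_E` lies outside the analyte
  range.
* **Gain invariance** needs the background estimator to be exactly linear
  in the detector gain, which a binned histogram only achieves when the
  retained pixel set cannot change under scaling: the check uses a
  noiseless stack whose constant background (0.04) exceeds half the maximum
  signal (κ = 0.03, wide σ = 12 px spots), so the `2·b_G` cutoff retains
  every pixel at every scale factor.
* **Alignment tolerance** uses κ = 0.1 (no sensor clipping, so the
  comparison is purely geometric) with small constant noise σ = 0.002:
  noiseless histograms are degenerate, while the default growing noise
  makes dim-spot differences noise-dominated rather than
  geometry-dominated. Post-alignment anchor error is measured as the
  background-subtracted intensity centroid of each reference box against
  its canonical center on the early half of the stack.
* **Mode consistency** uses κ = 0.1 and `C_E` in 10⁻¹⁰–10⁻⁹ M, the
  quasi-linear regime: correlation-mode slopes measure growth and invert
  their ranking once a spot's luminol plateaus, so rank agreement with the
  kinetic readout is only expected away from both the sensor ceiling and
  the kinetic plateau.

## Limitations

* The background is a single scalar per frame; vignetting or gradients are
  not modeled.
* Quantification is relative: absolute `C_E` values inherit the
  uncertainty of `k_r` and the non-identifiability inside κ.
* Spots wider than the structuring element leak into the morphological
  background of `local_bg` mode (inherent to grayscale opening).
* The anchor consistency guard assumes the majority of frames yield correct
  anchors; a stack in which most frames mis-detect would not be repaired.
* Membranes whose true layout deviates from the configured grid (swollen
  or stretched membranes needing non-affine warps) are out of scope.
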