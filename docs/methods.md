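# Methods

`parmap` quantifies how the dosage of PAR polarity proteins maps onto
polarity and asymmetric-division phenotypes in the *C. elegans* zygote. It
implements the full measurement chain — autofluorescence correction,
cortical quantitation, polarity indices, division phenotypes,
dose-response statistics — together with a synthetic-embryo generator
that provides analytic ground truth for every quantity the chain
estimates. This note records the models, the parameters that matter, the
numerical choices, and the known limits.

## The measurement model

### Cross-membrane intensity profile

A linescan perpendicular to the cell cortex (coordinate `x` in µm,
increasing from outside to inside) is modelled as

```
I(x) = A exp(-(x-c)² / 2w_g²) + (C/2) (1 + erf((x-c) / w_e√2)) + O
```

— a Gaussian membrane ridge of amplitude `A` (the membrane concentration
readout) riding on an error-function cytoplasmic step of plateau `C`,
sharing a centre `c` because the ridge sits on the cell boundary. `w_g`
is the ridge SD (PSF-scale, default 0.5 µm), `w_e` the edge width, `O` a
flat offset.

### Cortical quantitation chain

1. **Segmentation** (`cortex.segment_embryo`): Otsu threshold on a
   Gaussian-blurred copy (σ = 2 px), hole filling, largest object
   (≥ 2,000 px²); marching-squares subpixel contour of the smoothed mask;
   the contour is then refined onto the membrane midline by fitting the
   profile model along inward normals — one global pass, then up to three
   per-position passes (converged when the largest shift is < 0.02 µm).
   Refinement is required, not cosmetic: a raw threshold contour sits on
   the outer membrane flank, ~0.5–1 µm off, a 3–5% perimeter error.
   The anterior pole (s = 0) is the long-axis end whose adjacent 20% arc
   is brighter in a designated anterior-marker channel; an explicit
   anchor point may be supplied instead, and with neither the choice is
   deterministic but flagged.
2. **Straightening** (`cortex.straighten_cortex`): a 50 px (12.8 µm) band
   is sampled along inward normals at 1 px arc spacing, then a 20 px
   (5.1 µm) circular rolling average is applied along the perimeter.
   Sampling is bicubic; bilinear is available but its implicit
   triangle-kernel smoothing broadens the ~2 px ridge and biases fitted
   amplitudes low by ~2%.
3. **Decomposition** (`cortex.fit_membrane_profiles`): widths and offset
   are shared across positions; per position the centre is found by
   bounded golden-section search with an inner non-negative least-squares
   solve for (A, C). Shared parameters are estimated by joint variable
   projection over a subset of rows — fitting them on the
   position-averaged profile is biased whenever the centre c(s) wanders
   along the perimeter, because the averaged step is then artificially
   broadened.

### Centre registration across channels

Where the ridge is weak the model is nearly degenerate: shifting the
centre by δc and adding a Gaussian of amplitude `C φ'(0) δc ≈ 40 δc`
per µm (at C = 50, w = 0.5 µm) reproduces the profile to first order. A
~0.02 µm systematic centre error therefore inflates a weak amplitude by
~1 unit — fatal when the true amplitude is ~5 (the opposite-pole plateau
of a strongly polarized embryo). Because aPAR and pPAR proteins decorate
the *same* membrane with complementary domains, their summed channel has
a strong ridge around the entire perimeter; the pipeline fits the sum
first and pins each channel's centre to that registration
(`fixed_center=`). Single-channel fitting remains available and is
accurate wherever the channel's own ridge is strong.

### Regional metrics

Cortical levels are means of A(s) over the pole-centred 33% perimeter
arcs (anterior arc for aPARs, posterior for pPARs). Total dosage is the
whole-embryo mean intensity in the 1 px-eroded mask, divided by the
control-cohort mean (controls ≈ 1). The domain boundary is the first
half-max crossing of A(s) walking from a pole, linearly interpolated.

## Polarity indices

The composite asymmetry index combines both protein classes,
concentrations normalized to wild-type peaks (cohort mean of per-embryo
maxima of A(s)):

```
ASI = ((A_A − A_P) − (P_A − P_P)) / (A_A + A_P + P_A + P_P)
```

with A/P subscripts denoting anterior/posterior pole arcs of the aPAR
(A·) and pPAR (P·) proteins. It is 1 for perfect complementary polarity,
0 for uniform, antisymmetric under axis inversion, and invariant to
common rescaling. Single-protein indices use semicircle ROI means,
`(A−P)/(A+P)` for anterior-enriched and `(P−A)/(A+P)` for
posterior-enriched proteins, so correct polarity is positive. The
composite-ASI inputs use the 33% pole arcs for consistency with the
cortical means; the averaging region is a free choice here, stated in
config.

The domain-count classifier thresholds a closed membrane:cytoplasm ratio
trace: arcs with r > θ_high (default 1.5), merged across the s = 0 wrap
and at least 5% of the perimeter long, count as domains (1 = monopolar,
≥2 = bipolar); no arcs is `no_domains` below θ_low (1.2) and `unclear`
between. These thresholds are free parameters of an automated proxy for
what is, in practice, human scoring.

## Division phenotypes

Size asymmetry is AB area over whole-embryo area on the midplane.
Asynchrony is the signed furrow lag `t_P1 − t_AB` (~120 s in wild type).
Oscillation magnitude σ is the population SD of the pole's off-axis
displacement y from prometaphase to telophase (population vs sample
normalization is immaterial at the ≥ 30 frames typical here). Severing
velocities smooth x and y with a 10-frame (1 s at 10 fps) moving
average, measure Euclidean displacement over rolling 1 s windows, and
report the maximum per pole plus ΔV = v_max(P) − v_max(A). Event frames
(prometaphase, anaphase onset, telophase, furrows) are inputs, mirroring
manual annotation; there is no automatic mitotic staging.

## Dose-response statistics

* **Compensation fraction** `(x_het_null − x_het_wt)/(x_hom − x_het_wt)`:
  0 = none, 1 = full; values outside [0, 1] are kept and flagged;
  per-genotype SEMs propagate to a delta-method 95% CI.
* **LOWESS** (`doseresponse.lowess_bootstrap`): local *linear* fits with
  tricube weights over the `span`-fraction nearest neighbours, evaluated
  on a 100-point grid, with percentile 95% bands from case-resampling
  bootstrap (n_boot = 1000, seeded). Default span 0.3: with span 0.5 the
  smoothing bias on a Hill transition with K = 0.5, n = 6 reaches ~0.07
  sup-norm, washing out exactly the steep region of interest; 0.3 keeps
  it under 0.05 while remaining stable at n ≈ 200. A flat-kernel option
  exists (span 1 + flat kernel ≡ ordinary least squares) as a
  correctness hook. The steepest point of a fitted trend is read from a
  Savitzky–Golay first derivative (quadratic, 15 grid points), which is
  robust to grid-scale wiggle.
* **Gaussian-window variance** (`doseresponse.gaussian_window_stats`):
  at each window centre, weights `w_i = exp(−(x_i−x₀)²/2h²)`; the
  Σw-normalized weighted variance of the phenotype is plotted against the
  weighted mean dosage, with bootstrap CIs. The half-width h = 0.1 is
  interpreted as the Gaussian σ; a half-of-FWHM interpretation is a flag
  away. No effective-sample-size correction is applied to the weighted
  variance (the plain Σw form). Under a steep dose-response with
  constant measurement noise the variance profile peaks where the curve
  is steepest — near 50% dosage for the default Hill map.

## The synthetic-embryo generator

`synthetic.render_embryo` draws an elliptical midplane embryo
(semi-axes 25 × 15 µm, pixel scale 0.256 µm/px — back-computed from a
50 px ≡ 12.8 µm linescan band) with, per protein, a membrane ridge whose
amplitude follows a logistic plateau model in perimeter coordinate and a
cytoplasmic erf step, plus an autofluorescence component `af_mean +
af_gradient·(x/a)` inside the embryo that bleeds into the protein
channels with factor `bleed_factor`, a flat camera offset, and additive
Gaussian read noise (a Poisson option is deliberately absent to keep
test determinism). The plateau transition `expit(4k(s_b − u))` with
sharpness k = 20 has a 10–90% width of ~1.1/k ≈ 5% of the perimeter.
Distances to the boundary are exact Euclidean distances to a dense
boundary polygon (KD-tree), so cross-membrane profiles along true
normals equal the 1-D model by construction.

Rundown cohorts (`simulate_rundown_cohort`) draw dosages uniformly on
[0, 1] and map them through Hill phenotype curves
`p_min + (p_wt − p_min)·dⁿ/(dⁿ + Kⁿ)` with K = 0.5 (inflection near 50%
depletion) and n = 6, plus additive measurement noise. The bimodal
asymmetry regime inside dosage window [0.25, 0.75]: the probability of
retaining near-wild-type asymmetry (ASI ≈ 0.95) falls linearly from 1 at
the window top to 0 at the bottom; non-retaining embryos get an ASI
reduced linearly with dosage (≤ 0.7), so the two populations straddle
the 0.9 / 0.75 labeling thresholds. Spindle tracks are sinusoids
`y = a sin(2πft)` plus drift and noise (population SD of a whole-period
sinusoid is a/√2 — the oracle for σ). Two-cell masks split the ellipse
by the transverse chord whose pixel-counted AB fraction best matches the
target; division events are placed 120 s apart by default.

What the generator does **not** emulate: membrane ruffling and
non-elliptical shapes, intracellular structure (nuclei, granules —
the mem:cyt cytoplasm ROI exclusion is exercised only through the API),
photobleaching, depth-dependent blur, spatially correlated (granular)
autofluorescence, or cortical flows. Passing tests therefore demonstrate
correctness of the measurement chain under its stated model, not
robustness to every real-microscopy artifact.

Embryo-to-embryo variance at fixed dosage is not reported in the source
material; synthetic noise magnitudes (read noise SD 2 at plateau 50–100,
ASI noise SD 0.02) are free, chosen once as plausible for spinning-disk
confocal data.

## Autofluorescence correction

GFP-channel autofluorescence is estimated from a red-shifted channel via
a line `green = m·AF + b` fitted on GFP-negative control embryos —
pixel-pooled (deterministically strided to ≤ 10⁵ samples) or on
per-embryo means — and subtracted pixelwise or as a scalar per embryo.
Pixel-mode regression on a noisy AF channel is attenuated by the
classical errors-in-variables factor `var(AF_true)/(var(AF_true) +
var(noise))` (~4% at the generator's defaults); embryo-mode means
average the noise away and are unbiased, which is why whole-embryo
quantitation uses embryo mode. Corrected intensities may be negative and
are never clipped. mNG/mCherry channels use flat background
subtraction measured on unlabeled embryos. Local (empty-field)
background subtraction is optional and off by default.

## Numerical choices and degenerate inputs

* Profile-fit bounds: c within ±2 µm of the global centre, widths in
  [0.2, 2] µm, optimizer tolerances 1e-8 (global), 1e-4 µm (centre
  search); non-convergent positions are flagged NaN, > 20% flagged is an
  error.
* For step-only profiles (no ridge) the amplitude is identifiable only
  up to the centre degeneracy; noiseless fits return ≲ 0.5% of the
  plateau, and the noise floor on Â is amplified one to two orders of
  magnitude relative to the pixel noise. Cross-channel registration (above) is the remedy when a
  bright shared-membrane channel exists.
* Uniform profiles have no half-max crossing; `domain_boundary` returns
  NaN with a `no_boundary` flag rather than guessing.
* Bootstrap bands are percentile intervals, clipped to bracket the point
  estimate; identical seeds reproduce bands bit-for-bit.
* All randomness flows through `numpy.random.default_rng(seed)`; specs
  carry their seed, outputs record it.

## Problem sizes

The verification runs use desk-scale problems: 20–28 rendered embryos
for the image round trip, 100 profile positions for fit recovery,
cohorts of 200 for dose-response properties, 10-embryo pipelines for
determinism. These sizes put Monte-Carlo error well below the asserted
tolerances while keeping a full run in minutes on one CPU.

## Known limitations

* Segmentation assumes a single bright convex-ish embryo; touching
  embryos or border-clipped embryos are flagged, not resolved.
* The cortical chain quantifies single midplane snapshots; there is no
  time-lapse tracking or bleach correction.
* The domain-count classifier is a thresholding proxy with free
  parameters; it reproduces clean synthetic truth but is not a
  replacement for expert scoring near threshold.
* Composite-ASI pole concentrations use 33% pole arcs; if the intended
  averaging region was the semicircles, absolute ASI values shift
  slightly (the qualitative behaviour does not).
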