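# Methods

`sacbias` analyses why human saccade directions are biased toward the
horizontal, and how that bias splits into an image-driven (allocentric)
component and an observer-anchored (egocentric) component.  This note
documents the models, the estimators, the synthetic data they are tested
on, and the numerical choices behind both.

## Conventions

All positions are in degrees of visual angle.  Directions are measured
y-up: 0° = rightward, 90° = upward, counterclockwise positive.  Image-like
arrays are stored `[row, col]` with row 0 at the top; the single conversion
between the two frames lives in `sacbias.grids`.  Densities over direction
are probability per radian on a fixed 1° grid (360 points).

## Circular statistics

**Kernel density estimate.**  Direction distributions are smoothed with a
wrapped-Gaussian KDE: each sample contributes a Gaussian of standard
deviation σ = 0.1 rad (the single bandwidth used for every analysis),
summed over ±3 full turns (already exact to double precision for σ < 1).
The estimate is evaluated on the 1° grid and renormalized so its Riemann
sum is exactly 1; at the default bandwidth the correction is < 1e-12.
Weighted samples are supported so that density-like features (spectral
wedge profiles, orientation-likelihood vectors) pass through the same
operator as raw direction samples.

**Horizontal-bias metric.**  The mean of the smoothed density at 0° and
180°.  Two calibration points anchor its scale at σ = 0.1: a distribution
with directions exclusively at 0°/180° scores 2 (half a Gaussian peak,
0.5/(0.1·√(2π)) ≈ 1.995, at each horizontal pole), and the uniform circular
distribution scores 0.16 (= 1/2π to the printed precision).

**Rayleigh test.**  z = n·R̄² with R̄ the (weighted) mean resultant length
and n the effective sample size (Σw)²/Σw²; p from the standard large-sample
approximation exp(√(1+4n+4(n²−R²)) − (1+2n)), R = n·R̄.  Cross-checked
against an independent implementation in the test suite.

**Circular cross-correlation and reorientation.**  The angular displacement
between two direction distributions is the integer lag in (−180°, 180°]
maximizing the Pearson correlation of the mean-centered density vectors.
Near-ties matter here: a direction distribution obtained by sampling
fixations independently from a map is *exactly* 180°-periodic in
expectation (every A→B step has an equally likely B→A partner), so the true
lag and its 180° alias differ only by sampling noise.  Lags within
`tie_tol` (default 0.05 on the correlation scale) of the maximum are
grouped into contiguous clusters, each represented by its best lag, and the
smallest-|displacement| cluster wins — a conservative rule that biases
toward "no reorientation" and resolves the alias the same way an exact tie
is resolved.  `tie_tol=0` gives the strict argmax.

The reorientation index for a ±30°-tilt pair of displacements is
((−d₋₃₀) + d₊₃₀) / 2 / 30: 0 means the direction distribution ignored the
image tilt (purely egocentric), 1 means it rotated fully with the image
(purely allocentric).  Values are not clamped.

## Eye-movement preprocessing

Blinks and artifacts appear as non-finite samples; a margin of
`blink_pad_ms` (default 50 ms) around each run is also invalidated to
remove lid transients.  Saccades are detected with the Engbert–Kliegl
velocity-threshold scheme: velocity from a centered moving-window
differentiator (window 5 samples; for window 2m+1,
v_n = Σⱼ(x_{n+j}−x_{n−j}) / (m(m+1)Δt)), per-axis robust SD
σ = √(median(v²) − median(v)²), and an elliptic criterion
(v_x/λσ_x)² + (v_y/λσ_y)² > 1.  λ defaults to 8 (250 Hz video tracking)
with a λ = 15 preset (200 Hz dual-Purkinje).  Candidate runs shorter than
`min_duration_ms` (6 ms) are dropped, runs closer than `merge_gap_ms`
(20 ms) merged, and runs touching invalid samples discarded.  The exact
published variants of this detector differ in such bookkeeping details;
ours are config-exposed rather than hidden.

## Image orientation features

Three per-image features quantify orientation anisotropy; all three are
reduced to the same horizontal-bias metric through the shared KDE, so their
scales are directly comparable with the saccade metric.

1. **Spectral profile.**  The image mean is removed, the image is
   Hann-windowed (and the residual mean removed — a constant image maps to
   exactly zero), and the FFT amplitude is averaged inside ring × wedge
   masks: 10 log-spaced frequency annuli between `f_lo` and `f_hi`
   (presets 0.3–12.1 c/deg and 0.5–18.1 c/deg for the two source-corpus
   pixel densities) and 180 double-sided wedges, 1° apart and 10° wide.
   The profile is the mean over annuli, taken over populated wedge × band
   cells.  Wedge angle is reported as *contour* orientation (90° from the
   Fourier energy axis), so horizontal stripes peak at 0° and "horizontal"
   means the same thing in every feature; the raw Fourier-axis convention
   is available behind a flag.

   *Scale guidance:* on small synthetic images (128–256 px) the lowest DFT
   bins carry window leakage and the thinnest annulus samples different
   radii in different wedges, which biases a 1/f spectrum's profile.  The
   synthetic-scale analyses therefore raise the low band floor (f_lo = 0.8
   c/deg for white noise at 128 px; 1.5 c/deg for 1/f noise at 256 px).
   The dataset presets assume full-resolution corpora.

2. **Saliency-sampled saccades.**  Saliency maps are *inputs* (the study
   used a pretrained saliency network; any per-pixel fixation-probability
   map works).  2000 saccades are simulated as consecutive differences of
   i.i.d. fixations drawn from the map (pixel by inverse CDF plus uniform
   sub-pixel jitter, so zero-length saccades have measure zero), and the
   direction samples feed the bias metric.  `proxy_saliency_map` (local RMS
   luminance contrast) is a deliberately crude, orientation-neutral
   stand-in used by the white-noise control.

3. **Structural likelihood.**  A 360-element likelihood over the image's
   rotation angle.  The default proxy is the gradient-magnitude-weighted
   histogram of Sobel gradient orientations folded to 180° and duplicated;
   a trained orientation classifier plugs in through the same 360-vector
   contract.

## Saccade-targeting model

Target likelihood at pixel (x, y) given fixation (xₙ, yₙ):

    l(x, y) = l_ego(x−xₙ, y−yₙ)^α · l_allo(x, y)^β
    l_ego(x′, y′) = f(x′, y′) · v(θ) · s(x′, y′)

with f a planar Cauchy over the offset radius (scale a, degrees; favours
short saccades with a heavy tail of long ones), v a four-lobe von Mises
mixture over direction θ = atan2(y′, x′) (weights on the simplex; the
cardinal/horizontal bias), and s = 1 − exp(−r²/(2·0.9²)) a fixed penalty
suppressing sub-degree saccades.  The planar Cauchy is not integrable on
the infinite plane, so every map is normalized over the finite pixel grid.
Scanpaths are simulated by rebuilding the egocentric map at each fixation,
combining with the allocentric map, and sampling the next fixation
(inverse-CDF pixel + sub-pixel jitter).  α = 0 reduces exactly to i.i.d.
allocentric sampling (the map is then built once); β = 0 ignores scene
content.  The defaults α = 0.7, β = 1.3 are the compromise between upright
horizontal bias and tilt response found by a grid search over
{0.1, …, 2.0}².

**Fitting.**  The 13 free egocentric parameters (log a; four lobe means,
log-concentrations, softmax weights) are estimated by maximum likelihood
over observed saccade vectors.  The per-fixation grid normalization is
computed exactly: the unnormalized density is evaluated once per parameter
vector on an extended offset grid covering every possible pixel offset, and
each fixation's normalizing constant is an axis-aligned box sum obtained in
O(1) from a summed-area table.  Observed offsets are snapped to the nearest
pixel (the sampler's jitter makes this off by at most one pixel; an offset
landing on the zero-density center pixel is floored rather than rejected).
Optimization uses L-BFGS-B with numerical gradients from 8 seeded starts —
the first at the cardinal directions with equal weights, the rest perturbed
— returning the best.  Mixture labels carry no order; `match_lobes`
resolves the permutation against reference parameters.

Identifiability caveat: with broad lobes (κ ≲ 3 at 90° spacing) the mixture
sits on a likelihood ridge (κ trades off against weight and against the
neighbouring lobes), and the weak-lobe κ is only determined to about ±1.
Recovery of all 13 parameters at tight tolerances requires clearly
separated lobes, which the synthetic ground truth provides (below).

## Corpus-level statistics

- **Shuffle chance comparison.**  Per-image bias variance is compared with
  the variance after permuting the image–saccade correspondence
  (per-image counts preserved).  F = var(real)/var(chance), two-sided p at
  (n_images−1, n_shuffles·n_images−1) df; both ratio orientations are
  reported since a ratio far below 1 is as informative as one far above.
  The p-value is exactly calibrated for a single shuffle (the df then
  reduce to the classical pair) and the null suite runs it that way.
- **Regression.**  OLS of the saccade bias on the three feature biases with
  intercept, reported as an Estimate/SE/tStat/P table plus R²;
  rank-deficient designs are rejected.  Collinearity is addressed with a
  2-component PLS regression and VIP scores
  (VIPⱼ = √(p·Σₐ SSYₐ(wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ)); the mean squared VIP is 1 by
  construction.
- **Tilt experiment.**  Saliency maps are rotated ±30° about their center
  (zero-padded, renormalized) — the tilt is applied to the map, not by
  re-running a saliency model on a rotated image.  For each image and model
  variant (full, allocentric-only, egocentric-only) the tilted direction
  distributions are cross-correlated against the upright one and reduced to
  the reorientation index; Spearman's ρ compares each variant with the
  reference (human or human-proxy) across images.  Qualitative anchors:
  allocentric-only over-rotates (index ≈ 1), egocentric-only barely rotates
  (index ≈ 0), the full model lies between.
- **Amplitude bins.**  Saccades are split at pooled amplitude quartiles;
  the reorientation pipeline runs per (image, bin) and the amplitude trend
  is the least-squares slope of index on bin rank over per-image values — a
  fixed-effects approximation on per-image means, used in place of a mixed
  model whose random-effects structure would be arbitrary here.

## Synthetic data

Every input has a generator that is a pure function of its spec and seed:

- **Oriented noise images**: 1/f-amplitude noise whose Fourier amplitude is
  multiplied by 1 + strength·cos 2(φ−φ₀) (point symmetry preserved); the
  orientation parameter is the contour orientation of the dominant
  structure.  Strength 0 is isotropic; the bias metric rises monotonically
  with strength.
- **Saliency maps**: elongated Gaussian blobs along a line through the
  center (default horizontal), times an isotropic center-bias Gaussian.
  Blob peak heights ramp ±40% along the line because real scenes are not
  point-symmetric — a perfectly symmetric map would make the reorientation
  displacement ill-defined (see the tie discussion above).
- **Eye traces**: piecewise-stationary fixations joined by minimum-jerk
  saccade profiles whose duration is set so the peak velocity follows a
  saturating main sequence (Vp = 550·(1−e^{−A/5}) deg/s, Vp = 1.875·A/T),
  plus white position noise and injected non-finite blink runs; ground
  truth is returned alongside.
- **Model corpora**: scanpaths simulated from known parameters over
  upright and ±30°-tilted maps.  The canonical ground-truth parameters are
  a = 1.5°, cardinal lobes with κ = (8, 5, 8, 5) and
  w = (0.35, 0.15, 0.30, 0.20): sharply cardinal (as in human free
  viewing), asymmetric left/right and up/down, and well-separated enough
  that all mixture parameters are identifiable from 5000 saccades.

The default synthetic grid is 64 px at 0.35 deg/px (a 22.4° field,
comparable to free-viewing displays); spectral analyses use denser grids as
noted above.

What the generators do *not* emulate: photorealistic scene content,
tracker-specific noise spectra, torsion, head tilt, sequential dependencies
in fixation selection beyond the model's own, or the saliency network
itself.  Passing tests therefore demonstrate that the estimators and the
fitting machinery are correct and calibrated under the model's own
assumptions — not that the model explains human data; the study-level
human-data effect sizes require the original recordings and are out of
scope here.

## Problem sizes and determinism

Default analysis scales were chosen so the whole suite runs comfortably on
one CPU: 5000 saccades for parameter recovery (8 optimizer starts, ~15 s);
5–6 images × 3 tilts × 400–500 saccades for the tilt experiment; 100
white-noise images for the uniformity control; 500 seeds for the
null-calibration sweeps.  Every stochastic step takes an explicit seed or
`numpy.random.Generator`; identical seeds give bit-identical outputs.

## Known limitations

- Observed-offset snapping adds up to one pixel of quantization noise to
  the fit; negligible at the default grid but relevant if deg_per_px is
  made very coarse.
- The reorientation tie tolerance (0.05) is a noise-scale heuristic; for
  distributions estimated from very few saccades (≲100) the alias can still
  flip, and for genuinely near-symmetric processes the index is
  conservative by construction.
- The F-test p-value treats per-image bias metrics as approximately normal
  (CLT over per-image saccade counts); heavy-tailed per-image counts would
  need a permutation p instead.
- PLSR VIP uses 2 components by default; with 3 predictors this is the
  maximum meaningful choice short of saturation.
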