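# Methods

This note documents the models and procedures implemented in `hsimoist`, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical and design choices made where the problem left them open.

## The synthetic generator

### Generative model

Per sample *i* with moisture *m_i* (% wet basis), at wavelength λ (nm):

    a_i(λ) = baseline(λ) + fixed(λ) + g · m_i · Σ_k G(λ; c_k, w_k)
    r_i(λ) = s_i · exp(−a_i(λ)) + o_i + ε_i(λ)

* `G` are unit-height Gaussians. The moisture term places water features in
  the 1450 nm O–H-overtone region (a 1430/1470 nm doublet plus the weaker
  1190 nm second overtone) and the 1940 nm O–H-combination region
  (1900/1935/1975 nm), widths 20–26 nm. Gain `g` defaults to 0.10 absorbance
  per % moisture — near the sensitivity optimum of a Beer–Lambert model,
  where ∂r/∂m = g·exp(−g·m−baseline) is maximized at g ≈ 1/m.
* `fixed` collects moisture-independent constituent bands (C–H overtones and
  combinations of starch/oil at ~1210/1360/1725/2310 nm, protein N–H at
  ~1530/2180 nm, starch at ~2050 nm, and a deep 2420 nm shoulder). They play
  two roles real spectra play: they anchor each sample's multiplicative/
  additive scatter estimate, and — together with the quartic baseline that
  rises steeply toward 2500 nm — they fix the spectrum's global minimum at
  the long-wavelength end and its maximum at the bright short-wave plateau.
  Both extremes are therefore moisture-independent, which is what makes
  per-spectrum min–max normalization a benign affine rescaling instead of a
  signal-destroying one.
* Scatter: `s_i ~ N(1, 0.01)`, `o_i ~ N(0, 0.005)`. These are *dish-mean*
  magnitudes: each study sample is the mean spectrum of a dish of many
  kernels, so per-kernel path-length variation largely averages out.
* Noise: iid Gaussian per band, sd 0.005 reflectance units in the analysis
  region, inflated 5× in the first/last ~6.6 % of bands (17 of 256 per
  side). The inflated zone coincides with the bands the default trim
  discards — the trim exists precisely because the spectral extremes are
  noise-dominated.
* Reflectance is clipped to (0, 1.5]; values slightly above 1 occur (bright
  plateau ≈ 1.06) as they can in white-referenced data.
* Moisture is drawn uniformly over [7.377, 11.993] % so the calibration
  range is always fully covered; SPXY behaviour is range-driven.

Sampling order is fixed (moisture, then scatter, then noise), so a given
config+seed is bit-reproducible and noise-free variants share moisture
draws.

### Scenes

`generate_scene` places non-overlapping ellipses ("seeds") on a dark
background, assigns each one moisture value (optional within-seed Gaussian
spread), generates pixel spectra from the same model, and synthesizes
raw/white/dark frames by inverting the reflectance correction against a
smooth lamp profile — so `reflectance_correct(raw, white, dark)` recovers
the cube to machine precision. Seed placement retries are bounded; an
overfull scene raises a capacity error.

### What the generator does and does not emulate

Emulated: the band count and wavelength range of the acquisition (256 bands,
935.5–2539 nm), moisture-scaled water features, scatter artifacts matched to
the pretreatments designed to remove them (SNV/MSC/normalization ↔ affine
scatter; detrending ↔ polynomial baseline; smoothing ↔ band noise),
edge-concentrated noise matched to the trim, and per-pixel ground truth for
visualization tests.

Not emulated: realistic seed morphology, embryo/endosperm surface
differences, variety-specific composition differences, band-position shifts
with temperature or water binding state, and spectrally correlated
(structured) instrument noise. The last point matters for interpreting
results: with iid band noise, a full-spectrum model averages noise across
all bands, so wavelength selection here buys dimensionality reduction at a
small accuracy cost rather than an accuracy gain. On real data, where errors
are dominated by structured interferences rather than white noise, selection
can also improve accuracy. Passing tests demonstrate that each algorithm does
what its definition says under known ground truth — not that its relative
ranking on real maize spectra is reproduced.

### The planted-signal benchmark

`generate_planted_signal` makes selector sensitivity measurable: each
planted band responds to its own latent analyte component (sd 0.1) on top of
a background fluctuation every band carries (sd 0.03), the response is a
fixed linear combination of the latents, and iid measurement noise (default
sd 0.005) is added everywhere. A band is "informative" because the analyte
makes it vary — which is also what lets variance-driven SPA chains find it.

## Imaging

* Reflectance correction is elementwise; any non-positive `white − dark`
  element is an error reporting the offending count, never a silent clamp —
  a bad denominator flags an acquisition fault.
* The general trim is a closed wavelength interval. The default trim for a
  256-band axis drops the first 21 and last 17 band indices, retaining the
  218 central bands (~1067–2432 nm): the printed endpoints in circulation
  (1065–2432 nm) are mutually inconsistent with a 256-point linear grid
  under strict inclusion (217 bands), and the 218-band axis is the one the
  downstream analysis is defined on.
* Segmentation thresholds the band image nearest 1100 nm (good
  seed/background contrast, clear of deep water absorption) with Otsu's
  method, labels 8-connected components, and drops regions under 20 px.
* ENVI I/O is a minimal header/binary reader-writer (BIL/BIP/BSQ, common
  dtypes, wavelength list or start/end interpolation).

## Pretreatments

All seven methods operate row-wise (per spectrum). Parameter defaults follow
the study settings: window 7 for moving average and Savitzky–Golay,
polynomial order 2 for Savitzky–Golay and detrending.

* Moving-average edges shrink to the valid overlap rather than padding (no
  fabricated reflectance values); Savitzky–Golay uses the standard
  polynomial-fit edge evaluation (`mode="interp"`).
* "Baseline" subtracts the line through the two endpoints, then the
  per-spectrum minimum (simplest standard offset correction); polynomial
  baselines are available via detrending.
* "Normalization" defaults to per-spectrum min–max scaling, with unit-vector
  and max-normalization variants behind a flag.
* SNV uses the sample standard deviation (ddof = 1).
* MSC regresses each spectrum on a reference and inverts the fit; the
  reference is the calibration-set mean, learned by `Preprocessor.fit` and
  never recomputed on test or pixel data (leakage prevention). Degenerate
  rows (zero SNV sd, |MSC slope| < 1e−12) raise an error naming the row.

## SPXY splitting

Joint distance `d = d_x/max d_x + d_y/max d_y`; selection seeds with the
maximal-distance pair and repeatedly adds the sample whose minimum distance
to the selected set is maximal. Calibration size = round(fraction·n),
default fraction 0.75 (60/20 for n = 80). Deterministic; ties break to the
lowest sample index. Distances are computed on raw trimmed spectra by
default (the split precedes pretreatment in the pipeline, so pretreatment
constants can be learned on the calibration set only). Strict
range-coverage (calibration moisture range ⊇ prediction range) holds
exactly on noise-free data; under band noise, near-duplicate extreme
samples can land on either side.

## Wavelength selection

### SPA

Every column serves as a candidate chain start. A chain grows by projecting
all remaining columns orthogonally to the span of the chosen ones
(implemented as rank-one updates; verified against explicit pinv-based
projectors) and adding the column of maximal residual norm; chains truncate
if the residual degenerates (norm < 1e−12). Every (start, size) prefix with
size in [n_min, n_max] is scored by the leave-one-out RMSE of a multiple
linear regression — computed in closed form from the hat matrix
(`e_loo = e/(1−h)`), verified against a naive refit loop — and the global
minimum wins (ties: fewer bands, then lower start index). Default
n_max = 25, capped at min(bands, samples−1).

### CARS

Defaults: 50 Monte-Carlo iterations, 10-fold RMSECV scoring, 80 % row
subsampling. Each iteration fits PLS on a random subsample of the retained
bands, weights bands by |regression coefficient| (normalized), keeps the top
⌈r_i·n⌉ by weight under the exponential decay schedule (endpoints r_1 = 1
and r_N = 2/n exactly; ceiling rounding preserves the final two-band
endpoint, floor-bounded at 2), then resamples that many bands with
replacement with probability ∝ weight; the retained set is the unique draw.
The weight fit uses the capped maximum component count (10); the recorded
per-iteration RMSECV is minimized over 1..cap using per-component NIPALS
predictions, so one fit per fold covers the whole grid. The subset of the
minimal-RMSECV iteration wins. Seeded and reproducible; early termination
below 2 bands is recorded in the diagnostics.

### UVE

A uniform-[0,1] noise block of the same width as X, scaled by 1e−10, is
appended; leave-one-out PLS models (12 latent variables by default) yield a
coefficient row per left-out sample; stability is mean/sd (ddof = 1) per
column, ±∞ with a diagnostic flag where the sd underflows. The threshold is
the maximum |stability| over the noise columns and selection is two-sided
(|C| > C_max). Because coefficient stability is scale-free, the real
columns' stabilities are invariant to the noise scale and seed (verified to
1e−8); the *threshold* is a maximum over random draws, so marginal
selections can differ between seeds — and on weakly structured data the
threshold can reject every band, which the pipeline treats as a legitimate
empty selection (the method drops out of the model grid with a warning).

## Calibration models and metrics

* PLSR is PLS1 NIPALS with mean centring and no variance scaling
  (pretreatment owns the scale), deflation-based and deterministic; one pass
  yields the coefficient path for every component count. Cross-checked
  against an independent PLS implementation and against OLS at full rank.
* PCR takes the leading principal components of centred X (SVD) and
  regresses y on the scores; equals OLS at full rank.
* SVR is RBF-kernel ε-SVR on standardized inputs; hyperparameters come from
  a seeded 5-fold grid search (C ∈ {1, 10, 100}, γ ∈ {scale, 0.1, 1},
  ε ∈ {0.01, 0.1}) run once on the calibration set; cross-validation folds
  refit with those fixed hyperparameters (refitting the search inside
  leave-one-out is prohibitively slow and changes results negligibly).
* R² defaults to the squared Pearson correlation between measured and
  predicted values — the standard RC²/RP² of calibration tables; it is
  sign-blind by construction. A "printed" variant (unsquared cross-product
  over the sum of the two sums of squares) circulates in parts of the
  applied literature; it is not a coefficient of determination (it cannot
  reach 1 unless the two spreads coincide) and is available behind
  `formula="printed"` for comparison only.
* RMSE is the plain root-mean-square residual.
* Component counts are chosen by out-of-fold RMSECV (leave-one-out by
  default, seeded k-fold otherwise), capped at 15.
* The "validation set" columns of the report are leave-one-out
  cross-validation on the calibration set, not a third partition.

## Pipeline

Stage order: generate → trim → SPXY split (raw trimmed spectra) →
pretreatment comparison on the calibration set (PLSR + LOOCV per method;
winner = minimal RMSECV) → fit the winning pretreatment on the calibration
set and apply frozen everywhere → SPA/CARS/UVE → (band sets × model kinds)
grid evaluated on the held-out prediction set. All randomness sits behind
named seeds in the config; identical configs reproduce every table
byte-for-byte. Artifacts (config, split, selections, tables) are written
under the configured output directory.

## Visualization

Pixel spectra pass through the same frozen pretreatment, band restriction,
and model as the calibration spectra — a pixel is test data, so the MSC
reference and any fitted constants come from calibration. Degenerate pixels
are flagged invalid and counted, not fatal; an empty mask yields a warning
diagnostic. Rendering maps values linearly from the fixed 0–12 % range onto
a continuous colormap (jet-like by default, configurable), clamps and counts
out-of-range values, and renders background neutral grey.

## Problem sizes and observed behaviour

The test suite and the analysis scripts run the study at its native size
(80 samples × 218 analysis bands, SPXY 60/20); selector benchmarks use 60
samples × 60 bands over 20 seeds; scenes are 64×64 or 96×96 pixels. At
these sizes the whole suite completes in a few minutes on one CPU.

Observed on the default generator (seeds 0–9): full-spectrum PLSR reaches
RP² ≈ 0.99 and RMSEP ≈ 0.05–0.08 % moisture; the normalization → SPA → PLSR
route reaches RP² ≥ 0.98 in 10/10 seeds with RMSEP ≈ 0.09–0.14 %. The
subset route's error floor is statistical, not a bug: with iid band noise
sd σ and peak sensitivity capped near exp(−1)/m ≈ 0.035 reflectance per %
moisture, a k-band model cannot beat σ/(0.035·√k), and SPA's
collinearity-pruning keeps only a handful of water-band cores because the
moisture signal is rank-one across bands. Pixel-map recovery on noiseless
scenes is within 0.3 % moisture per seed (typically ≤ 0.1 %).

## Known limitations

* The generator's moisture signal is rank-one and its noise iid, so the
  relative merit of wavelength selection versus full-spectrum modelling does
  not transfer to interference-dominated real data (see above).
* UVE's max-over-noise threshold is a single extreme statistic; a quantile
  threshold would be more stable but is deliberately not the default, to
  keep the classical formulation.
* SVR cross-validation reuses hyperparameters searched on the full
  calibration set; its RCV² is therefore mildly optimistic.
* ENVI support covers the common header fields only (no BBL, no per-band
  FWHM).
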