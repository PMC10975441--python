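# hsimoist

Chemometrics pipeline for predicting seed moisture content from near-infrared
hyperspectral images, exercised end to end on a synthetic maize-seed data
generator with known ground truth.

Grain moisture is the key quality variable during maize harvesting, storage,
and breeding, and the reference assay (oven drying) destroys the seed. NIR
hyperspectral imaging offers a non-destructive alternative: water's O–H
overtone and combination bands (near 1450 nm and 1940 nm) deepen with
moisture, so a calibration built from a modest set of reference-assayed
samples can predict moisture for new samples — and, pixel by pixel, render a
moisture map of every seed in the image.

The package implements the full calibration workflow:

1. **Reflectance calibration** — black/white correction
   `R = (I_raw − I_dark) / (I_white − I_dark)` and trimming of the noisy
   spectral extremes (256 → 218 bands, ≈1065–2432 nm).
2. **Spectral pretreatment** — moving average, Savitzky–Golay, baseline,
   min–max normalization, SNV, MSC, and detrending behind one dispatcher,
   with calibration-set statistics frozen before touching test data.
3. **SPXY sample partitioning** — Kennard–Stone selection on the joint
   distance `d(i,j) = d_x(i,j)/max d_x + d_y(i,j)/max d_y`, so the
   calibration set spans both spectral and moisture space.
4. **Wavelength selection** — SPA (successive projections algorithm),
   CARS (competitive adaptive reweighted sampling with the exponential decay
   schedule `r_i = μ e^(−k i)`, `μ = (n/2)^{1/(N−1)}`, `k = ln(n/2)/(N−1)`),
   and UVE (uninformative variable elimination by coefficient stability
   `C_i = mean(b_i)/sd(b_i)` against an appended noise block).
5. **Calibration models** — PLSR (NIPALS), PCR, and RBF-kernel SVR, with
   component counts chosen by leave-one-out RMSECV, reported as
   RC²/RMSEC (calibration), RCV²/RMSECV (cross-validation), and
   RP²/RMSEP (held-out prediction).
6. **Visualization** — pixel-wise prediction through the frozen pipeline and
   pseudo-color rendering on a fixed 0–12 % moisture scale.

Because no public dataset accompanies the study design, the `synthetic`
module is a first-class component: a Beer–Lambert reflectance model with
moisture-scaled water bands, moisture-independent constituent bands,
multiplicative/additive scatter, and heteroscedastic detector noise — plus
small imaged "scenes" of elliptical seeds whose raw/white/dark frames invert
the reflectance correction exactly. Every stage is tested against this
generator's ground truth. See `docs/methods.md` for the model and its
deliberate departures from real data.

## Worked example

The numbered scripts under `analysis/` run the study step by step:

```bash
python analysis/01_simulate_dataset.py --seed 0     # 80 samples, 256 bands
python analysis/02_preprocess_comparison.py --seed 0
python analysis/03_select_wavelengths.py --seed 0
python analysis/04_model_grid.py --seed 0
python analysis/05_moisture_maps.py --seed 0
```

`04_model_grid.py` prints the model-comparison table (seed 0):

```
    model  bands  PCs      RC2    RMSEC     RCV2   RMSECV      RP2    RMSEP
     PLSR    218  4.0 0.999637 0.026621 0.996856 0.078375 0.996033 0.077735
      PCR    218 15.0 0.998018 0.062199 0.996445 0.083349 0.996337 0.075486
     SVMR    218  NaN 0.999961 0.009882 0.951436 0.388542 0.901023 0.478464
 SPA-PLSR      8  3.0 0.996811 0.078908 0.995753 0.091062 0.985985 0.142913
  ...
```

Each row is one (band set × regressor) cell: `bands` is the retained
wavelength count, `PCs` the cross-validated latent-variable count, and the
three metric pairs measure calibration fit, cross-validated stability, and
held-out prediction. Here full-spectrum PLSR/PCR predict the held-out
moisture to within ≈0.08 % (RP² ≈ 0.996) of the planted truth, while the
8-wavelength SPA subset still reaches RP² ≈ 0.986 with a 27-fold reduction
in bands.

`05_moisture_maps.py` closes the loop on an imaged scene (seed 0):

```
seed 1: truth 11.974%  predicted 11.874%
seed 2: truth  9.694%  predicted  9.802%
seed 3: truth 10.936%  predicted 10.966%
seed 4: truth  9.658%  predicted  9.747%
```

Per-seed mean predictions land within ≈0.1 % moisture of the planted
per-seed truth, and `results/figures/moisture_map.png` shows the rendered
pseudo-color map.

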