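#!/usr/bin/env python
"""Extract moisture-informative wavelengths with SPA, CARS, and UVE.

Runs all three selectors on the pretreated calibration set and writes each
result (indices, wavelengths, diagnostics) as JSON, plus diagnostic figures:
the SPA RMSE-versus-subset-size curve, the CARS retained-count and RMSECV
traces, and the UVE stability profile with its noise threshold.
"""
import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from hsimoist import (
    PreprocessSpec,
    Preprocessor,
    SyntheticConfig,
    cars_select,
    default_trim,
    generate_spectra,
    spa_select,
    spxy_split,
    uve_select,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--preprocess", default="normalization")
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--figdir", type=Path, default=Path("results/figures"))
args = parser.parse_args()

spectra, moisture = generate_spectra(SyntheticConfig(n_samples=80, seed=args.seed))
trimmed = default_trim(spectra)
split = spxy_split(trimmed, moisture, 0.75)
pre = Preprocessor(PreprocessSpec(method=args.preprocess)).fit(
    trimmed.select_samples(split.calibration_idx)
)
xcal = pre.transform(trimmed.select_samples(split.calibration_idx))
ycal = moisture[split.calibration_idx]

args.outdir.mkdir(parents=True, exist_ok=True)
args.figdir.mkdir(parents=True, exist_ok=True)

selections = {
    "spa": spa_select(xcal, ycal, n_max=25),
    "cars": cars_select(xcal, ycal, seed=args.seed),
    "uve": uve_select(xcal, ycal, n_latent=12, seed=args.seed),
}
for name, sel in selections.items():
    sel.to_json(args.outdir / f"selection_{name}.json")
    print(
        f"{name.upper():4s}: {sel.n_selected:3d}/{xcal.n_bands} bands "
        f"({sel.fraction_pct(xcal.n_bands):.1f}%)"
    )

# --- figures ---------------------------------------------------------------
spa = selections["spa"]
fig, ax = plt.subplots()
ax.plot(spa.diagnostics["sizes"], spa.diagnostics["rmse_by_size"], "o-")
ax.set_xlabel("number of selected wavelengths")
ax.set_ylabel("LOOCV-MLR RMSE (% moisture)")
ax.axvline(spa.diagnostics["best_size"], color="r", ls="--")
fig.savefig(args.figdir / "spa_rmse_vs_size.png", dpi=150, bbox_inches="tight")

cars = selections["cars"]
fig, axes = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
axes[0].plot(cars.diagnostics["retained_counts"], "o-")
axes[0].set_ylabel("retained wavelengths")
axes[1].plot(cars.diagnostics["rmsecv"], "o-")
axes[1].axvline(cars.diagnostics["best_iteration"] - 1, color="r", ls="--")
axes[1].set_ylabel("10-fold RMSECV")
axes[1].set_xlabel("Monte-Carlo iteration")
fig.savefig(args.figdir / "cars_traces.png", dpi=150, bbox_inches="tight")

uve = selections["uve"]
p = xcal.n_bands
fig, ax = plt.subplots(figsize=(7, 4))
st = uve.diagnostics["stability"]
ax.plot(range(p), st[:p], label="spectral variables")
ax.plot(range(p, 2 * p), st[p:], label="noise variables")
thr = uve.diagnostics["threshold"]
ax.axhline(thr, color="k", ls="--")
ax.axhline(-thr, color="k", ls="--")
ax.axvline(p - 0.5, color="grey")
ax.set_xlabel("variable index (left: spectra, right: noise)")
ax.set_ylabel("stability C")
ax.legend()
fig.savefig(args.figdir / "uve_stability.png", dpi=150, bbox_inches="tight")
plt.close("all")
print(f"Diagnostics written to {args.outdir}/, figures to {args.figdir}/")
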