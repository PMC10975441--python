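#!/usr/bin/env python
"""Generate the synthetic 80-variety maize moisture dataset.

Emulates the study's sample structure: 80 dish-mean NIR reflectance spectra
(256 bands, 935.5-2539 nm) with reference moisture values spanning
7.38-11.99 % wet basis. Writes the spectra+moisture CSV (large, regenerable)
to scratch/ and a small summary table to results/.
"""
import argparse
import json
from pathlib import Path

import numpy as np

from hsimoist import SyntheticConfig, generate_spectra

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--datadir", type=Path, default=Path("scratch"))
args = parser.parse_args()

config = SyntheticConfig(n_samples=80, seed=args.seed)
spectra, moisture = generate_spectra(config)

args.datadir.mkdir(parents=True, exist_ok=True)
args.outdir.mkdir(parents=True, exist_ok=True)
spectra.to_csv(args.datadir / "spectra_80.csv", moisture=moisture)
config.to_yaml(args.datadir / "synthetic_config.yaml")

summary = {
    "n_samples": int(config.n_samples),
    "n_bands": int(config.n_bands),
    "wavelength_range_nm": [config.wl_start, config.wl_end],
    "moisture_min": round(float(moisture.min()), 3),
    "moisture_max": round(float(moisture.max()), 3),
    "moisture_mean": round(float(moisture.mean()), 3),
    "moisture_sd": round(float(moisture.std(ddof=1)), 3),
}
(args.outdir / "dataset_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
print("Simulated dataset:", json.dumps(summary, indent=2))
print(f"Spectra written to {args.datadir/'spectra_80.csv'}")
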