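"""Full-study orchestration: pretreatment comparison and the model grid.

The study design mirrors standard NIR calibration practice: trim the noisy
spectral extremes, partition samples with SPXY on the raw trimmed spectra,
choose the pretreatment by comparing PLSR models under leave-one-out
cross-validation on the calibration set, extract wavelengths with SPA, CARS
and UVE, and evaluate every (band set x regression kind) cell on the
held-out prediction set. All randomness sits behind named seeds in the
config; reruns with the same config reproduce every table bit-for-bit.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .containers import SpectraMatrix
from .errors import ConfigurationError
from .imaging import default_trim, trim_bands
from .modeling import EvaluationReport, cross_validate, evaluate_grid, fit, predict, r_squared, rmse
from .preprocessing import METHODS, Preprocessor, PreprocessSpec
from .selection import SelectionResult, cars_select, spa_select, uve_select
from .splitting import SplitResult, spxy_split
from .synthetic import SyntheticConfig, generate_spectra

__all__ = ["PipelineConfig", "StudyResult", "run_preprocess_comparison", "run_full_study"]

log = logging.getLogger("hsimoist")


@dataclass
class PipelineConfig:
    """Configuration for the full study.

    ``preprocess_method=None`` lets the pretreatment comparison pick the
    winner (minimal RMSECV); set a method name to pin it. ``selection_seeds``
    seeds the stochastic selectors (CARS subsampling, UVE noise block).
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    trim: str | tuple[float, float] = "default"
    preprocess_methods: tuple[str, ...] = METHODS
    preprocess_method: str | None = None
    calib_fraction: float = 0.75
    selection_methods: tuple[str, ...] = ("spa", "cars", "uve")
    selection_seeds: dict = field(default_factory=lambda: {"cars": 0, "uve": 0})
    spa_n_max: int = 25
    model_kinds: tuple[str, ...] = ("plsr", "pcr", "svmr")
    model_seed: int = 0
    outdir: str | Path | None = None

    def validate(self) -> None:
        if not self.preprocess_methods:
            raise ConfigurationError("at least one preprocess method is required")
        if not self.model_kinds:
            raise ConfigurationError("at least one model kind is required")
        unknown = set(self.preprocess_methods) - set(METHODS)
        if unknown:
            raise ConfigurationError(f"unknown preprocess methods {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "synthetic": self.synthetic.__dict__,
            "trim": list(self.trim) if isinstance(self.trim, tuple) else self.trim,
            "preprocess_methods": list(self.preprocess_methods),
            "preprocess_method": self.preprocess_method,
            "calib_fraction": self.calib_fraction,
            "selection_methods": list(self.selection_methods),
            "selection_seeds": dict(self.selection_seeds),
            "spa_n_max": self.spa_n_max,
            "model_kinds": list(self.model_kinds),
            "model_seed": self.model_seed,
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["synthetic"] = SyntheticConfig(**d.get("synthetic", {}))
        if isinstance(d.get("trim"), list):
            d["trim"] = tuple(d["trim"])
        for key in ("preprocess_methods", "selection_methods", "model_kinds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StudyResult:
    preprocess_report: EvaluationReport
    winner: str
    split: SplitResult
    selections: dict[str, SelectionResult]
    grid_report: EvaluationReport
    preprocessor: Preprocessor
    spectra: SpectraMatrix
    moisture: np.ndarray


def run_preprocess_comparison(
    xcal: SpectraMatrix,
    ycal: np.ndarray,
    methods: tuple[str, ...] = METHODS,
    cv_scheme: str = "loo",
) -> EvaluationReport:
    """PLSR under each pretreatment, LOOCV on the calibration set.

    Emits one row per method (including the untreated control); the winner
    is the row with minimal RMSECV.
    """
    rows = []
    for method in methods:
        pre = Preprocessor(PreprocessSpec(method=method)).fit(xcal)
        xt = pre.transform(xcal)
        cv = cross_validate("plsr", xt, ycal, scheme=cv_scheme)
        model = fit("plsr", xt, ycal, n_components=cv.best_components)
        yhat = predict(model, xt)
        rows.append(
            {
                "model": method,
                "bands": xt.n_bands,
                "PCs": cv.best_components,
                "RC2": r_squared(ycal, yhat),
                "RMSEC": rmse(ycal, yhat),
                "RCV2": cv.rcv2,
                "RMSECV": cv.rmsecv,
            }
        )
    return EvaluationReport(rows)


def _trim(config: PipelineConfig, x: SpectraMatrix) -> SpectraMatrix:
    if config.trim == "default":
        return default_trim(x) if x.n_bands == 256 else x
    if config.trim == "none":
        return x
    lo, hi = config.trim
    return trim_bands(x, lo, hi)


def run_full_study(config: PipelineConfig) -> StudyResult:
    """Execute the whole calibration study on synthetic data.

    Stage order: generate -> trim -> SPXY split (on raw trimmed spectra) ->
    pretreatment comparison on the calibration set -> fit the winning
    pretreatment on the calibration set and apply frozen everywhere ->
    SPA/CARS/UVE -> (band sets x model kinds) grid. Artifacts are written
    under ``config.outdir`` when set.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    t0 = time.perf_counter()
    spectra, moisture = generate_spectra(config.synthetic)
    trimmed = _trim(config, spectra)
    log.info("generated %d samples, %d bands after trim", trimmed.n_samples, trimmed.n_bands)

    split = spxy_split(trimmed, moisture, config.calib_fraction)
    xcal_raw = trimmed.select_samples(split.calibration_idx)
    xpred_raw = trimmed.select_samples(split.prediction_idx)
    ycal = moisture[split.calibration_idx]
    ypred = moisture[split.prediction_idx]

    pre_report = run_preprocess_comparison(xcal_raw, ycal, config.preprocess_methods)
    if config.preprocess_method is not None:
        winner = config.preprocess_method
    else:
        winner = str(pre_report.table.loc[pre_report.table["RMSECV"].idxmin(), "model"])
    log.info("pretreatment winner: %s", winner)

    preprocessor = Preprocessor(PreprocessSpec(method=winner)).fit(xcal_raw)
    xcal = preprocessor.transform(xcal_raw)
    xpred = preprocessor.transform(xpred_raw)

    selections: dict[str, SelectionResult] = {}
    for method in config.selection_methods:
        t = time.perf_counter()
        if method == "spa":
            selections[method] = spa_select(xcal, ycal, n_max=config.spa_n_max)
        elif method == "cars":
            selections[method] = cars_select(
                xcal, ycal, seed=config.selection_seeds.get("cars", 0)
            )
        elif method == "uve":
            n_latent = min(12, len(ycal) - 2)
            selections[method] = uve_select(
                xcal, ycal, n_latent=n_latent, seed=config.selection_seeds.get("uve", 0)
            )
        else:
            raise ConfigurationError(f"unknown selection method {method!r}")
        log.info(
            "%s selected %d/%d bands (%.1f%%) in %.1fs",
            method,
            selections[method].n_selected,
            xcal.n_bands,
            selections[method].fraction_pct(xcal.n_bands),
            time.perf_counter() - t,
        )

    # a selector may legitimately reject every band (e.g. UVE when no real
    # column beats the noise threshold); such methods are dropped from the
    # grid rather than aborting the study
    usable = [m for m in config.selection_methods if selections[m].n_selected > 0]
    for m in set(config.selection_methods) - set(usable):
        log.warning("selection %s returned no bands; omitted from the model grid", m)
    grid = evaluate_grid(
        xcal,
        ycal,
        xpred,
        ypred,
        selections=[None] + [selections[m] for m in usable],
        kinds=config.model_kinds,
        seed=config.model_seed,
    )
    log.info("full study finished in %.1fs", time.perf_counter() - t0)

    if outdir is not None:
        split.to_csv(outdir / "split.csv", trimmed.sample_ids)
        pre_report.to_csv(outdir / "preprocess_comparison.csv")
        grid.to_csv(outdir / "model_grid.csv")
        for method, sel in selections.items():
            sel.to_json(outdir / f"selection_{method}.json")
        (outdir / "study.json").write_text(
            json.dumps(
                {
                    "winner_preprocess": winner,
                    "n_calibration": len(split.calibration_idx),
                    "n_prediction": len(split.prediction_idx),
                    "best_model": str(grid.best("RMSEP")["model"]),
                },
                indent=2,
            )
        )

    return StudyResult(
        preprocess_report=pre_report,
        winner=winner,
        split=split,
        selections=selections,
        grid_report=grid,
        preprocessor=preprocessor,
        spectra=trimmed,
        moisture=moisture,
    )
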