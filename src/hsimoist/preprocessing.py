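"""The seven spectral pretreatments behind one dispatcher.

Methods (all row-wise, i.e. per spectrum): moving average, Savitzky-Golay
smoothing, baseline (endpoint-line plus minimum-offset subtraction), min-max
normalization, standard normal variate (SNV), multiplicative scatter
correction (MSC), and polynomial detrending — plus ``none`` as the untreated
control.

Statefulness: MSC regresses each spectrum onto a reference learned from the
calibration set (its mean spectrum) and never recomputed on test or pixel
data; use :class:`Preprocessor` (fit on calibration, transform anything) to
honour that contract. ``preprocess(x, spec)`` is the stateless convenience
for methods with no fitted constants.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .containers import SpectraMatrix
from .errors import ConfigurationError, DegenerateSpectrumError

__all__ = ["PreprocessSpec", "Preprocessor", "preprocess", "METHODS"]

METHODS = (
    "none",
    "moving_average",
    "savitzky_golay",
    "baseline",
    "normalization",
    "snv",
    "msc",
    "detrending",
)

_NORM_VARIANTS = ("minmax", "unit_vector", "max")


@dataclass
class PreprocessSpec:
    """Pretreatment selection and parameters.

    window/poly_order defaults (7, 2) are the stated smoothing settings;
    detrending uses ``poly_order`` as the polynomial degree. ``norm_variant``
    picks the normalization flavour (min-max per spectrum by default).
    """

    method: str = "none"
    window: int = 7
    poly_order: int = 2
    norm_variant: str = "minmax"
    msc_reference: np.ndarray | None = None

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(
                f"method must be one of {METHODS}, got {self.method!r}"
            )
        if self.method in ("moving_average", "savitzky_golay"):
            if self.window < 3 or self.window % 2 == 0:
                raise ConfigurationError("window must be odd and >= 3")
        if self.method == "savitzky_golay" and self.poly_order >= self.window:
            raise ConfigurationError("poly_order must be < window")
        if self.method == "detrending" and self.poly_order < 0:
            raise ConfigurationError("poly_order must be >= 0")
        if self.method == "normalization" and self.norm_variant not in _NORM_VARIANTS:
            raise ConfigurationError(
                f"norm_variant must be one of {_NORM_VARIANTS}"
            )

    # ----------------------------------------------------------- serialisation
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["msc_reference"] is not None:
            d["msc_reference"] = [float(v) for v in d["msc_reference"]]
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessSpec":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("msc_reference") is not None:
            d["msc_reference"] = np.asarray(d["msc_reference"], dtype=float)
        return cls(**d)


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centred window mean; edge windows shrink to the valid overlap."""
    n = v.shape[1]
    half = window // 2
    padded = np.cumsum(np.concatenate([np.zeros((v.shape[0], 1)), v], axis=1), axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (padded[:, hi] - padded[:, lo]) / (hi - lo)


def _baseline(v: np.ndarray, wl: np.ndarray) -> np.ndarray:
    """Subtract the line through the two endpoints, then shift so min = 0."""
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    line = v[:, [0]] + (v[:, [-1]] - v[:, [0]]) * t[None, :]
    out = v - line
    return out - out.min(axis=1, keepdims=True)


def _normalization(v: np.ndarray, variant: str) -> np.ndarray:
    if variant == "minmax":
        lo = v.min(axis=1, keepdims=True)
        rng = v.max(axis=1, keepdims=True) - lo
        _check_nonzero(rng, "min-max range")
        return (v - lo) / rng
    if variant == "unit_vector":
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        _check_nonzero(norm, "vector norm")
        return v / norm
    if variant == "max":
        mx = np.abs(v).max(axis=1, keepdims=True)
        _check_nonzero(mx, "max magnitude")
        return v / mx
    raise ConfigurationError(f"unknown normalization variant {variant!r}")


def _check_nonzero(scale: np.ndarray, what: str) -> None:
    bad = np.flatnonzero(np.abs(scale.ravel()) < 1e-12)
    if bad.size:
        raise DegenerateSpectrumError(
            f"zero {what} in row {bad[0]}", row=int(bad[0])
        )


def _snv(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=1, keepdims=True, ddof=1)
    _check_nonzero(sd, "standard deviation (SNV)")
    return (v - v.mean(axis=1, keepdims=True)) / sd


def _msc(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """OLS fit x ~ a + b*ref per spectrum; corrected = (x - a)/b."""
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-12:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    b = (v - v.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) < 1e-12)
    if bad.size:
        raise DegenerateSpectrumError(
            f"MSC slope below 1e-12 in row {bad[0]}", row=int(bad[0])
        )
    a = v.mean(axis=1) - b * ref.mean()
    return (v - a[:, None]) / b[:, None]


def _detrend(v: np.ndarray, wl: np.ndarray, order: int) -> np.ndarray:
    """Subtract the per-spectrum least-squares polynomial in wavelength."""
    t = (wl - wl.mean()) / (wl.max() - wl.min())  # conditioning
    vander = np.polynomial.polynomial.polyvander(t, order)
    coef, *_ = np.linalg.lstsq(vander, v.T, rcond=None)
    return v - (vander @ coef).T


class Preprocessor:
    """Fit pretreatment constants on the calibration set; apply frozen.

    Only MSC carries fitted state (the reference spectrum = calibration mean
    unless the spec supplies one); all other methods are stateless and
    ``fit`` is a no-op for them.
    """

    def __init__(self, spec: PreprocessSpec):
        spec.validate()
        self.spec = spec
        self._reference: np.ndarray | None = (
            np.asarray(spec.msc_reference, dtype=float)
            if spec.msc_reference is not None
            else None
        )

    @property
    def reference_(self) -> np.ndarray | None:
        return self._reference

    def fit(self, x: SpectraMatrix) -> "Preprocessor":
        if self.spec.method == "msc" and self._reference is None:
            self._reference = x.values.mean(axis=0)
        return self

    def transform(self, x: SpectraMatrix) -> SpectraMatrix:
        spec = self.spec
        v, wl = x.values, x.wavelengths
        if spec.method == "none":
            out = v.copy()
        elif spec.method == "moving_average":
            out = _moving_average(v, spec.window)
        elif spec.method == "savitzky_golay":
            out = savgol_filter(
                v, spec.window, spec.poly_order, axis=1, mode="interp"
            )
        elif spec.method == "baseline":
            out = _baseline(v, wl)
        elif spec.method == "normalization":
            out = _normalization(v, spec.norm_variant)
        elif spec.method == "snv":
            out = _snv(v)
        elif spec.method == "msc":
            if self._reference is None:
                raise ConfigurationError(
                    "MSC requires fit() on the calibration set first"
                )
            if self._reference.size != v.shape[1]:
                raise ConfigurationError(
                    "MSC reference length does not match the band axis"
                )
            out = _msc(v, self._reference)
        elif spec.method == "detrending":
            out = _detrend(v, wl, spec.poly_order)
        else:  # pragma: no cover - guarded by validate()
            raise ConfigurationError(f"unknown method {spec.method!r}")
        return SpectraMatrix(out, wl, list(x.sample_ids))

    def fit_transform(self, x: SpectraMatrix) -> SpectraMatrix:
        return self.fit(x).transform(x)


def preprocess(x: SpectraMatrix, spec: PreprocessSpec) -> SpectraMatrix:
    """One-shot pretreatment (fits any constants on ``x`` itself)."""
    return Preprocessor(spec).fit_transform(x)
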