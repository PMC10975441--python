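"""In-memory containers shared across the pipeline.

A :class:`Hypercube` is what a push-broom NIR camera produces: a 3-D array
(rows x cols x bands) with a strictly increasing wavelength axis, either raw
detector counts or dimensionless reflectance after black/white calibration.
A :class:`SpectraMatrix` is the X matrix of all downstream chemometrics: one
mean reflectance spectrum per sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = ["Hypercube", "SpectraMatrix"]


def _check_wavelengths(wavelengths: np.ndarray, n_bands: int) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size != n_bands:
        raise ContractError(
            f"wavelength axis length {wl.size} does not match band count {n_bands}"
        )
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ContractError("wavelengths must be strictly increasing")
    return wl


@dataclass
class Hypercube:
    """3-D hyperspectral array with a wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Raw intensity (counts) or reflectance (dimensionless).
    wavelengths : ndarray, shape (bands,)
        Band-centre wavelengths in nm, strictly increasing.
    kind : {"raw", "reflectance"}
        Reflectance cubes must be all-finite.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ContractError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.kind not in ("raw", "reflectance"):
            raise ContractError(f"unknown cube kind {self.kind!r}")
        self.wavelengths = _check_wavelengths(self.wavelengths, self.data.shape[2])
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ContractError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_nearest(self, wavelength_nm: float) -> int:
        """Index of the band whose centre is closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def select_bands(self, idx: np.ndarray) -> "Hypercube":
        idx = np.asarray(idx, dtype=int)
        return Hypercube(self.data[:, :, idx], self.wavelengths[idx], self.kind)


@dataclass
class SpectraMatrix:
    """Per-sample spectra: the chemometric X matrix (samples x bands)."""

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths = _check_wavelengths(self.wavelengths, self.values.shape[1])
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ContractError("sample_ids length does not match sample count")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("spectra matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def band_nearest(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def select_bands(self, idx: np.ndarray) -> "SpectraMatrix":
        idx = np.asarray(idx, dtype=int)
        return SpectraMatrix(self.values[:, idx], self.wavelengths[idx], list(self.sample_ids))

    def select_samples(self, idx: np.ndarray) -> "SpectraMatrix":
        idx = np.asarray(idx, dtype=int)
        return SpectraMatrix(
            self.values[idx, :], self.wavelengths, [self.sample_ids[i] for i in idx]
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path, moisture: np.ndarray | None = None) -> None:
        """Write sample_id, optional moisture_pct, then one column per band (nm)."""
        cols: dict[str, object] = {"sample_id": self.sample_ids}
        if moisture is not None:
            cols["moisture_pct"] = np.asarray(moisture, dtype=float)
        for j, wl in enumerate(self.wavelengths):
            cols[f"{wl:.1f}"] = self.values[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> tuple["SpectraMatrix", np.ndarray | None]:
        """Read a spectra CSV; returns the matrix and the moisture vector if present."""
        df = pd.read_csv(path)
        ids = [str(s) for s in df["sample_id"]]
        moisture = None
        band_cols = [c for c in df.columns if c != "sample_id"]
        if "moisture_pct" in df.columns:
            moisture = df["moisture_pct"].to_numpy(dtype=float)
            band_cols.remove("moisture_pct")
        wl = np.array([float(c) for c in band_cols])
        return cls(df[band_cols].to_numpy(dtype=float), wl, ids), moisture
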