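"""SPXY calibration/prediction partitioning.

SPXY extends Kennard-Stone sample selection to a joint distance over spectra
and response: d(i,j) = dx(i,j)/max(dx) + dy(i,j)/max(dy), with dx the
Euclidean distance between spectra and dy = |y_i - y_j|. Selection seeds with
the most distant pair and then repeatedly adds the sample whose minimum
distance to the already-selected set is maximal, so the calibration set
spans the joint X-Y space and its response range covers the prediction
set's. Fully deterministic; ties break to the lowest sample index.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .containers import SpectraMatrix
from .errors import ConfigurationError, DegenerateInputError

__all__ = ["SplitResult", "spxy_split", "random_split"]


@dataclass
class SplitResult:
    """Disjoint calibration/prediction index lists covering all samples."""

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray
    ratio: float

    def to_csv(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        n = len(self.calibration_idx) + len(self.prediction_idx)
        ids = sample_ids if sample_ids is not None else [f"s{i:03d}" for i in range(n)]
        subset = np.array(["prediction"] * n, dtype=object)
        subset[self.calibration_idx] = "calibration"
        pd.DataFrame({"sample_id": ids, "subset": subset}).to_csv(path, index=False)


def _joint_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = squareform(pdist(x, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    dx_max, dy_max = dx.max(), dy.max()
    if dx_max == 0 and dy_max == 0:
        raise DegenerateInputError("all samples identical in X and y")
    d = np.zeros_like(dx)
    if dx_max > 0:
        d += dx / dx_max
    if dy_max > 0:
        d += dy / dy_max
    return d


def spxy_split(
    x: SpectraMatrix | np.ndarray, y: np.ndarray, calib_fraction: float = 0.75
) -> SplitResult:
    """Partition samples with SPXY; calibration size = round(fraction * n)."""
    xv = x.values if isinstance(x, SpectraMatrix) else np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, dtype=float)
    n = xv.shape[0]
    if n < 3:
        raise ConfigurationError("SPXY needs at least 3 samples")
    if not 0 < calib_fraction < 1:
        raise ConfigurationError("calib_fraction must be in (0, 1)")
    if y.shape[0] != n:
        raise ConfigurationError("y length does not match the sample count")

    n_cal = int(round(calib_fraction * n))
    n_cal = min(max(n_cal, 2), n - 1)
    d = _joint_distance(xv, y)

    # seed: the pair with maximal joint distance (ties -> lowest flat index)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)] if i != j else [int(i)]
    remaining = np.setdiff1d(np.arange(n), selected)
    # min distance from each remaining sample to the selected set
    min_d = d[np.ix_(remaining, selected)].min(axis=1)
    while len(selected) < n_cal:
        k = int(np.argmax(min_d))  # argmax returns first max -> lowest index wins
        chosen = int(remaining[k])
        selected.append(chosen)
        remaining = np.delete(remaining, k)
        min_d = np.delete(min_d, k)
        if remaining.size:
            min_d = np.minimum(min_d, d[remaining, chosen])

    cal = np.sort(np.array(selected, dtype=int))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, pred, calib_fraction)


def random_split(
    n: int, calib_fraction: float = 0.75, seed: int = 0
) -> SplitResult:
    """Plain random partition; baseline for comparing against SPXY."""
    if not 0 < calib_fraction < 1:
        raise ConfigurationError("calib_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(round(calib_fraction * n))
    return SplitResult(
        np.sort(perm[:n_cal]), np.sort(perm[n_cal:]), calib_fraction
    )
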