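"""Pixel-wise moisture prediction and pseudo-color rendering.

Every foreground pixel's spectrum is pushed through the *same frozen*
pipeline as the calibration spectra — pretreatment with calibration-set
constants, band restriction, model prediction — giving a moisture map that
is rendered on a fixed 0-12 % color scale so images of different scenes are
directly comparable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import Hypercube, SpectraMatrix
from .errors import ContractError, DegenerateSpectrumError
from .modeling import RegressionModel, predict
from .preprocessing import Preprocessor

__all__ = ["MoistureMap", "predict_map", "render", "save_map_png"]


@dataclass
class MoistureMap:
    """Per-pixel predicted moisture (%); NaN outside the foreground mask."""

    values: np.ndarray
    mask: np.ndarray  # True where defined
    color_range: tuple[float, float] = (0.0, 12.0)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.color_range
        if not lo < hi:
            raise ContractError("color_range lo must be < hi")


def predict_map(
    cube: Hypercube,
    model: RegressionModel,
    preprocessor: Preprocessor,
    selection=None,
    mask: np.ndarray | None = None,
    color_range: tuple[float, float] = (0.0, 12.0),
) -> MoistureMap:
    """Predict moisture for every foreground pixel of a reflectance cube.

    ``cube`` must carry the band axis the preprocessor was fitted on (the
    trimmed analysis axis); ``selection`` (None = full axis) restricts bands
    after pretreatment exactly as during calibration. Pixels whose spectra
    are degenerate under the pretreatment (e.g. constant under SNV) are
    flagged invalid and counted, not fatal.
    """
    if cube.kind != "reflectance":
        raise ContractError("predict_map expects a reflectance cube")
    rows, cols, _ = cube.shape
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    mask = np.asarray(mask) != 0
    if mask.shape != (rows, cols):
        raise ContractError("mask shape does not match the cube")

    values = np.full((rows, cols), np.nan)
    diagnostics: dict = {"n_invalid": 0}
    fg = np.argwhere(mask)
    if fg.size == 0:
        warnings.warn("predict_map: mask has no foreground pixels")
        diagnostics["warning"] = "empty mask"
        return MoistureMap(values, mask, color_range, diagnostics)

    pixels = SpectraMatrix(cube.data[mask], cube.wavelengths)
    try:
        treated = preprocessor.transform(pixels)
        preds = _predict_selected(treated, model, selection)
    except DegenerateSpectrumError:
        # fall back to per-pixel treatment so one bad pixel cannot sink the map
        preds = np.full(pixels.n_samples, np.nan)
        for i in range(pixels.n_samples):
            row = SpectraMatrix(pixels.values[[i]], cube.wavelengths)
            try:
                preds[i] = _predict_selected(preprocessor.transform(row), model, selection)[0]
            except DegenerateSpectrumError:
                diagnostics["n_invalid"] += 1
    values[mask] = preds
    valid = np.isfinite(values)
    out_mask = mask & valid
    diagnostics["n_pixels"] = int(mask.sum())
    return MoistureMap(values, out_mask, color_range, diagnostics)


def _predict_selected(treated: SpectraMatrix, model: RegressionModel, selection):
    if selection is not None:
        treated = treated.select_bands(np.asarray(selection.selected_idx, dtype=int))
    return predict(model, treated)


def render(
    moisture_map: MoistureMap, colormap: str = "jet"
) -> tuple[np.ndarray, int]:
    """Linear pseudo-color rendering; returns (RGB uint8 image, clamp count).

    Map values are mapped linearly from ``color_range`` onto the colormap;
    background pixels render neutral grey; out-of-range values are clamped
    and counted.
    """
    lo, hi = moisture_map.color_range
    vals = moisture_map.values
    mask = moisture_map.mask
    clamped = int(np.sum((vals[mask] < lo) | (vals[mask] > hi)))
    pos = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    cmap = plt.get_cmap(colormap)
    rgb = np.full(vals.shape + (3,), 180, dtype=np.uint8)  # neutral background
    colored = (cmap(pos[mask])[:, :3] * 255).astype(np.uint8)
    rgb[mask] = colored
    return rgb, clamped


def save_map_png(
    moisture_map: MoistureMap, path: str | Path, colormap: str = "jet"
) -> None:
    """Write the rendered map with an annotated color bar (% moisture)."""
    rgb, _ = render(moisture_map, colormap)
    lo, hi = moisture_map.color_range
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(rgb)
    ax.set_axis_off()
    sm = plt.cm.ScalarMappable(
        cmap=plt.get_cmap(colormap), norm=plt.Normalize(vmin=lo, vmax=hi)
    )
    fig.colorbar(sm, ax=ax, label="moisture content (%)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
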