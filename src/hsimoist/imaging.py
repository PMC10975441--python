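"""Reflectance calibration, band trimming, and seed segmentation.

The camera records raw intensity; dividing out white-reference and
dark-current frames yields dimensionless reflectance:

    R = (I_raw - I_dark) / (I_white - I_dark)

Band trimming discards the noisy spectral extremes before chemometrics; the
default window reduces a 256-band acquisition axis to the 218 central bands
(~1065-2432 nm) used throughout the analysis.
"""
from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _label

from .containers import Hypercube, SpectraMatrix
from .errors import CalibrationError, ContractError, RangeError, SegmentationError

__all__ = [
    "reflectance_correct",
    "trim_bands",
    "default_trim",
    "segment_seeds",
    "DEFAULT_TRIM_HEAD",
    "DEFAULT_TRIM_TAIL",
]

# Default trim for a 256-band axis: drop the first 21 and last 17 band
# indices, retaining the 218 central bands.
DEFAULT_TRIM_HEAD = 21
DEFAULT_TRIM_TAIL = 17


def reflectance_correct(
    raw: Hypercube, white: np.ndarray, dark: np.ndarray
) -> Hypercube:
    """Black/white reflectance correction.

    ``white`` and ``dark`` may be full frames (rows x cols x bands) or any
    shape broadcastable to the cube (e.g. a per-band spectrum for a spatially
    flat reference). Requires white > dark wherever used; offending elements
    are an error, never silently clamped — a non-positive denominator flags
    an acquisition fault.
    """
    if raw.kind != "raw":
        raise ContractError("reflectance_correct expects a raw-intensity cube")
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    denom = np.broadcast_to(white - dark, raw.shape)
    bad = int(np.count_nonzero(denom <= 0))
    if bad:
        raise CalibrationError(
            f"white - dark is non-positive at {bad} (pixel, band) elements"
        )
    corrected = (raw.data - dark) / denom
    return Hypercube(corrected, raw.wavelengths, kind="reflectance")


def trim_bands(x, wl_lo: float, wl_hi: float):
    """Retain the bands whose wavelengths lie in the closed [wl_lo, wl_hi].

    Works on :class:`Hypercube` and :class:`SpectraMatrix`; returns the same
    type with the wavelength axis subset.
    """
    if wl_lo >= wl_hi:
        raise RangeError(f"wl_lo ({wl_lo}) must be < wl_hi ({wl_hi})")
    keep = np.flatnonzero((x.wavelengths >= wl_lo) & (x.wavelengths <= wl_hi))
    if keep.size == 0:
        raise RangeError(f"no bands inside [{wl_lo}, {wl_hi}] nm")
    return x.select_bands(keep)


def default_trim(x):
    """Drop the first 21 and last 17 band indices (256 -> 218 bands).

    The noisy head and tail of the acquisition axis are discarded so the
    analysis runs on the 218 central bands. Requires the full 256-band axis.
    """
    n = x.n_bands
    if n != DEFAULT_TRIM_HEAD + 218 + DEFAULT_TRIM_TAIL:
        raise RangeError(
            f"default trim is defined for a 256-band axis, got {n} bands; "
            "use trim_bands(x, wl_lo, wl_hi) instead"
        )
    keep = np.arange(DEFAULT_TRIM_HEAD, n - DEFAULT_TRIM_TAIL)
    return x.select_bands(keep)


def segment_seeds(
    cube: Hypercube,
    contrast_wl: float = 1100.0,
    threshold: str = "otsu",
    min_area: int = 20,
) -> tuple[np.ndarray, SpectraMatrix]:
    """Threshold-and-label seed segmentation; returns one mean spectrum per seed.

    The single-band image nearest ``contrast_wl`` (default 1100 nm: strong
    seed/background contrast, outside the deep water absorption bands) is
    thresholded (Otsu), connected components above ``min_area`` pixels are
    labelled, and the arithmetic mean spectrum of each labelled region forms
    one row of the returned matrix.
    """
    if cube.kind != "reflectance":
        raise ContractError("segment_seeds expects a reflectance cube")
    if threshold != "otsu":
        raise ContractError(f"unknown threshold method {threshold!r}")
    band_img = cube.data[:, :, cube.band_nearest(contrast_wl)]
    try:
        thresh = threshold_otsu(band_img)
    except ValueError as exc:  # constant image
        raise SegmentationError("contrast band image is constant") from exc
    fg = band_img > thresh
    labels = _label(fg, connectivity=2)
    # drop small regions and relabel densely 1..k
    out = np.zeros_like(labels)
    next_label = 0
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if region.sum() >= min_area:
            next_label += 1
            out[region] = next_label
    if next_label == 0:
        raise SegmentationError("no foreground regions above the minimum area")

    spectra = np.empty((next_label, cube.n_bands))
    ids = []
    for lab in range(1, next_label + 1):
        spectra[lab - 1] = cube.data[out == lab].mean(axis=0)
        ids.append(f"seed{lab:02d}")
    return out, SpectraMatrix(spectra, cube.wavelengths, ids)
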