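"""Synthetic NIR hyperspectral seed data with known ground truth.

The generator emulates the statistical structure that seed-moisture
chemometrics assumes: a Beer-Lambert-style absorbance model with water
absorption peaks near 1450 nm (O-H overtone) and 1940 nm (O-H combination
band) whose depth scales linearly with moisture content, wrapped in the
artifacts real reflectance data carries — multiplicative scatter (path-length
variation between kernels), additive baseline offsets, a smooth spectral
baseline, and heteroscedastic detector noise inflated at the spectral
extremes where InGaAs sensitivity falls off.

Per sample i with moisture m_i (% wet basis), at wavelength lambda:

    a_i(lambda) = baseline(lambda) + fixed(lambda)
                  + peak_gain * m_i * sum_k G(lambda; c_k, w_k)

where ``fixed`` collects moisture-independent constituent absorption bands
(C-H overtones and combinations of starch/oil, a starch O-H/C-O band) — as
in real seed spectra, these anchor the per-sample scatter estimate, which is
what makes moisture identifiable under multiplicative/additive scatter; and
the reflectance is
    r_i(lambda) = slope_i * exp(-a_i(lambda)) + offset_i + eps_i(lambda)

with slope_i ~ N(1, scatter_slope_sd), offset_i ~ N(0, scatter_offset_sd),
and eps heteroscedastic (first/last ~15% of bands inflated by
edge_noise_factor). Reflectance is clipped to (0, 1.5]: calibrated
reflectance slightly above 1 does occur in practice and deliberately survives
generation.

Moisture is drawn uniformly over [moisture_min, moisture_max] so the full
calibration range is always covered — sample-set partitioning behaviour is
range-driven.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .containers import Hypercube, SpectraMatrix
from .errors import CapacityError, ConfigurationError

__all__ = [
    "SyntheticConfig",
    "SyntheticScene",
    "generate_spectra",
    "generate_scene",
    "generate_planted_signal",
]

_REFLECTANCE_CEIL = 1.5
_REFLECTANCE_FLOOR = 1e-9


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study conditions.

    Wavelength grid and moisture range follow the acquisition range
    (256 bands over 935.5-2539 nm) and the observed moisture span of the
    80-variety maize sample set (7.377-11.993 % wet basis).
    """

    n_samples: int = 80
    n_bands: int = 256
    wl_start: float = 935.5
    wl_end: float = 2539.0
    moisture_min: float = 7.377
    moisture_max: float = 11.993
    # water features: the 1450 nm O-H overtone region (doublet at 1430/1470,
    # the substructure real water bands show) with its weaker 1190 nm second
    # overtone, and the 1940 nm O-H combination region (1900/1935/1975)
    peak_centers: list[float] = field(
        default_factory=lambda: [1190.0, 1430.0, 1470.0, 1900.0, 1935.0, 1975.0]
    )
    peak_widths: list[float] = field(
        default_factory=lambda: [25.0, 20.0, 20.0, 22.0, 22.0, 22.0]
    )
    peak_gain: float = 0.10  # absorbance units per % moisture
    # moisture-independent constituent bands (center nm, width nm, amplitude):
    # C-H overtones and combinations of starch/oil (~1210, ~1360, ~1725,
    # ~2310), protein N-H (~1530, ~2180), starch O-H/C-O (~2050), and the
    # deep C-H combination shoulder (~2420); together with the rising
    # baseline, the 2420 nm band puts the spectrum's global minimum at the
    # long-wavelength end, as in real seed spectra
    fixed_bands: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (1210.0, 40.0, 0.20),
            (1360.0, 30.0, 0.15),
            (1530.0, 30.0, 0.18),
            (1725.0, 35.0, 0.25),
            (2050.0, 40.0, 0.20),
            (2180.0, 35.0, 0.22),
            (2310.0, 40.0, 0.30),
            (2420.0, 50.0, 0.60),
        ]
    )
    # quartic absorbance baseline: bright, nearly flat plateau at the short
    # end (reflectance slightly above 1, as calibrated data can show) with a
    # steep rise toward 2500 nm
    baseline_coeffs: list[float] = field(
        default_factory=lambda: [-0.07, 0.1, 0.0, 0.0, 2.2]
    )
    # between-sample scatter for dish-mean spectra: averaging over many
    # kernels leaves only a small residual path-length/offset variation
    scatter_slope_sd: float = 0.01
    scatter_offset_sd: float = 0.005
    noise_sd: float = 0.005
    edge_noise_factor: float = 5.0
    # fraction of bands at each spectral extreme carrying inflated noise;
    # the default (~17/256 per side) places the noisy sections inside the
    # region that the default band trim discards, which is the stated reason
    # the trim exists
    edge_fraction: float = 0.066
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_bands < 2:
            raise ConfigurationError("n_bands must be >= 2")
        if not self.wl_start < self.wl_end:
            raise ConfigurationError("wl_start must be < wl_end")
        if not self.moisture_min < self.moisture_max:
            raise ConfigurationError("moisture_min must be < moisture_max")
        if len(self.peak_centers) != len(self.peak_widths):
            raise ConfigurationError("peak_centers and peak_widths lengths differ")
        for c in self.peak_centers:
            if not (self.wl_start <= c <= self.wl_end):
                raise ConfigurationError(
                    f"peak_centers entry {c} outside [wl_start, wl_end]"
                )
        if any(w <= 0 for w in self.peak_widths):
            raise ConfigurationError("peak_widths must be positive")
        if self.peak_gain < 0:
            raise ConfigurationError("peak_gain must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.edge_noise_factor < 1:
            raise ConfigurationError("edge_noise_factor must be >= 1")
        if not 0 <= self.edge_fraction < 0.5:
            raise ConfigurationError("edge_fraction must be in [0, 0.5)")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_end, self.n_bands)

    # ----------------------------------------------------------- serialisation
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticScene:
    """A small imaged scene of seeds on a dark background with ground truth.

    ``raw``/``white_frame``/``dark_frame`` are constructed by inverting the
    black/white reflectance correction, so applying the correction to them
    recovers ``cube`` to numerical precision.
    """

    cube: Hypercube
    raw: Hypercube
    white_frame: np.ndarray
    dark_frame: np.ndarray
    seed_mask: np.ndarray  # integer labels, 0 = background
    truth_map: np.ndarray  # per-pixel moisture %, NaN on background


def _absorbance(config: SyntheticConfig, moisture: np.ndarray) -> np.ndarray:
    """Noise-free absorbance, shape (n, bands), for a moisture vector."""
    wl = config.wavelengths
    t = (wl - config.wl_start) / (config.wl_end - config.wl_start)
    baseline = np.polynomial.polynomial.polyval(t, config.baseline_coeffs)
    for c, w, amp in config.fixed_bands:
        baseline = baseline + amp * np.exp(-0.5 * ((wl - c) / w) ** 2)
    peaks = np.zeros_like(wl)
    for c, w in zip(config.peak_centers, config.peak_widths):
        peaks += np.exp(-0.5 * ((wl - c) / w) ** 2)
    m = np.asarray(moisture, dtype=float).reshape(-1, 1)
    return baseline[None, :] + config.peak_gain * m * peaks[None, :]


def _noise_profile(config: SyntheticConfig) -> np.ndarray:
    """Per-band noise sd: flat in the middle, inflated at the edges."""
    n_edge = int(round(config.edge_fraction * config.n_bands))
    profile = np.full(config.n_bands, config.noise_sd)
    profile[:n_edge] *= config.edge_noise_factor
    profile[config.n_bands - n_edge:] *= config.edge_noise_factor
    return profile


def _reflectance(
    config: SyntheticConfig, moisture: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(moisture)
    a = _absorbance(config, moisture)
    slope = rng.normal(1.0, config.scatter_slope_sd, size=(n, 1))
    offset = rng.normal(0.0, config.scatter_offset_sd, size=(n, 1))
    eps = rng.standard_normal((n, config.n_bands)) * _noise_profile(config)[None, :]
    r = slope * np.exp(-a) + offset + eps
    return np.clip(r, _REFLECTANCE_FLOOR, _REFLECTANCE_CEIL)


def generate_spectra(config: SyntheticConfig) -> tuple[SpectraMatrix, np.ndarray]:
    """Generate per-sample mean spectra and reference moisture values.

    Deterministic for a given config (seeded RNG); moisture values are drawn
    first, then scatter terms, then noise, so noise-free variants of the same
    config share moisture draws.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    moisture = rng.uniform(config.moisture_min, config.moisture_max, config.n_samples)
    values = _reflectance(config, moisture, rng)
    return SpectraMatrix(values, config.wavelengths), moisture


def generate_scene(
    config: SyntheticConfig,
    n_seeds: int,
    image_shape: tuple[int, int],
    within_seed_sd: float = 0.0,
    max_tries: int = 500,
) -> SyntheticScene:
    """Synthesize a hypercube of elliptical "seeds" on a dark background.

    Each seed region carries one moisture value (plus an optional small
    within-seed Gaussian perturbation, clipped to the configured range);
    pixel spectra follow the same generative model as :func:`generate_spectra`.
    Raw intensity frames are built by inverting the reflectance correction
    against a smooth white/dark illumination model.
    """
    config.validate()
    rows, cols = image_shape
    rng = np.random.default_rng(config.seed)

    # --- place non-overlapping ellipses -----------------------------------
    yy, xx = np.mgrid[0:rows, 0:cols]
    seed_mask = np.zeros((rows, cols), dtype=int)
    placed = 0
    tries = 0
    # radii sized so n_seeds can plausibly fit
    base_r = max(3.0, 0.55 * np.sqrt(rows * cols / max(n_seeds, 1)) / 2)
    while placed < n_seeds:
        if tries >= max_tries:
            raise CapacityError(
                f"could not place {n_seeds} seeds on a {rows}x{cols} grid "
                f"after {max_tries} tries ({placed} placed)"
            )
        tries += 1
        ra = base_r * rng.uniform(0.75, 1.1)
        rb = base_r * rng.uniform(0.55, 0.9)
        cy = rng.uniform(ra + 1, rows - ra - 1)
        cx = rng.uniform(rb + 1, cols - rb - 1)
        ellipse = ((yy - cy) / ra) ** 2 + ((xx - cx) / rb) ** 2 <= 1.0
        # demand a 1-px moat so labels stay separable
        dil = ((yy - cy) / (ra + 1.5)) ** 2 + ((xx - cx) / (rb + 1.5)) ** 2 <= 1.0
        if not ellipse.any() or (seed_mask[dil] != 0).any():
            continue
        placed += 1
        seed_mask[ellipse] = placed

    # --- ground-truth moisture per pixel ----------------------------------
    seed_moisture = rng.uniform(config.moisture_min, config.moisture_max, n_seeds)
    truth_map = np.full((rows, cols), np.nan)
    for label in range(1, n_seeds + 1):
        region = seed_mask == label
        m = np.full(region.sum(), seed_moisture[label - 1])
        if within_seed_sd > 0:
            m = m + rng.normal(0.0, within_seed_sd, size=m.size)
            m = np.clip(m, config.moisture_min, config.moisture_max)
        truth_map[region] = m

    # --- pixel spectra ------------------------------------------------------
    n_bands = config.n_bands
    cube = np.empty((rows, cols, n_bands))
    fg = seed_mask > 0
    cube[fg] = _reflectance(config, truth_map[fg], rng)
    n_bg = int((~fg).sum())
    bg_noise = rng.standard_normal((n_bg, n_bands)) * _noise_profile(config)[None, :]
    cube[~fg] = np.clip(0.04 + bg_noise, _REFLECTANCE_FLOOR, _REFLECTANCE_CEIL)
    reflectance = Hypercube(cube, config.wavelengths, kind="reflectance")

    # --- invert the black/white correction to obtain raw frames ------------
    wl01 = (config.wavelengths - config.wl_start) / (config.wl_end - config.wl_start)
    white_spectrum = 3500.0 * (0.75 + 0.25 * np.sin(np.pi * wl01))  # lamp profile
    dark_spectrum = 120.0 + 30.0 * wl01  # dark current drift
    white_frame = np.broadcast_to(white_spectrum, (rows, cols, n_bands)).copy()
    dark_frame = np.broadcast_to(dark_spectrum, (rows, cols, n_bands)).copy()
    raw = dark_frame + cube * (white_frame - dark_frame)
    raw_cube = Hypercube(raw, config.wavelengths, kind="raw")

    return SyntheticScene(
        cube=reflectance,
        raw=raw_cube,
        white_frame=white_frame,
        dark_frame=dark_frame,
        seed_mask=seed_mask,
        truth_map=truth_map,
    )


def generate_planted_signal(
    n_samples: int = 60,
    n_bands: int = 60,
    informative_idx: tuple[int, ...] = (10, 30, 50),
    noise_sd: float = 0.005,
    signal_sd: float = 0.1,
    background_sd: float = 0.03,
    seed: int = 0,
) -> tuple[SpectraMatrix, np.ndarray, np.ndarray]:
    """Benchmark data where y depends on exactly the planted bands.

    Each planted band responds to its own latent analyte component (sd
    ``signal_sd``) — as in spectroscopy, a band is informative because the
    analyte makes it vary — on top of the background fluctuation (sd
    ``background_sd``) every band carries; the response is a fixed linear
    combination of the latent components; measurement noise of sd
    ``noise_sd`` is then added to every band. Used to measure the selection
    sensitivity (planted bands recovered) of the wavelength selectors.

    Returns (spectra, y, informative_idx as array).
    """
    rng = np.random.default_rng(seed)
    informative = np.asarray(informative_idx, dtype=int)
    z = rng.standard_normal((n_samples, len(informative)))
    x = 0.5 + rng.standard_normal((n_samples, n_bands)) * background_sd
    x[:, informative] += signal_sd * z
    x += rng.standard_normal((n_samples, n_bands)) * noise_sd
    coefs = np.linspace(1.0, 0.5, len(informative))
    y = 9.0 + z @ coefs
    wl = np.linspace(1000.0, 2400.0, n_bands)
    return SpectraMatrix(x, wl), y, informative
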