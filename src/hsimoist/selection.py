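"""Wavelength selection: SPA, CARS, and UVE over the calibration set.

SPA (successive projections algorithm) grows chains of mutually
low-collinearity wavelengths: from each candidate start column it repeatedly
adds the column with the largest norm after orthogonal projection away from
the span of those already chosen, then scores every (start, size) subset by
the leave-one-out RMSE of a multiple linear regression and keeps the best.

CARS (competitive adaptive reweighted sampling) runs Monte-Carlo iterations
that fit PLS on random row subsamples, weight wavelengths by absolute
regression coefficient, shrink the retained count along an exponential decay
(EDF), resample survivors with weight-proportional probabilities (ARS), and
keep the iteration subset with minimal k-fold RMSECV.

UVE (uninformative variable elimination) appends an equally wide artificial
noise block, collects PLS coefficient vectors over leave-one-out models, and
keeps the real wavelengths whose coefficient stability (mean/sd across
models) exceeds the most stable noise column — wavelengths no more stable
than noise carry no usable information.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._pls import pls_cv_predictions, pls_fit
from .containers import SpectraMatrix
from .errors import ConfigurationError

__all__ = [
    "SelectionResult",
    "spa_select",
    "cars_select",
    "uve_select",
    "edf_ratio",
    "selected_fraction",
    "loocv_mlr_rmse",
]


@dataclass
class SelectionResult:
    """Selected band indices plus method-specific diagnostics."""

    method: str
    selected_idx: np.ndarray  # sorted, unique, within the band axis
    selected_wl: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected_idx)

    def fraction_pct(self, n_bands: int) -> float:
        return selected_fraction(self.n_selected, n_bands)

    def to_json(self, path: str | Path) -> None:
        """Serialize indices, wavelengths, and diagnostics.

        Large matrix diagnostics (the CARS coefficient paths) stay in
        memory only; scalar traces are rounded to keep files compact.
        """

        def _clean(obj):
            if isinstance(obj, np.ndarray):
                if obj.ndim > 1:
                    return None
                if np.issubdtype(obj.dtype, np.floating):
                    return [round(float(v), 6) for v in obj]
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            if isinstance(obj, dict):
                out = {k: _clean(v) for k, v in obj.items()}
                return {k: v for k, v in out.items() if v is not None}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        payload = {
            "method": self.method,
            "selected_idx": self.selected_idx.tolist(),
            "selected_wl": self.selected_wl.tolist(),
            "diagnostics": _clean(self.diagnostics),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def selected_fraction(n_selected: int, n_bands: int) -> float:
    """Share of the band axis retained, as a percentage with one decimal."""
    return round(100.0 * n_selected / n_bands, 1)


def edf_ratio(i: int, n_bands: int, n_iterations: int) -> float:
    """Exponential-decay retention ratio r_i at CARS iteration i (1-based).

    r_i = mu * exp(-k*i) with mu = (n/2)^(1/(N-1)) and k = ln(n/2)/(N-1),
    so r_1 = 1 (all bands) and r_N = 2/n (two bands survive).
    """
    if n_bands < 2 or n_iterations < 2:
        raise ConfigurationError("EDF requires n_bands >= 2 and n_iterations >= 2")
    mu = (n_bands / 2.0) ** (1.0 / (n_iterations - 1))
    k = np.log(n_bands / 2.0) / (n_iterations - 1)
    return float(mu * np.exp(-k * i))


# --------------------------------------------------------------------- SPA


def loocv_mlr_rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out RMSE of ordinary multiple linear regression.

    Uses the closed form e_loo = e / (1 - h) from the hat matrix of the
    intercept-augmented design; exact, no refitting loop.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    z = np.column_stack([np.ones(len(y)), x])
    # least-squares via economy QR keeps the hat diagonal cheap and stable
    q, r = np.linalg.qr(z)
    coef = np.linalg.lstsq(r, q.T @ y, rcond=None)[0]
    resid = y - z @ coef
    h = np.clip(np.einsum("ij,ij->i", q, q), 0.0, 1.0 - 1e-10)
    e_loo = resid / (1.0 - h)
    return float(np.sqrt(np.mean(e_loo**2)))


def _spa_chain(xc: np.ndarray, start: int, n_max: int) -> np.ndarray:
    """Projection chain from one start column.

    ``xc`` is the column-centred matrix. At each step the remaining columns
    are projected orthogonally to the span of the chosen ones and the column
    of maximal residual norm is added. Truncates if the residual matrix
    degenerates (norm < 1e-12). Ties break to the lowest column index.
    """
    p = xc.shape[1]
    proj = xc.copy()
    chain = [start]
    available = np.ones(p, dtype=bool)
    available[start] = False
    for _ in range(1, n_max):
        v = proj[:, chain[-1]]
        vv = float(v @ v)
        if vv < 1e-12:
            break
        proj = proj - np.outer(v, v @ proj) / vv
        norms = np.linalg.norm(proj, axis=0)
        norms[~available] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < 1e-12:
            break
        chain.append(nxt)
        available[nxt] = False
    return np.array(chain, dtype=int)


def spa_select(
    xcal: SpectraMatrix,
    ycal: np.ndarray,
    n_min: int = 1,
    n_max: int | None = None,
) -> SelectionResult:
    """SPA over all candidate start columns, scored by LOOCV-MLR RMSE.

    Every column serves as a chain start; every prefix of each chain with
    size in [n_min, n_max] is scored; the global RMSE minimum wins (ties:
    fewer bands, then lower start index). Deterministic.
    """
    x = xcal.values
    y = np.asarray(ycal, dtype=float)
    n, p = x.shape
    cap = min(p, n - 1)
    n_max = cap if n_max is None else min(n_max, cap)
    if not 1 <= n_min <= n_max:
        raise ConfigurationError(f"need 1 <= n_min <= n_max (got {n_min}, {n_max})")

    xc = x - x.mean(axis=0)
    best = (np.inf, np.inf, np.inf)  # (rmse, size, start)
    best_subset: np.ndarray | None = None
    rmse_by_size = np.full(n_max + 1, np.inf)
    truncated = []
    for start in range(p):
        chain = _spa_chain(xc, start, n_max)
        if len(chain) < n_max:
            truncated.append((start, len(chain)))
        for size in range(n_min, len(chain) + 1):
            subset = chain[:size]
            score = loocv_mlr_rmse(x[:, subset], y)
            rmse_by_size[size] = min(rmse_by_size[size], score)
            key = (score, size, start)
            if key < best:
                best = key
                best_subset = subset
    assert best_subset is not None
    idx = np.sort(best_subset)
    sizes = np.arange(n_min, n_max + 1)
    return SelectionResult(
        method="spa",
        selected_idx=idx,
        selected_wl=xcal.wavelengths[idx],
        diagnostics={
            "rmse_by_size": rmse_by_size[n_min : n_max + 1],
            "sizes": sizes,
            "best_rmse": best[0],
            "best_size": int(best[1]),
            "best_start": int(best[2]),
            "truncated_chains": truncated,
        },
    )


# --------------------------------------------------------------------- CARS


def cars_select(
    xcal: SpectraMatrix,
    ycal: np.ndarray,
    n_mc: int = 50,
    folds: int = 10,
    seed: int | None = 0,
    max_components: int = 10,
    subsample_fraction: float = 0.8,
) -> SelectionResult:
    """CARS Monte-Carlo wavelength selection (seed-reproducible).

    Defaults follow the study settings: 50 MC iterations, 10-fold RMSECV
    scoring, 80% row subsampling, PLS component count chosen by internal
    minimum RMSECV up to 10.
    """
    if n_mc < 2:
        raise ConfigurationError("n_mc must be >= 2")
    x = xcal.values
    y = np.asarray(ycal, dtype=float)
    n_samples, n_bands = x.shape
    rng = np.random.default_rng(seed)

    retained = np.arange(n_bands)
    subsets: list[np.ndarray] = []
    rmsecv_trace: list[float] = []
    ncomp_trace: list[int] = []
    edf_counts: list[int] = []
    coef_paths = np.zeros((n_mc, n_bands))
    truncated = False

    for i in range(1, n_mc + 1):
        if len(retained) < 2:
            truncated = True
            break
        # PLS weight fit on a random row subsample of the retained bands
        n_sub = max(2, int(round(subsample_fraction * n_samples)))
        rows = rng.choice(n_samples, size=n_sub, replace=False)
        cap = min(max_components, n_sub - 1, len(retained))
        fit = pls_fit(x[np.ix_(rows, retained)], y[rows], cap)
        coefs = fit.coefs[-1]
        coef_paths[i - 1, retained] = coefs
        w = np.abs(coefs)
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()

        # EDF: keep the strongest ceil(r_i * n) bands
        n_keep = max(2, int(np.ceil(edf_ratio(i, n_bands, n_mc) * n_bands)))
        n_keep = min(n_keep, len(retained))
        edf_counts.append(n_keep)
        order = np.argsort(-w, kind="stable")
        kept = retained[order[:n_keep]]
        w_kept = w[order[:n_keep]]

        # ARS: weight-proportional sampling with replacement among survivors
        draws = rng.choice(len(kept), size=n_keep, replace=True, p=w_kept / w_kept.sum())
        retained = np.unique(kept[draws])
        if len(retained) < 2:
            truncated = True
            break
        subsets.append(retained.copy())

        # score the iteration subset by k-fold PLS RMSECV (min over components)
        k = min(folds, n_samples)
        fold_idx = [f for f in np.array_split(rng.permutation(n_samples), k)]
        cap = min(max_components, len(retained), n_samples - max(len(f) for f in fold_idx) - 1)
        cap = max(cap, 1)
        preds = pls_cv_predictions(x[:, retained], y, cap, fold_idx)
        errs = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
        best_a = int(np.argmin(errs))
        rmsecv_trace.append(float(errs[best_a]))
        ncomp_trace.append(best_a + 1)

    if not subsets:
        raise ConfigurationError("CARS terminated before completing any iteration")
    best_iter = int(np.argmin(rmsecv_trace))
    idx = np.sort(subsets[best_iter])
    return SelectionResult(
        method="cars",
        selected_idx=idx,
        selected_wl=xcal.wavelengths[idx],
        diagnostics={
            "rmsecv": np.array(rmsecv_trace),
            "n_components": np.array(ncomp_trace),
            "edf_counts": np.array(edf_counts),
            "retained_counts": np.array([len(s) for s in subsets]),
            "coef_paths": coef_paths,
            "best_iteration": best_iter + 1,
            "truncated": truncated,
        },
    )


# ---------------------------------------------------------------------- UVE


def uve_select(
    xcal: SpectraMatrix,
    ycal: np.ndarray,
    n_latent: int = 12,
    noise_scale: float = 1e-10,
    seed: int | None = 0,
) -> SelectionResult:
    """UVE with leave-one-out PLS coefficient stability.

    A uniform-[0,1] noise block scaled by ``noise_scale`` (default tiny, so
    it defines the cutoff without perturbing the fit) is appended to X; the
    stability of each column is mean/sd of its coefficient across the n
    leave-one-out PLS models; real columns whose |stability| exceeds the
    largest noise-column |stability| are selected.
    """
    x = xcal.values
    y = np.asarray(ycal, dtype=float)
    n, p = x.shape
    if n_latent > n - 2:
        raise ConfigurationError("n_latent must be <= calibration samples - 2")
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.0, 1.0, size=(n, p)) * noise_scale
    xg = np.concatenate([x, g], axis=1)

    b = np.empty((n, 2 * p))
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        fit = pls_fit(xg[keep], y[keep], n_latent)
        b[i] = fit.coefs[-1]

    mean_b = b.mean(axis=0)
    sd_b = b.std(axis=0, ddof=1)
    zero_sd = sd_b < 1e-300
    stability = np.empty(2 * p)
    with np.errstate(divide="ignore", invalid="ignore"):
        stability[~zero_sd] = mean_b[~zero_sd] / sd_b[~zero_sd]
    stability[zero_sd] = np.inf

    c_max = float(np.max(np.abs(stability[p:])))
    selected = np.flatnonzero(np.abs(stability[:p]) > c_max)
    return SelectionResult(
        method="uve",
        selected_idx=selected,
        selected_wl=xcal.wavelengths[selected],
        diagnostics={
            "stability": stability,
            "threshold": c_max,
            "n_latent": n_latent,
            "zero_sd_columns": np.flatnonzero(zero_sd),
        },
    )
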