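"""NIPALS partial-least-squares core (PLS1, mean-centred, unscaled).

One NIPALS pass yields the regression coefficient vector for *every*
component count up to the requested maximum, which makes cross-validated
component selection cheap: one fit per fold covers the whole grid.
Deterministic (no RNG): deflation-based with a fixed deflation order.
"""
from __future__ import annotations

import numpy as np

__all__ = ["PLSCoefficients", "pls_fit", "pls_cv_predictions"]

_EPS = 1e-12


class PLSCoefficients:
    """Coefficient paths B_1..B_A plus centring constants.

    ``coefs[a-1]`` is the coefficient vector of the a-component model on the
    original (uncentred) X scale; ``n_components`` may be less than requested
    if deflation exhausted the covariance.
    """

    def __init__(self, coefs: np.ndarray, x_mean: np.ndarray, y_mean: float):
        self.coefs = coefs
        self.x_mean = x_mean
        self.y_mean = y_mean
        self.n_components = coefs.shape[0]

    def predict(self, x: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predictions of the ``n_components``-component model (default: max)."""
        a = self.n_components if n_components is None else n_components
        b = self.coefs[a - 1]
        return (np.asarray(x, float) - self.x_mean) @ b + self.y_mean

    def predict_all(self, x: np.ndarray) -> np.ndarray:
        """Predictions for every component count; shape (n, A)."""
        return (np.asarray(x, float) - self.x_mean) @ self.coefs.T + self.y_mean


def pls_fit(x: np.ndarray, y: np.ndarray, n_components: int) -> PLSCoefficients:
    """PLS1 via NIPALS; returns coefficient paths for 1..n_components."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    a_max = min(n_components, n - 1, p)
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xd = x - x_mean
    yd = y - y_mean

    ws, ps, qs = [], [], []
    for _ in range(a_max):
        w = xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < _EPS:
            break
        w /= norm
        t = xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        p_load = xd.T @ t / tt
        q = float(yd @ t / tt)
        ws.append(w)
        ps.append(p_load)
        qs.append(q)
        xd = xd - np.outer(t, p_load)
        yd = yd - q * t

    a = len(ws)
    if a == 0:
        # y uncorrelated with X: the 0-component model (mean only)
        return PLSCoefficients(np.zeros((1, p)), x_mean, y_mean)
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    q_vec = np.array(qs)
    coefs = np.empty((a, p))
    for k in range(1, a + 1):
        r = np.linalg.solve(p_mat[:, :k].T @ w_mat[:, :k], q_vec[:k])
        coefs[k - 1] = w_mat[:, :k] @ r
    return PLSCoefficients(coefs, x_mean, y_mean)


def pls_cv_predictions(
    x: np.ndarray, y: np.ndarray, n_components: int, folds: list[np.ndarray]
) -> np.ndarray:
    """Out-of-fold predictions for every component count; shape (n, A).

    ``folds`` is a list of held-out index arrays partitioning the samples.
    When deflation truncates a fold below the requested count, the last
    achievable model fills the remaining columns (the coefficient path is
    constant past exhaustion).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    preds = np.empty((n, n_components))
    all_idx = np.arange(n)
    for held in folds:
        train = np.setdiff1d(all_idx, held)
        fit = pls_fit(x[train], y[train], n_components)
        block = fit.predict_all(x[held])
        if block.shape[1] < n_components:
            pad = np.repeat(block[:, [-1]], n_components - block.shape[1], axis=1)
            block = np.concatenate([block, pad], axis=1)
        preds[held] = block
    return preds
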