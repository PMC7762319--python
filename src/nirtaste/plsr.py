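"""Partial least squares regression (univariate-response NIPALS).

The statistical baseline calibration: latent components are extracted to
maximise covariance between the (mean-centred) spectra and the response,
and the regression vector is reconstructed from the weights/loadings so
that prediction is a single affine map.  X columns are mean-centred but not
variance-scaled (spectral channels share units); y is mean-centred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateInputError, ShapeError

__all__ = ["PLSRModel", "fit_plsr", "predict_plsr", "select_ncomp"]


@dataclass
class PLSRModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # W, p x a, unit-norm columns
    x_loadings: np.ndarray  # P, p x a
    y_loadings: np.ndarray  # q, a
    scores: np.ndarray      # T, n x a (training scores, kept for diagnostics)
    coef: np.ndarray        # b, p
    intercept: float


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRModel:
    """Fit PLS1 by NIPALS with deflation of X only.

    ``n_components`` may not exceed ``min(n_samples - 1, n_features)``.
    Components whose residual covariance with y vanishes terminate the
    extraction early (the model then has fewer live components, with zero
    loadings beyond).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ShapeError("X must be 2-D with one row per y entry")
    n, p = X.shape
    if n < 2:
        raise ConfigError("need at least 2 samples")
    max_comp = min(n - 1, p)
    if not 0 <= n_components <= max_comp:
        raise ConfigError(
            f"n_components must be in [0, {max_comp}] for shape {X.shape}, got {n_components}"
        )
    if np.ptp(y) == 0:
        raise DegenerateInputError("y has zero variance; PLSR undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break  # no covariance left to extract
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
        T[:, a] = t

    # b = W (P^T W)^{-1} q in centred space; with dead trailing components
    # the corresponding rows/cols are zero, so restrict to the live block.
    live = np.flatnonzero(np.linalg.norm(W, axis=0) > 0)
    if live.size:
        Wl, Pl, ql = W[:, live], P[:, live], q[live]
        coef = Wl @ np.linalg.solve(Pl.T @ Wl, ql)
    else:
        coef = np.zeros(p)
    return PLSRModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        intercept=y_mean,
    )


def predict_plsr(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.x_mean.size:
        raise ShapeError(f"expected shape (n, {model.x_mean.size}), got {X.shape}")
    return (X - model.x_mean) @ model.coef + model.intercept


def select_ncomp(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_comp: int = 10,
) -> int:
    """Component count minimising validation MSE; ties go to the smaller count."""
    X_train = np.asarray(X_train, dtype=float)
    n, p = X_train.shape
    cap = min(max_comp, n - 1, p)
    if cap < 1:
        raise ConfigError("cannot select components: data too small")
    best = (np.inf, 1)
    for a in range(1, cap + 1):
        model = fit_plsr(X_train, y_train, a)
        mse = float(np.mean((predict_plsr(model, X_val) - np.asarray(y_val).ravel()) ** 2))
        if mse < best[0]:
            best = (mse, a)
    return best[1]
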