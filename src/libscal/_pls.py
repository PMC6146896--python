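"""Vectorised single-response PLS used by the cross-validated scorers.

Interval selection scores hundreds of candidate channel blocks by
leave-one-out RMSECV, so the hot path needs a PLS1 fit that returns the
coefficient path for every latent-variable count in one pass.  This is
plain NIPALS with the standard triangular-solve recovery of regression
coefficients; the test suite pins its predictions to scikit-learn's
``PLSRegression`` to machine precision.
"""
from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

__all__ = ["pls1_coef_path", "predict_path", "loo_rmsecv_path"]


def pls1_coef_path(X: np.ndarray, y: np.ndarray, max_lv: int):
    """Fit PLS1 and return the coefficient path.

    Returns ``(B, x_mean, y_mean)`` where column ``a`` of ``B`` holds the
    regression coefficients of the centred model with ``a + 1`` latent
    variables.  Fewer columns are returned when the deflated matrix runs
    out of rank before ``max_lv``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must be a length-n vector")
    if not 1 <= max_lv <= min(n - 1, p):
        raise ValueError(f"max_lv must lie in [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = np.linalg.norm(Xc) * max(np.linalg.norm(yc), 1.0) + np.finfo(float).tiny

    W, P, Q = [], [], []
    for _ in range(max_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-13 * scale:
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-13:
            break
        pl = Xc.T @ t / tt
        q = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pl)
        yc = yc - q * t
        W.append(w)
        P.append(pl)
        Q.append(q)

    if not W:
        return np.zeros((p, 0)), x_mean, y_mean
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    q = np.array(Q)
    # P'W is unit upper triangular for NIPALS PLS1.
    M = Pm.T @ Wm
    R = Wm @ solve_triangular(M, np.eye(len(W)), lower=False)
    B = np.cumsum(R * q[None, :], axis=1)
    return B, x_mean, y_mean


def predict_path(B, x_mean, y_mean, Xnew: np.ndarray) -> np.ndarray:
    """Predictions for every latent-variable count; shape ``(n_new, a)``."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if B.shape[1] == 0:
        return np.full((Xnew.shape[0], 1), y_mean)
    return (Xnew - x_mean) @ B + y_mean


def loo_rmsecv_path(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """Leave-one-out RMSECV for 1..max_lv latent variables.

    When a fold's deflation exhausts rank early, the last available
    component's prediction stands in for the missing ones (the model
    cannot grow further), keeping the path length uniform across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out scoring needs at least 3 samples")
    if not 1 <= max_lv <= min(n - 2, X.shape[1]):
        raise ValueError(f"max_lv must lie in [1, {min(n - 2, X.shape[1])}]")
    errs = np.empty((n, max_lv))
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        B, xm, ym = pls1_coef_path(X[rest], y[rest], max_lv)
        pred = predict_path(B, xm, ym, X[i : i + 1])[0]
        if pred.size < max_lv:
            pred = np.concatenate([pred, np.full(max_lv - pred.size, pred[-1])])
        errs[i] = pred - y[i]
    return np.sqrt(np.mean(errs**2, axis=0))
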