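"""Multivariate calibration models and figures of merit.

PLS regression (latent-variable count chosen by leave-one-out
cross-validation) and epsilon-insensitive RBF support-vector regression
on principal components (hyperparameters chosen by seeded fivefold
cross-validation) — plus the four standard metrics: R^2 and RMSE on the
calibration side (cross-validated) and on the held-out prediction set.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import _pls

__all__ = [
    "Metrics",
    "CalibrationModel",
    "rmse",
    "r_squared",
    "fit_pls",
    "choose_lv_loocv",
    "fit_pls_loocv",
    "fit_svm_pcs",
    "evaluate",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_EPSILON_GRID",
]

DEFAULT_C_GRID = (1.0, 10.0, 100.0, 1000.0)
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-8, 3, 2))
DEFAULT_EPSILON_GRID = (0.01, 0.1)


def rmse(predicted, observed) -> float:
    """Root mean square difference, in concentration units."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size == 0 or p.size != o.size:
        raise ValueError("predicted and observed must be equal nonzero lengths")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(predicted, observed) -> float:
    """Coefficient of determination, 1 - SSE/SST about the observed mean.

    May be negative for predictions worse than the mean.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise ValueError("length mismatch")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance")
    return 1.0 - float(np.sum((p - o) ** 2)) / sst


@dataclass
class Metrics:
    """Calibration-set and prediction-set figures of merit."""

    r2_cal: float
    rmsecv: float
    r2_pred: float
    rmsep: float

    def as_dict(self) -> dict[str, float]:
        return {
            "r2_cal": self.r2_cal,
            "rmsecv": self.rmsecv,
            "r2_pred": self.r2_pred,
            "rmsep": self.rmsep,
        }


@dataclass
class CalibrationModel:
    """A fitted predictor with its training metadata.

    ``estimator`` exposes scikit-learn's ``predict``; ``rmsecv`` is the
    cross-validated calibration error under ``cv_scheme``.
    """

    kind: str
    estimator: Any
    n_factors: int
    rmsecv: float
    cv_scheme: str
    channels: Optional[np.ndarray] = None
    seed: Optional[int] = None
    params: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.asarray(self.estimator.predict(X)).ravel()


def fit_pls(X, y, n_lv: int) -> CalibrationModel:
    """Centred single-response PLS regression with ``n_lv`` latent
    variables (no per-channel scaling; intensities share units)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    bound = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_lv <= bound:
        raise ValueError(f"n_lv must lie in [1, {bound}]")
    est = PLSRegression(n_components=n_lv, scale=False)
    est.fit(X, y)
    return CalibrationModel(
        kind="pls",
        estimator=est,
        n_factors=n_lv,
        rmsecv=float("nan"),
        cv_scheme="none",
    )


def choose_lv_loocv(X, y, max_lv: int) -> tuple[int, float, np.ndarray]:
    """Latent-variable count minimising leave-one-out RMSECV.

    Returns ``(n_lv, rmsecv, path)`` where ``path[a-1]`` is the RMSECV
    at ``a`` latent variables; ties go to fewer latent variables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    path = _pls.loo_rmsecv_path(X, y, max_lv)
    best = int(np.argmin(path))
    return best + 1, float(path[best]), path


def fit_pls_loocv(X, y, max_lv: int) -> CalibrationModel:
    """PLS with the latent-variable count chosen by leave-one-out CV."""
    n_lv, score, path = choose_lv_loocv(X, y, max_lv)
    model = fit_pls(X, y, n_lv)
    model.rmsecv = score
    model.cv_scheme = "leave-one-out"
    model.params["rmsecv_path"] = path
    return model


def fit_svm_pcs(
    X,
    y,
    n_pcs: Optional[int] = None,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    epsilon_grid=DEFAULT_EPSILON_GRID,
    seed: int = 0,
    max_pcs: int = 13,
    n_folds: int = 5,
) -> CalibrationModel:
    """RBF support-vector regression on principal components.

    The spectra are mean-centred and projected onto the top principal
    components (loadings fitted on the calibration data only), the
    scores standardised, and fed to an epsilon-insensitive RBF SVR.  Cost, kernel width, epsilon —
    and the component count when ``n_pcs`` is None, capped at
    ``max_pcs`` — are chosen by seeded ``n_folds``-fold CV RMSE over the
    grid.  The reported RMSECV is the winning fold-mean (the tuning and
    reporting folds coincide, an optimistic estimate).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples")
    if not (len(c_grid) and len(gamma_grid) and len(epsilon_grid)):
        raise ValueError("hyperparameter grids must be nonempty")
    min_train = n - math.ceil(n / n_folds)
    bound = min(max_pcs, X.shape[1], min_train)
    if n_pcs is not None:
        if not 1 <= n_pcs <= min(X.shape[0], X.shape[1]):
            raise ValueError("n_pcs out of range")
        pc_candidates = [n_pcs]
    else:
        pc_candidates = list(range(1, bound + 1))

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))

    def make_pipe(npc, C, g, e):
        # intensities share units, so the PCA is on mean-centred (not
        # autoscaled) spectra, as in PLS; standardising the scores then
        # keeps the RBF length scale comparable across component counts
        return Pipeline(
            [
                ("pca", PCA(n_components=npc, svd_solver="full")),
                ("pc_scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=C, gamma=g, epsilon=e)),
            ]
        )

    best = None  # (cv_rmse, npc, C, g, e)
    for npc in pc_candidates:
        for C in c_grid:
            for g in gamma_grid:
                for e in epsilon_grid:
                    sq = 0.0
                    for tr, te in folds:
                        pipe = make_pipe(npc, C, g, e)
                        pipe.fit(X[tr], y[tr])
                        err = pipe.predict(X[te]) - y[te]
                        sq += float(err @ err)
                    cv_rmse = math.sqrt(sq / n)
                    if best is None or cv_rmse < best[0]:
                        best = (cv_rmse, npc, C, g, e)
    cv_rmse, npc, C, g, e = best
    final = make_pipe(npc, C, g, e)
    final.fit(X, y)
    return CalibrationModel(
        kind="svm",
        estimator=final,
        n_factors=npc,
        rmsecv=cv_rmse,
        cv_scheme=f"{n_folds}-fold",
        seed=seed,
        params={"C": C, "gamma": g, "epsilon": e},
    )


def evaluate(
    model: CalibrationModel, X_cal, y_cal, X_pred, y_pred
) -> Metrics:
    """All four figures of merit for a fitted model.

    R^2c comes from the fitted values on the calibration set, RMSECV
    from the model's own cross-validation scheme, R^2p and RMSEP from
    the held-out prediction set.
    """
    y_cal = np.asarray(y_cal, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    fit_cal = model.predict(X_cal)
    fit_pred = model.predict(X_pred)
    return Metrics(
        r2_cal=r_squared(fit_cal, y_cal),
        rmsecv=model.rmsecv,
        r2_pred=r_squared(fit_pred, y_pred),
        rmsep=rmse(fit_pred, y_pred),
    )
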