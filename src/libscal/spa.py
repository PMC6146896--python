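"""Successive projections algorithm (SPA).

Greedy selection of a minimally collinear channel subset: starting from
a seed column, each step adds the candidate whose residual after
orthogonal projection onto the span of the already-selected columns has
the largest norm.  Chains are grown from every candidate start; each
chain prefix is scored by the leave-one-out RMSECV of an ordinary
least-squares fit on the calibration samples, and the globally best
prefix wins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .intervals import SelectionResult, wavelength_ranges

__all__ = ["SpaChain", "spa_chain", "spa_select", "ols_loo_rmsecv"]

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class SpaChain:
    """One greedy projection chain.

    ``selected`` lists column indices in pick order (starting column
    first); ``projection_norms`` holds each pick's residual norm at its
    step (columns are mean-centred and unit-norm scaled beforehand, so
    the starting norm is 1 for any non-constant column).
    """

    start: int
    selected: tuple[int, ...]
    projection_norms: tuple[float, ...]


def _prepare_columns(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    norms[norms == 0] = 1.0
    return Xc / norms


def spa_chain(X: np.ndarray, start: int, p_max: int) -> SpaChain:
    """Grow one projection chain of length ``p_max`` from column ``start``.

    Columns are centred and scaled to unit norm before projecting.  Ties
    in the residual norm break toward the lowest column index; columns
    that are (numerically) linear combinations of the selected set are
    never picked while independent candidates remain.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not 0 <= start < m:
        raise ValueError("start column out of range")
    if not 1 <= p_max <= min(n - 1, m):
        raise ValueError(f"p_max must lie in [1, {min(n - 1, m)}]")
    V = _prepare_columns(X)
    selected = [start]
    norms = [float(np.linalg.norm(V[:, start]))]
    for _ in range(p_max - 1):
        r = V[:, selected[-1]]
        rr = float(r @ r)
        if rr <= _RANK_TOL:
            break  # chain exhausted the space
        V = V - np.outer(r, r @ V) / rr
        res = np.linalg.norm(V, axis=0)
        res[selected] = -1.0
        pick = int(np.argmax(res))
        if res[pick] <= _RANK_TOL:
            break
        selected.append(pick)
        norms.append(float(res[pick]))
    return SpaChain(start, tuple(selected), tuple(norms))


def ols_loo_rmsecv(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out RMSECV of an intercept-augmented OLS fit, by the
    closed-form leverage identity ``e_i / (1 - h_ii)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == X.size:
        X = X.reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    n = y.size
    A = np.column_stack([np.ones(n), X])
    # Pseudo-inverse keeps near-collinear prefixes finite and scored.
    pinv = np.linalg.pinv(A, rcond=1e-12)
    h = np.einsum("ij,ji->i", A, pinv)
    resid = y - A @ (pinv @ y)
    denom = 1.0 - h
    if np.any(denom <= 1e-10):
        return float("inf")  # a sample its own sole support: no honest CV
    loo = resid / denom
    return float(np.sqrt(np.mean(loo**2)))


def spa_select(
    data: SpectralDataset, candidates, p_max: int = 30
) -> SelectionResult:
    """Run SPA over a candidate channel set of the calibration data.

    Chains are grown from every candidate start and every prefix length
    from 1 to ``p_max`` is scored; the prefix with the smallest RMSECV
    is returned (ties toward fewer channels, then the earlier start).
    """
    candidates = np.unique(np.asarray(candidates, dtype=int))
    if candidates.size == 0:
        raise ValueError("candidate set must be nonempty")
    n = data.n
    p_eff = min(p_max, n - 2, candidates.size)
    if p_eff < 1:
        raise ValueError("too few calibration samples for SPA scoring")
    X = data.intensities[:, candidates]
    y = data.reference
    records = []
    best = None  # (score, n_sel, start, prefix columns)
    for si in range(candidates.size):
        chain = spa_chain(X, si, p_eff)
        for j in range(1, len(chain.selected) + 1):
            cols = list(chain.selected[:j])
            score = ols_loo_rmsecv(X[:, cols], y)
            records.append((int(candidates[si]), j, score))
            key = (score, j, si)
            if best is None or key < best[0]:
                best = (key, cols)
    (score, j, _), cols = best
    ch = candidates[cols]
    ledger = pd.DataFrame(records, columns=["start_channel", "n_selected", "rmsecv"])
    return SelectionResult(
        ch, wavelength_ranges(data.wavelengths, ch), None, score, j, ledger
    )
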