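"""Single-line calibration curves and intensity-ratio indices.

Univariate calibration relates the intensity of one emission line (or a
ratio index built from several) to the reference concentration by
ordinary least squares.  The two ratio indices use a strong, stable line
at 466.23 nm as an internal standard: because shot-to-shot fluctuation
multiplies every line of a spectrum by the same factor, dividing by a
line that carries no analyte signal cancels that fluctuation:

    index1 = (I_508.58 + I_361.05) / (2 * I_466.23)
    index2 = I_508.58 / I_466.23
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel, Metrics, r_squared, rmse
from .dataset import SpectralDataset
from .preprocess import SplitResult
from .simulate import Spectrum

__all__ = [
    "CatalogLine",
    "LineCatalog",
    "default_catalog",
    "CD_LINES_NM",
    "line_intensity",
    "index1",
    "index2",
    "fit_univariate",
    "lines_in_ranges",
    "univariate_report",
]

# The ten Cd I lines inside the iPLS/BiPLS-selected intervals.
CD_LINES_NM = (
    326.10,
    340.36,
    346.61,
    361.05,
    361.28,
    361.44,
    466.23,
    467.81,
    508.58,
    643.84,
)

_MATRIX_LINES = (
    ("C", 247.86),
    ("Mg", 279.55),
    ("Mg", 279.80),
    ("Mg", 383.82),
    ("Mg", 516.73),
    ("Ca", 373.69),
    ("Ca", 397.37),
    ("Ca", 422.67),
    ("Ca", 558.90),
    ("Ca", 643.91),
    ("Ca", 644.98),
    ("Ca", 849.80),
    ("Ca", 866.21),
    ("Cu", 324.75),
    ("Cu", 327.40),
    ("CN", 393.37),
    ("CN", 396.85),
    ("Na", 589.00),
    ("Na", 589.59),
    ("K", 766.49),
    ("K", 769.90),
)


@dataclass(frozen=True)
class CatalogLine:
    element: str
    nm: float

    def __post_init__(self) -> None:
        if self.nm <= 0:
            raise ValueError("wavelength must be positive")


@dataclass(frozen=True)
class LineCatalog:
    """Unique (element, wavelength) entries."""

    entries: tuple[CatalogLine, ...]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.element, e.nm)
            if key in seen:
                raise ValueError(f"duplicate catalog entry {key}")
            seen.add(key)

    def of_element(self, element: str) -> "LineCatalog":
        return LineCatalog(tuple(e for e in self.entries if e.element == element))


def default_catalog() -> LineCatalog:
    """Ten Cd I lines plus the strong matrix lines of root tissue."""
    entries = [CatalogLine("Cd", nm) for nm in CD_LINES_NM]
    entries += [CatalogLine(el, nm) for el, nm in _MATRIX_LINES]
    return LineCatalog(tuple(entries))


def line_intensity(
    spectrum: Spectrum,
    line_nm: float,
    mode: str = "nearest",
    window: float = 0.15,
) -> float:
    """Read one line's intensity off a spectrum.

    ``nearest`` takes the channel closest in wavelength; ``window_max``
    takes the maximum within ``+/- window`` nm, which tolerates small
    wavelength offsets between the catalog and the instrument axis.
    """
    w = spectrum.wavelengths
    if not (w[0] <= line_nm <= w[-1]):
        raise ValueError(f"{line_nm} nm is outside the spectral axis")
    if mode == "nearest":
        return float(spectrum.intensities[np.argmin(np.abs(w - line_nm))])
    if mode == "window_max":
        mask = np.abs(w - line_nm) <= window
        if not mask.any():
            mask = np.abs(w - line_nm) <= np.min(np.abs(w - line_nm))
        return float(spectrum.intensities[mask].max())
    raise ValueError("mode must be 'nearest' or 'window_max'")


def dataset_line_intensity(
    data: SpectralDataset, line_nm: float, mode: str = "nearest", window: float = 0.15
) -> np.ndarray:
    """Per-sample line intensities over a whole dataset."""
    return np.array(
        [
            line_intensity(
                Spectrum(data.wavelengths, data.intensities[i], data.ids[i]),
                line_nm,
                mode,
                window,
            )
            for i in range(data.n)
        ]
    )


def index1(i508: float, i361: float, i466: float):
    """(I_508.58 + I_361.05) / (2 * I_466.23); invariant to a common
    multiplicative factor on all three intensities."""
    i466 = np.asarray(i466, dtype=float)
    if np.any(i466 <= 0):
        raise ValueError("denominator intensity must be > 0")
    out = (np.asarray(i508, dtype=float) + np.asarray(i361, dtype=float)) / (2.0 * i466)
    return float(out) if out.ndim == 0 else out


def index2(i508: float, i466: float):
    """I_508.58 / I_466.23."""
    i466 = np.asarray(i466, dtype=float)
    if np.any(i466 <= 0):
        raise ValueError("denominator intensity must be > 0")
    out = np.asarray(i508, dtype=float) / i466
    return float(out) if out.ndim == 0 else out


class _Affine:
    """concentration = slope * predictor + intercept."""

    def __init__(self, slope: float, intercept: float):
        self.slope = float(slope)
        self.intercept = float(intercept)

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return self.slope * x + self.intercept


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _loo_rmsecv_line(x: np.ndarray, y: np.ndarray) -> float:
    # Closed-form leave-one-out for simple linear regression.
    n = x.size
    slope, intercept = _ols_line(x, y)
    resid = y - (slope * x + intercept)
    sxx = float(np.sum((x - x.mean()) ** 2))
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    return float(np.sqrt(np.mean((resid / (1.0 - h)) ** 2)))


def fit_univariate(
    predictor, reference, split: SplitResult
) -> tuple[CalibrationModel, Metrics]:
    """Calibration curve from one scalar predictor per sample.

    Fits concentration = a * predictor + b on the calibration samples,
    scores RMSECV by leave-one-out, and evaluates R^2p / RMSEP on the
    prediction samples.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(reference, dtype=float)
    xc, yc = x[split.calibration], y[split.calibration]
    xp, yp = x[split.prediction], y[split.prediction]
    if xc.size < 3:
        raise ValueError("need at least 3 calibration samples")
    if np.ptp(xc) == 0:
        raise ValueError("predictor has zero variance on the calibration set")
    slope, intercept = _ols_line(xc, yc)
    model = CalibrationModel(
        kind="univariate",
        estimator=_Affine(slope, intercept),
        n_factors=1,
        rmsecv=_loo_rmsecv_line(xc, yc),
        cv_scheme="leave-one-out",
        params={"slope": slope, "intercept": intercept},
    )
    fit_c = model.estimator.predict(xc)
    fit_p = model.estimator.predict(xp)
    metrics = Metrics(
        r2_cal=r_squared(fit_c, yc),
        rmsecv=model.rmsecv,
        r2_pred=r_squared(fit_p, yp),
        rmsep=rmse(fit_p, yp),
    )
    return model, metrics


def lines_in_ranges(catalog: LineCatalog, ranges) -> LineCatalog:
    """Catalog subset whose wavelengths fall in any of the closed
    ``[low, high]`` nm ranges."""
    kept = tuple(
        e
        for e in catalog.entries
        if any(lo <= e.nm <= hi for lo, hi in ranges)
    )
    return LineCatalog(kept)


def univariate_report(
    data: SpectralDataset,
    split: SplitResult,
    lines,
    mode: str = "nearest",
    window: float = 0.15,
) -> pd.DataFrame:
    """One calibration row per emission line: nm, R^2c, RMSECV, R^2p, RMSEP."""
    rows = []
    for nm in lines:
        nm = float(nm)
        x = dataset_line_intensity(data, nm, mode, window)
        _, m = fit_univariate(x, data.reference, split)
        rows.append((nm, m.r2_cal, m.rmsecv, m.r2_pred, m.rmsep))
    return pd.DataFrame(
        rows, columns=["line_nm", "r2_cal", "rmsecv", "r2_pred", "rmsep"]
    )
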