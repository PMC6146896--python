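"""Wavelet denoising and the rank-ordered calibration/prediction split."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .dataset import SpectralDataset

__all__ = [
    "wavelet_denoise",
    "denoise_dataset",
    "SplitResult",
    "split_rank_ordered",
    "write_split",
    "read_split",
]

DEFAULT_WAVELET = "db6"
DEFAULT_LEVEL = 3


def _check_level(n: int, wavelet: pywt.Wavelet, level: int) -> None:
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    if n < wavelet.dec_len:
        raise ValueError("signal shorter than the wavelet filter support")
    max_level = pywt.dwt_max_level(n, wavelet.dec_len)
    if level > max_level:
        raise ValueError(
            f"level {level} too deep for length {n} (max {max_level})"
        )


def _soft(d: np.ndarray, thr: np.ndarray) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - thr, 0.0)


def _denoise_rows(
    X: np.ndarray, wavelet: str, level: int
) -> np.ndarray:
    """Row-wise multilevel soft thresholding (universal threshold with a
    per-row, per-level MAD noise estimate; symmetric boundary extension)."""
    w = pywt.Wavelet(wavelet)
    p = X.shape[-1]
    _check_level(p, w, level)
    coeffs = pywt.wavedec(X, w, level=level, mode="symmetric", axis=-1)
    out = [coeffs[0]]
    for d in coeffs[1:]:
        sigma = np.median(np.abs(d), axis=-1, keepdims=True) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(p))
        out.append(_soft(d, thr))
    rec = pywt.waverec(out, w, mode="symmetric", axis=-1)
    return rec[..., :p]


def wavelet_denoise(
    signal, wavelet: str = DEFAULT_WAVELET, level: int = DEFAULT_LEVEL
) -> np.ndarray:
    """Denoise one spectrum by wavelet detail thresholding.

    Decomposes with the given wavelet (Daubechies 6 by default, level 3),
    soft-thresholds each detail band at the universal threshold
    ``sigma * sqrt(2 log n)`` with ``sigma`` estimated per band from the
    median absolute deviation, and reconstructs to the original length.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional signal")
    return _denoise_rows(x[None, :], wavelet, level)[0]


def denoise_dataset(
    data: SpectralDataset,
    wavelet: str = DEFAULT_WAVELET,
    level: int = DEFAULT_LEVEL,
) -> SpectralDataset:
    """Row-wise wavelet denoising; axis, reference and ids pass through."""
    return SpectralDataset(
        data.wavelengths.copy(),
        _denoise_rows(data.intensities, wavelet, level),
        data.reference.copy(),
        list(data.ids),
    )


@dataclass(frozen=True)
class SplitResult:
    """Calibration/prediction row indices (into the original dataset).

    Indices are stored in reference-rank order: the prediction set is
    every fourth sample of the concentration-sorted sequence.
    """

    calibration: np.ndarray
    prediction: np.ndarray

    def __post_init__(self) -> None:
        cal = set(self.calibration.tolist())
        pred = set(self.prediction.tolist())
        if cal & pred:
            raise ValueError("calibration and prediction sets must be disjoint")


def split_rank_ordered(reference) -> SplitResult:
    """Sort by reference concentration and send 3 of every 4 samples to
    calibration, the 4th to prediction; a trailing partial block of fewer
    than four samples goes to calibration.

    Ties sort stably by original index, so the split is deterministic.
    """
    ref = np.asarray(reference, dtype=float)
    n = ref.size
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    order = np.argsort(ref, kind="stable")
    pos = np.arange(n)
    is_pred = pos % 4 == 3
    return SplitResult(order[~is_pred], order[is_pred])


def write_split(split: SplitResult, ids, path) -> None:
    rows = [(ids[i], "calibration") for i in split.calibration]
    rows += [(ids[i], "prediction") for i in split.prediction]
    pd.DataFrame(rows, columns=["id", "assignment"]).to_csv(
        path, sep="\t", index=False
    )


def read_split(path, ids) -> SplitResult:
    df = pd.read_csv(path, sep="\t")
    lookup = {s: i for i, s in enumerate(ids)}
    cal = np.array([lookup[s] for s in df[df.assignment == "calibration"].id])
    pred = np.array([lookup[s] for s in df[df.assignment == "prediction"].id])
    return SplitResult(cal, pred)
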