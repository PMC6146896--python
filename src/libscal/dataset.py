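"""Container for spectral calibration data and its delimited-text format.

The on-disk layout is a plain CSV: column 1 holds sample ids, column 2 the
reference analyte concentration (mg g^-1), and the remaining columns one
intensity per wavelength channel, with the wavelength axis (nm) as the
header row.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset"]


@dataclass
class SpectralDataset:
    """A samples-by-channels intensity matrix plus its wavelength axis.

    Attributes
    ----------
    wavelengths
        Strictly increasing axis in nm, length ``p``.
    intensities
        ``(n, p)`` matrix, one emission spectrum per row.
    reference
        Length-``n`` reference concentrations in mg g^-1 (all >= 0).
    ids
        Length-``n`` sample labels.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    reference: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.reference = np.asarray(self.reference, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        n, p = self.intensities.shape
        if self.wavelengths.size != p:
            raise ValueError(
                f"axis length {self.wavelengths.size} != channel count {p}"
            )
        if self.reference.size != n or len(self.ids) != n:
            raise ValueError("reference/ids length must match the number of rows")
        if np.any(self.reference < 0):
            raise ValueError("reference concentrations must be >= 0")

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.intensities.shape[0]

    @property
    def p(self) -> int:
        """Number of wavelength channels."""
        return self.intensities.shape[1]

    def take(self, rows) -> "SpectralDataset":
        """Row subset (e.g. the calibration half of a split)."""
        rows = np.asarray(rows, dtype=int)
        return SpectralDataset(
            self.wavelengths.copy(),
            self.intensities[rows],
            self.reference[rows],
            [self.ids[i] for i in rows],
        )

    def select_channels(self, channels) -> "SpectralDataset":
        """Column subset keeping only the given channel indices."""
        channels = np.asarray(channels, dtype=int)
        if channels.size == 0:
            raise ValueError("channel subset must be nonempty")
        order = np.argsort(channels)
        channels = channels[order]
        return SpectralDataset(
            self.wavelengths[channels],
            self.intensities[:, channels],
            self.reference.copy(),
            list(self.ids),
        )

    def nearest_channel(self, nm: float) -> int:
        """Index of the channel whose wavelength is closest to ``nm``."""
        if not (self.wavelengths[0] <= nm <= self.wavelengths[-1]):
            raise ValueError(f"{nm} nm is outside the spectral axis")
        return int(np.argmin(np.abs(self.wavelengths - nm)))

    # -- delimited-text round trip ------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.intensities, columns=[str(w) for w in self.wavelengths]
        )
        df.insert(0, "reference", self.reference)
        df.insert(0, "id", self.ids)
        # 17 significant digits: exact float round trip
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "SpectralDataset":
        df = pd.read_csv(Path(path), float_precision="round_trip")
        if df.shape[1] < 3 or list(df.columns[:2]) != ["id", "reference"]:
            raise ValueError(
                "expected columns: id, reference, then one column per wavelength"
            )
        wavelengths = np.array([float(c) for c in df.columns[2:]])
        return cls(
            wavelengths,
            df.iloc[:, 2:].to_numpy(dtype=float),
            df["reference"].to_numpy(dtype=float),
            df["id"].astype(str).tolist(),
        )
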