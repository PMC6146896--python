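"""Equidistant interval partitions, iPLS selection and BiPLS elimination.

iPLS scores every interval of every candidate partition by the
leave-one-out RMSECV of a PLS model restricted to that interval and
keeps the single best interval.  BiPLS starts from all intervals of one
partition and repeatedly discards the interval whose removal yields the
best remaining model, logging a removal ledger; the step with the lowest
recorded RMSECV defines the selected interval set.

Channel indices are 0-based half-open internally; ledgers report
1-based interval numbers, the convention of published removal tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _pls
from .dataset import SpectralDataset

__all__ = [
    "IntervalPartition",
    "partition_equidistant",
    "EliminationLedger",
    "EliminationStep",
    "SelectionResult",
    "interval_score",
    "ipls_select",
    "bipls_eliminate",
    "bipls_select",
    "wavelength_ranges",
    "write_selection",
    "read_selection",
]

DEFAULT_K_RANGE = range(2, 31)


@dataclass(frozen=True)
class IntervalPartition:
    """``k`` contiguous, disjoint index ranges covering ``[0, p)``.

    Sizes differ by at most one; the larger intervals come first
    (remainder-first convention).
    """

    p: int
    k: int
    boundaries: tuple[tuple[int, int], ...]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.boundaries)

    def channels(self, interval: int) -> np.ndarray:
        """Channel indices of one interval (0-based interval number)."""
        s, e = self.boundaries[interval]
        return np.arange(s, e)

    def channels_of(self, intervals: Iterable[int]) -> np.ndarray:
        """Sorted union of channel indices over several intervals."""
        parts = [self.channels(i) for i in sorted(intervals)]
        return np.concatenate(parts) if parts else np.empty(0, dtype=int)

    def replay_counts(self, removal_order: Sequence[int]) -> list[int]:
        """Remaining-channel count at each ledger step for a given
        1-based removal order (last entry is the surviving interval).

        Pure integer bookkeeping: entry ``t`` is the number of channels
        the step-``t`` model uses, i.e. ``p`` minus the sizes of the
        intervals removed before step ``t``.
        """
        if sorted(removal_order) != list(range(1, self.k + 1)):
            raise ValueError("removal order must be a permutation of 1..k")
        sizes = self.sizes
        counts = [self.p]
        for idx in removal_order[:-1]:
            counts.append(counts[-1] - sizes[idx - 1])
        return counts


def partition_equidistant(p: int, k: int) -> IntervalPartition:
    """Split ``p`` channels into ``k`` near-equal contiguous intervals,
    the first ``p mod k`` of size ``ceil(p/k)`` and the rest ``floor(p/k)``."""
    if k < 1:
        raise ValueError("interval count must be >= 1")
    if k > p:
        raise ValueError("cannot make more intervals than channels")
    base, rem = divmod(p, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    bounds = []
    start = 0
    for s in sizes:
        bounds.append((start, start + s))
        start += s
    return IntervalPartition(p, k, tuple(bounds))


def wavelength_ranges(
    wavelengths: np.ndarray, channels: np.ndarray
) -> tuple[tuple[float, float], ...]:
    """Closed nm ranges covered by the maximal contiguous runs of
    ``channels`` (sorted unique indices)."""
    ch = np.unique(np.asarray(channels, dtype=int))
    if ch.size == 0:
        return ()
    breaks = np.where(np.diff(ch) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [ch.size - 1]])
    return tuple(
        (float(wavelengths[ch[s]]), float(wavelengths[ch[e]]))
        for s, e in zip(starts, ends)
    )


@dataclass
class SelectionResult:
    """Outcome of a variable-selection run.

    ``channels`` are sorted 0-based indices into the full axis;
    ``ledger`` records the per-candidate cross-validation scores that
    drove the choice.
    """

    channels: np.ndarray
    ranges: tuple[tuple[float, float], ...]
    k: Optional[int]
    score: float
    n_lv: int
    ledger: pd.DataFrame

    def __post_init__(self) -> None:
        self.channels = np.unique(np.asarray(self.channels, dtype=int))
        if self.channels.size == 0:
            raise ValueError("selection must keep at least one channel")


def _max_lv_bound(n: int, n_channels: int, max_lv: int) -> int:
    return max(1, min(max_lv, n - 2, n_channels))


def interval_score(
    data: SpectralDataset, channels, max_lv: int
) -> tuple[float, int]:
    """Leave-one-out RMSECV of a PLS model on a channel subset.

    Returns the lowest RMSECV over 1..max_lv latent variables and the
    latent-variable count attaining it (ties go to fewer LVs).
    """
    channels = np.asarray(channels, dtype=int)
    if channels.size == 0:
        raise ValueError("channel set must be nonempty")
    if data.n < 3:
        raise ValueError("need at least 3 calibration samples")
    bound = min(data.n - 2, channels.size)
    if max_lv > bound:
        raise ValueError(f"max_lv {max_lv} exceeds the rank bound {bound}")
    path = _pls.loo_rmsecv_path(
        data.intensities[:, channels], data.reference, max_lv
    )
    best = int(np.argmin(path))
    return float(path[best]), best + 1


def ipls_select(
    data: SpectralDataset,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    max_lv: int = 10,
) -> SelectionResult:
    """Interval PLS: keep the single interval, over all candidate
    partition granularities, with the lowest RMSECV.

    Ties break toward smaller ``k`` then lower interval index (the scan
    order), so runs are deterministic.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be nonempty")
    records = []
    best = None  # (score, k, interval, n_lv, channels)
    for k in ks:
        part = partition_equidistant(data.p, k)
        for i in range(k):
            ch = part.channels(i)
            lv = _max_lv_bound(data.n, ch.size, max_lv)
            score, n_lv = interval_score(data, ch, lv)
            lo, hi = float(data.wavelengths[ch[0]]), float(data.wavelengths[ch[-1]])
            records.append((k, i + 1, lo, hi, ch.size, score, n_lv))
            if best is None or score < best[0]:
                best = (score, k, i, n_lv, ch)
    ledger = pd.DataFrame(
        records,
        columns=["k", "interval", "low_nm", "high_nm", "n_channels", "rmsecv", "n_lv"],
    )
    score, k, _, n_lv, ch = best
    return SelectionResult(
        ch, wavelength_ranges(data.wavelengths, ch), k, score, n_lv, ledger
    )


@dataclass(frozen=True)
class EliminationStep:
    """One row of a BiPLS removal ledger.

    ``n_channels`` and ``rmsecv`` describe the model fitted on the
    intervals still present at this step; ``removed`` (1-based) is the
    interval discarded after scoring (for the final step, the survivor).
    """

    n_intervals: int
    remaining: tuple[int, ...]  # 1-based, before this step's removal
    removed: int
    rmsecv: float
    n_lv: int
    n_channels: int


@dataclass
class EliminationLedger:
    partition: IntervalPartition
    steps: list[EliminationStep]

    @property
    def remaining_counts(self) -> list[int]:
        return [s.n_channels for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.n_intervals, s.removed, s.rmsecv, s.n_lv, s.n_channels)
                for s in self.steps
            ],
            columns=["n_intervals", "removed_interval", "rmsecv", "n_lv", "n_channels"],
        )


def bipls_eliminate(
    data: SpectralDataset, k: int, max_lv: int = 10
) -> EliminationLedger:
    """Backward interval elimination over one equidistant partition.

    At each step the model on all remaining intervals is scored (that
    score and channel count are what the ledger records), then every
    single-interval removal is tried and the one giving the lowest
    remaining-model RMSECV is discarded; ties go to the lower interval
    index.  Continues until one interval is left.
    """
    if k < 2:
        raise ValueError("BiPLS needs at least 2 intervals")
    part = partition_equidistant(data.p, k)
    remaining = list(range(k))
    steps: list[EliminationStep] = []
    while remaining:
        ch = part.channels_of(remaining)
        lv = _max_lv_bound(data.n, ch.size, max_lv)
        score, n_lv = interval_score(data, ch, lv)
        if len(remaining) > 1:
            best_removal = None  # (score, interval)
            for r in remaining:
                rest = [i for i in remaining if i != r]
                rest_ch = part.channels_of(rest)
                lv_r = _max_lv_bound(data.n, rest_ch.size, max_lv)
                s_r, _ = interval_score(data, rest_ch, lv_r)
                if best_removal is None or s_r < best_removal[0]:
                    best_removal = (s_r, r)
            removed = best_removal[1]
        else:
            removed = remaining[0]
        steps.append(
            EliminationStep(
                n_intervals=len(remaining),
                remaining=tuple(i + 1 for i in remaining),
                removed=removed + 1,
                rmsecv=score,
                n_lv=n_lv,
                n_channels=ch.size,
            )
        )
        remaining.remove(removed)
    return EliminationLedger(part, steps)


def bipls_select(
    data: SpectralDataset,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    max_lv: int = 10,
) -> SelectionResult:
    """Backward interval PLS over several partition granularities.

    For each ``k`` the elimination ledger's lowest-RMSECV step defines
    that ``k``'s candidate interval set (ties toward fewer channels);
    the best candidate across all ``k`` wins (ties toward smaller ``k``).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range must be nonempty")
    records = []
    best = None  # (score, k, channels, n_lv)
    for k in ks:
        ledger = bipls_eliminate(data, k, max_lv)
        cand = None
        for step in ledger.steps:
            if cand is None or step.rmsecv <= cand.rmsecv:
                cand = step
        ch = ledger.partition.channels_of([i - 1 for i in cand.remaining])
        records.append(
            (k, cand.rmsecv, cand.n_lv, len(cand.remaining), ch.size)
        )
        if best is None or cand.rmsecv < best[0]:
            best = (cand.rmsecv, k, ch, cand.n_lv)
    summary = pd.DataFrame(
        records, columns=["k", "rmsecv", "n_lv", "n_intervals", "n_channels"]
    )
    score, k, ch, n_lv = best
    return SelectionResult(
        ch, wavelength_ranges(data.wavelengths, ch), k, score, n_lv, summary
    )


def write_selection(result: SelectionResult, path) -> None:
    """Channel-index file with a wavelength-range summary header."""
    with open(path, "w") as fh:
        fh.write(f"# k={result.k} rmsecv={result.score:.6g} n_lv={result.n_lv}\n")
        for lo, hi in result.ranges:
            fh.write(f"# range {lo:.3f}-{hi:.3f} nm\n")
        for c in result.channels:
            fh.write(f"{int(c)}\n")


def read_selection(path) -> np.ndarray:
    chans = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                chans.append(int(line))
    return np.array(chans, dtype=int)
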