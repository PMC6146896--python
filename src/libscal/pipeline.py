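"""End-to-end orchestration: simulate/load, denoise, split, select, fit,
evaluate, report.

Variable selection and every model choice (latent variables, principal
components, SVR hyperparameters) operate strictly on the calibration
split; prediction samples enter only the final evaluation.
"""
from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import calibrate, intervals, preprocess, spa, univariate
from .dataset import SpectralDataset
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline", "METHODS", "MODELS"]

METHODS = ("full", "ipls", "bipls", "ipls_spa", "bipls_spa")
MODELS = ("pls", "svm", "univariate", "index1", "index2")


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one input source."""

    simulation: Optional[SimulationConfig] = None
    dataset_path: Optional[str] = None
    dataset: Optional[SpectralDataset] = None
    denoise: bool = True
    wavelet: str = preprocess.DEFAULT_WAVELET
    level: int = preprocess.DEFAULT_LEVEL
    method: str = "ipls"
    model: str = "pls"
    k_min: int = 2
    k_max: int = 20
    bipls_k: Optional[int] = None  # single-partition BiPLS when set
    max_lv: int = 8
    spa_max: int = 30
    svm_max_pcs: int = 13
    svm_c_grid: tuple = calibrate.DEFAULT_C_GRID
    svm_gamma_grid: tuple = calibrate.DEFAULT_GAMMA_GRID
    svm_epsilon_grid: tuple = calibrate.DEFAULT_EPSILON_GRID
    line_mode: str = "nearest"
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        sources = sum(
            x is not None for x in (self.simulation, self.dataset_path, self.dataset)
        )
        if sources != 1:
            raise ValueError("exactly one input source must be given")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")


@dataclass
class RunReport:
    """Outcome of one pipeline run, with per-stage provenance."""

    metrics: pd.DataFrame
    split: preprocess.SplitResult
    selection: Optional[intervals.SelectionResult]
    channels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        if self.selection is not None:
            intervals.write_selection(self.selection, out / "selection.txt")
        with open(out / "report.yaml", "w") as fh:
            yaml.safe_dump(self.provenance, fh, sort_keys=True)


def _load(cfg: RunConfig) -> SpectralDataset:
    if cfg.simulation is not None:
        return simulate_dataset(cfg.simulation)
    if cfg.dataset is not None:
        return cfg.dataset
    return SpectralDataset.from_csv(cfg.dataset_path)


def _select(cfg: RunConfig, cal: SpectralDataset):
    k_range = range(cfg.k_min, cfg.k_max + 1)
    bipls_range = [cfg.bipls_k] if cfg.bipls_k else k_range
    if cfg.method == "full":
        return None
    if cfg.method == "ipls":
        return intervals.ipls_select(cal, k_range, cfg.max_lv)
    if cfg.method == "bipls":
        return intervals.bipls_select(cal, bipls_range, cfg.max_lv)
    if cfg.method == "ipls_spa":
        base = intervals.ipls_select(cal, k_range, cfg.max_lv)
        return spa.spa_select(cal, base.channels, cfg.spa_max)
    base = intervals.bipls_select(cal, bipls_range, cfg.max_lv)
    return spa.spa_select(cal, base.channels, cfg.spa_max)


def _index_rows(cfg, data, split):
    i508 = univariate.dataset_line_intensity(data, 508.58, cfg.line_mode)
    i466 = univariate.dataset_line_intensity(data, 466.23, cfg.line_mode)
    if cfg.model == "index1":
        i361 = univariate.dataset_line_intensity(data, 361.05, cfg.line_mode)
        values = univariate.index1(i508, i361, i466)
    else:
        values = univariate.index2(i508, i466)
    _, m = univariate.fit_univariate(values, data.reference, split)
    return [
        dict(
            method=cfg.method,
            model=cfg.model,
            line_nm=np.nan,
            n_variables=3 if cfg.model == "index1" else 2,
            factors=1,
            **m.as_dict(),
        )
    ]


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run the configured analysis end to end; deterministic given seeds."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    data = _load(cfg)
    timings["load_s"] = time.perf_counter() - t0

    if cfg.denoise:
        t = time.perf_counter()
        data = preprocess.denoise_dataset(data, cfg.wavelet, cfg.level)
        timings["denoise_s"] = time.perf_counter() - t

    split = preprocess.split_rank_ordered(data.reference)
    cal = data.take(split.calibration)
    pred = data.take(split.prediction)

    t = time.perf_counter()
    selection = _select(cfg, cal)
    timings["select_s"] = time.perf_counter() - t
    channels = (
        selection.channels if selection is not None else np.arange(data.p)
    )

    t = time.perf_counter()
    rows: list[dict] = []
    if cfg.model == "pls":
        Xc = cal.intensities[:, channels]
        max_lv = max(1, min(cfg.max_lv, cal.n - 2, channels.size))
        model = calibrate.fit_pls_loocv(Xc, cal.reference, max_lv)
        m = calibrate.evaluate(
            model, Xc, cal.reference, pred.intensities[:, channels], pred.reference
        )
        rows.append(
            dict(
                method=cfg.method,
                model="pls",
                line_nm=np.nan,
                n_variables=channels.size,
                factors=model.n_factors,
                **m.as_dict(),
            )
        )
    elif cfg.model == "svm":
        Xc = cal.intensities[:, channels]
        model = calibrate.fit_svm_pcs(
            Xc,
            cal.reference,
            c_grid=cfg.svm_c_grid,
            gamma_grid=cfg.svm_gamma_grid,
            epsilon_grid=cfg.svm_epsilon_grid,
            seed=cfg.seed,
            max_pcs=cfg.svm_max_pcs,
        )
        m = calibrate.evaluate(
            model, Xc, cal.reference, pred.intensities[:, channels], pred.reference
        )
        rows.append(
            dict(
                method=cfg.method,
                model="svm",
                line_nm=np.nan,
                n_variables=channels.size,
                factors=model.n_factors,
                **m.as_dict(),
            )
        )
    elif cfg.model == "univariate":
        if selection is not None:
            ranges = selection.ranges
        else:
            ranges = ((float(data.wavelengths[0]), float(data.wavelengths[-1])),)
        cat = univariate.lines_in_ranges(
            univariate.default_catalog().of_element("Cd"), ranges
        )
        if not cat.entries:
            raise ValueError("no catalogued Cd line inside the selected ranges")
        table = univariate.univariate_report(
            data, split, [e.nm for e in cat.entries], cfg.line_mode
        )
        for r in table.itertuples(index=False):
            rows.append(
                dict(
                    method=cfg.method,
                    model="univariate",
                    line_nm=r.line_nm,
                    n_variables=1,
                    factors=1,
                    r2_cal=r.r2_cal,
                    rmsecv=r.rmsecv,
                    r2_pred=r.r2_pred,
                    rmsep=r.rmsep,
                )
            )
    else:  # index1 / index2
        rows = _index_rows(cfg, data, split)
    timings["fit_s"] = time.perf_counter() - t

    metrics = pd.DataFrame(rows)
    cfg_echo = {
        f.name: getattr(cfg, f.name)
        for f in dataclasses.fields(cfg)
        if f.name not in ("dataset", "simulation")
    }
    cfg_echo["simulated"] = cfg.simulation is not None
    if cfg.simulation is not None:
        cfg_echo["simulation_seed"] = cfg.simulation.seed
        cfg_echo["n_samples"] = int(sum(cfg.simulation.group_sizes))
    provenance = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg_echo.items()},
        "n_calibration": int(split.calibration.size),
        "n_prediction": int(split.prediction.size),
        "n_channels_used": int(np.asarray(channels).size),
        "timings": {k: round(v, 3) for k, v in timings.items()},
    }
    report = RunReport(metrics, split, selection, np.asarray(channels), provenance)
    if cfg.outdir is not None:
        report.write(cfg.outdir)
        preprocess.write_split(split, data.ids, Path(cfg.outdir) / "split.txt")
    return report
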