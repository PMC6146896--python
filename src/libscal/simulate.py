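"""Synthetic LIBS spectrum generator for cadmium-stressed plant tissue.

Emulates the statistical structure of averaged laser-induced breakdown
spectra of pressed root pellets: a dense uniform wavelength grid, narrow
pseudo-Voigt emission lines of the analyte (Cd) whose peak heights scale
linearly with concentration, fixed matrix-element lines (Ca, Mg, Na, K,
Fe, C, CN) with an optional mild concentration trend, stable
background-like lines that track the laser pulse energy but not the
analyte, a shared multiplicative shot-to-shot factor per laser shot, and
additive detector noise.  Pellet spectra are averages over many shots
that share one true concentration.

The generator is the data source for every downstream stage (denoising,
interval selection, successive projections, univariate indices,
multivariate calibration), so its mechanisms are chosen to expose the
phenomena those stages exploit — in particular, the shared shot factor
is what makes intensity-ratio indices beneficial.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .dataset import SpectralDataset

__all__ = [
    "EmissionLine",
    "SimulationConfig",
    "Spectrum",
    "build_axis",
    "line_profile",
    "simulate_sample",
    "simulate_dataset",
    "default_line_catalog",
    "small_config",
    "read_line_catalog",
    "write_line_catalog",
    "read_config",
    "write_config",
]

LINE_KINDS = ("analyte", "matrix", "interferent", "background-like")


@dataclass(frozen=True)
class EmissionLine:
    """One emission line of the synthetic plasma.

    ``sensitivity`` is the peak height per mg g^-1 for analyte lines and
    the fixed base peak height for every other kind.  Matrix and
    interferent lines additionally pick up the configured mild
    concentration trend; background-like lines never do.
    """

    element: str
    center: float  # nm
    width: float = 0.1  # FWHM, nm
    sensitivity: float = 0.0
    kind: str = "matrix"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("line width (FWHM) must be > 0")
        if self.sensitivity < 0:
            raise ValueError("sensitivity must be >= 0")
        if self.kind not in LINE_KINDS:
            raise ValueError(f"kind must be one of {LINE_KINDS}")


def default_line_catalog() -> tuple[EmissionLine, ...]:
    """Line catalog of a Cd-stressed root pellet.

    The ten Cd I lines carry concentration information with 508.58 nm the
    most sensitive and interference-free; 361.05 nm sits 0.17 nm from a
    strong Fe I line; 466.23 nm is configured background-like (a strong,
    stable line uncorrelated with Cd) so that it serves as the internal
    reference of the ratio indices.  Matrix lines are the strong Ca, Mg,
    Na, K, Cu, C and CN features of root tissue.
    """
    cd = [
        # (nm, peak height per mg/g); relative magnitudes mirror how well
        # each line tracks the analyte, with 508.58 nm dominant.
        (326.10, 0.40),
        (340.36, 0.30),
        (346.61, 0.35),
        (361.05, 0.45),
        (361.28, 0.25),
        (361.44, 0.06),
        (467.81, 0.20),
        (508.58, 1.00),
        (643.84, 0.05),
    ]
    matrix = [
        ("C", 247.86, 30.0),
        ("Mg", 279.55, 45.0),
        ("Mg", 279.80, 40.0),
        ("Mg", 383.82, 35.0),
        ("Mg", 516.73, 18.0),
        ("Ca", 373.69, 50.0),
        ("Ca", 397.37, 40.0),
        ("Ca", 422.67, 45.0),
        ("Ca", 558.90, 30.0),
        ("Ca", 643.91, 20.0),
        ("Ca", 644.98, 18.0),
        ("Ca", 849.80, 12.0),
        ("Ca", 866.21, 12.0),
        ("Cu", 324.75, 25.0),
        ("Cu", 327.40, 22.0),
        ("Na", 589.00, 60.0),
        ("Na", 589.59, 55.0),
        ("K", 766.49, 50.0),
        ("K", 769.90, 45.0),
    ]
    lines = [EmissionLine("Cd", nm, 0.1, s, "analyte") for nm, s in cd]
    # Strong stable line used as the denominator of the ratio indices.
    lines.append(EmissionLine("Cd", 466.23, 0.1, 50.0, "background-like"))
    # Fe I adjacent to Cd I 361.05 nm.
    lines.append(EmissionLine("Fe", 360.88, 0.1, 25.0, "interferent"))
    # Smooth, steady background-like signals.
    for nm, s in [(331.24, 4.0), (474.64, 8.0), (493.51, 10.0), (507.47, 12.0)]:
        lines.append(EmissionLine("bg", nm, 0.1, s, "background-like"))
    lines += [EmissionLine(el, nm, 0.1, s, "matrix") for el, nm, s in matrix]
    # CN molecular bands are broader than atomic lines.
    lines += [
        EmissionLine("CN", 393.37, 0.3, 28.0, "matrix"),
        EmissionLine("CN", 396.85, 0.3, 26.0, "matrix"),
    ]
    return tuple(lines)


@dataclass
class SimulationConfig:
    """Full description of one synthetic acquisition campaign.

    Defaults follow the hydroponic Cd-stress design: five concentration
    groups (control plus four stress levels) with the group means and
    spreads of the reference-method measurements, a 229.99-880.01 nm
    axis with 22,015 channels, and 80 averaged shots per pellet.
    """

    group_sizes: tuple[int, ...] = (12, 12, 18, 18, 18)
    group_means: tuple[float, ...] = (0.001, 0.015, 2.304, 6.663, 11.577)
    group_sds: tuple[float, ...] = (0.006, 0.087, 0.602, 1.735, 2.617)
    lines: tuple[EmissionLine, ...] = field(default_factory=default_line_catalog)
    axis_min: float = 229.99
    axis_max: float = 880.01
    n_channels: int = 22015
    shot_sigma: float = 0.2  # lognormal scale of the shared shot factor
    noise_sigma: float = 0.3  # additive noise, intensity units
    baseline_coeffs: tuple[float, ...] = (0.0,)
    matrix_trend: float = 0.02  # relative height change per mg/g on matrix lines
    lorentz_fraction: float = 0.3  # pseudo-Voigt mixing parameter
    replicates: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.axis_max <= self.axis_min:
            raise ValueError("axis_max must exceed axis_min")
        if min(self.shot_sigma, self.noise_sigma) < 0:
            raise ValueError("noise spreads must be >= 0")
        if any(m < 0 for m in self.group_means):
            raise ValueError("group means must be >= 0")
        if any(s < 0 for s in self.group_sds):
            raise ValueError("group spreads must be >= 0")
        if not (len(self.group_sizes) == len(self.group_means) == len(self.group_sds)):
            raise ValueError("group sizes, means and spreads must align")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for line in self.lines:
            if not (self.axis_min <= line.center <= self.axis_max):
                raise ValueError(
                    f"line {line.element} {line.center} nm outside the axis"
                )

    def axis(self) -> np.ndarray:
        return build_axis(self.axis_min, self.axis_max, self.n_channels)


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale preset used throughout the test suite and examples.

    Forty samples (8 per group), a ~0.15 nm grid over the full range and
    3 averaged shots per pellet keep every downstream stage fast while
    preserving all the structural features of the full-scale default.
    """
    base = dict(group_sizes=(8, 8, 8, 8, 8), n_channels=4342, replicates=3)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class Spectrum:
    """One emission spectrum on its wavelength axis."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")


def build_axis(min_nm: float, max_nm: float, n_channels: int) -> np.ndarray:
    """Uniform wavelength grid with exact endpoints."""
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if max_nm <= min_nm:
        raise ValueError("max_nm must exceed min_nm")
    return np.linspace(min_nm, max_nm, n_channels)


def line_profile(
    center: float,
    width: float,
    height: float,
    axis: np.ndarray,
    lorentz_fraction: float = 0.0,
) -> np.ndarray:
    """Pseudo-Voigt line shape normalised to ``height`` at the channel
    nearest ``center``.

    The normalisation at the nearest grid point (rather than at the
    continuous maximum) makes the peak-channel intensity exact on any
    grid, which downstream single-channel extraction relies on.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if not 0.0 <= lorentz_fraction <= 1.0:
        raise ValueError("lorentz_fraction must lie in [0, 1]")
    axis = np.asarray(axis, dtype=float)
    if height == 0:
        return np.zeros_like(axis)
    d = axis - center
    gamma = width / 2.0
    gauss = np.exp(-4.0 * np.log(2.0) * (d / width) ** 2)
    lorentz = gamma**2 / (d**2 + gamma**2)
    shape = (1.0 - lorentz_fraction) * gauss + lorentz_fraction * lorentz
    peak = shape[np.argmin(np.abs(d))]
    if peak <= 0:
        raise ValueError("line center too far from the wavelength axis")
    return (height / peak) * shape


def _line_height(line: EmissionLine, cd: float, matrix_trend: float) -> float:
    if line.kind == "analyte":
        return line.sensitivity * cd
    if line.kind in ("matrix", "interferent"):
        return line.sensitivity * (1.0 + matrix_trend * cd)
    return line.sensitivity  # background-like: tracks the shot factor only


def _line_sum(config: SimulationConfig, cd: float, axis: np.ndarray) -> np.ndarray:
    total = np.zeros_like(axis)
    for line in config.lines:
        h = _line_height(line, cd, config.matrix_trend)
        if h != 0:
            total += line_profile(
                line.center, line.width, h, axis, config.lorentz_fraction
            )
    return total


def _baseline(config: SimulationConfig, axis: np.ndarray) -> np.ndarray:
    x = (axis - config.axis_min) / (config.axis_max - config.axis_min)
    return np.polynomial.polynomial.polyval(x, np.asarray(config.baseline_coeffs))


def simulate_sample(
    config: SimulationConfig,
    cd: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> Spectrum:
    """Single-shot spectrum for one pellet of concentration ``cd``.

    intensity = baseline(lambda) + f * sum(lines) + additive noise, where
    ``f`` is one lognormal shot factor shared by all lines of the shot.
    """
    if cd < 0:
        raise ValueError("cd must be >= 0")
    axis = config.axis()
    clean = _line_sum(config, cd, axis)
    base = _baseline(config, axis)
    f = float(np.exp(rng.normal(0.0, config.shot_sigma))) if config.shot_sigma > 0 else 1.0
    noise = rng.normal(0.0, config.noise_sigma, axis.size) if config.noise_sigma > 0 else 0.0
    return Spectrum(axis, base + f * clean + noise, sample_id)


def simulate_dataset(config: SimulationConfig) -> SpectralDataset:
    """Full campaign: concentrations drawn per group, spectra averaged
    over the configured shot count.

    Group concentrations follow a normal distribution truncated at zero;
    each pellet's spectrum is the average of ``config.replicates`` shots
    that share the pellet's true concentration but not the shot factor.
    """
    if any(s < 1 for s in config.group_sizes):
        raise ValueError("every concentration group must be nonempty")
    rng = np.random.default_rng(config.seed)
    axis = config.axis()
    base = _baseline(config, axis)

    cds: list[float] = []
    ids: list[str] = []
    for gi, (ns, m, sd) in enumerate(
        zip(config.group_sizes, config.group_means, config.group_sds)
    ):
        if sd > 0:
            a = (0.0 - m) / sd
            draws = stats.truncnorm.rvs(
                a, np.inf, loc=m, scale=sd, size=ns, random_state=rng
            )
        else:
            draws = np.full(ns, float(m))
        cds.extend(float(c) for c in draws)
        ids.extend(f"g{gi + 1}s{si + 1:03d}" for si in range(ns))

    rows = np.empty((len(cds), axis.size))
    r = config.replicates
    for i, cd in enumerate(cds):
        clean = _line_sum(config, cd, axis)
        if config.shot_sigma > 0:
            f_mean = float(np.mean(np.exp(rng.normal(0.0, config.shot_sigma, r))))
        else:
            f_mean = 1.0
        if config.noise_sigma > 0:
            noise_mean = rng.normal(0.0, config.noise_sigma, (r, axis.size)).mean(axis=0)
        else:
            noise_mean = 0.0
        rows[i] = base + f_mean * clean + noise_mean
    return SpectralDataset(axis, rows, np.array(cds), ids)


# -- flat-file interfaces ---------------------------------------------

_CATALOG_COLUMNS = ["element", "center", "width", "sensitivity", "kind"]


def write_line_catalog(lines, path) -> None:
    pd.DataFrame(
        [[l.element, l.center, l.width, l.sensitivity, l.kind] for l in lines],
        columns=_CATALOG_COLUMNS,
    ).to_csv(path, index=False)


def read_line_catalog(path) -> tuple[EmissionLine, ...]:
    df = pd.read_csv(path)
    missing = set(_CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog file missing columns: {sorted(missing)}")
    return tuple(
        EmissionLine(
            str(r.element), float(r.center), float(r.width), float(r.sensitivity), str(r.kind)
        )
        for r in df.itertuples()
    )


def write_config(config: SimulationConfig, path, catalog_path=None) -> None:
    """Flat key-value config file; the line catalog goes to its own CSV."""
    d = dataclasses.asdict(config)
    d.pop("lines")
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    if catalog_path is not None:
        write_line_catalog(config.lines, catalog_path)
        d["catalog"] = str(catalog_path)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    catalog = d.pop("catalog", None)
    for k in ("group_sizes", "group_means", "group_sds", "baseline_coeffs"):
        if k in d:
            d[k] = tuple(d[k])
    if catalog is not None:
        d["lines"] = read_line_catalog(catalog)
    return SimulationConfig(**d)
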