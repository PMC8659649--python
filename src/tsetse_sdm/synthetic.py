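"""Synthetic landscapes, truth surfaces and trap surveys.

Everything downstream — filtering, pseudo-absence design, ENFA, MaxEnt,
validation — is exercised against landscapes generated here, which mimic
the statistical structure of the field study area: spatially autocorrelated
continuous covariates on a 500 m grid, a contiguous protected-area mask, a
categorical vegetation layer, effort-biased trap placement concentrated on
protected areas, and overdispersed (negative-binomial) catch counts whose
mean follows a known logistic suitability surface.

Spatial autocorrelation is produced by Gaussian-kernel smoothing of white
noise — a cheap, controllable stand-in for a full Gaussian-process
simulator whose correlation length is set by ``spatial_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, special

from .errors import ConfigError, DataError
from .fielddata import TrapRecord
from .grid import GridSpec
from .stack import BINARY, CATEGORICAL, CONTINUOUS, CovariateStack

VEGETATION_CLASSES = ("dense_forest", "savannah_woodland", "shrub_savannah", "herbaceous")


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic survey.

    Defaults describe the reference scenario used throughout the test-bed:
    a 100x100 grid of 500 m cells (a 50 x 50 km block), three informative
    continuous covariates with ~5 km autocorrelation range, protected
    reserves on ~20% of the area, 300 effort-biased traps deployed 3-60
    days, a peak catch rate of 0.1 flies/trap/day — the catch-rate scale
    of the sparser of the two vector species, for which zero catches are
    common and detection does not saturate — and negative-binomial
    dispersion (size) 5.0.  The size default is a free choice: it keeps
    per-trap counts overdispersed relative to Poisson while staying
    consistent with the Poisson zero-catch model that the absence
    significance filter assumes (under much heavier dispersion, zero
    catches stay common even in excellent habitat and a "significant"
    absence no longer indicates unsuitable habitat); the strong aggregation
    seen in field catches emerges anyway from the patchy suitability
    surface.  The default coefficients
    give the linear predictor an sd near 2.7, i.e. a patchy, near-bimodal
    suitability surface — the species occupy pockets of good habitat
    rather than a gently varying gradient — which is what yields genuine
    zero catches on long deployments.
    """

    grid_shape: tuple[int, int] = (100, 100)
    cell_size: float = 500.0
    n_continuous_covariates: int = 3
    spatial_range: float = 5000.0
    true_coefficients: tuple[float, ...] = (2.0, -1.5, 1.0)
    protected_effect: float = 1.5
    protected_fraction: float = 0.2
    n_traps: int = 300
    effort_bias: float = 0.5
    ad_max: float = 0.1
    dispersion: float = 5.0
    trap_days_range: tuple[int, int] = (3, 60)
    seed: int = 0
    site_block_cells: int = 10  # coarse blocks defining survey "sites"

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 1:
            raise ConfigError("grid_shape must be positive")
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be > 0")
        if not 0 <= self.protected_fraction <= 1:
            raise ConfigError("protected_fraction must be in [0, 1]")
        if self.ad_max < 0:
            raise ConfigError("ad_max must be >= 0")
        if self.trap_days_range[0] < 1 or self.trap_days_range[1] < self.trap_days_range[0]:
            raise ConfigError("trap_days_range must satisfy 1 <= min <= max")
        if self.effort_bias < 0:
            raise ConfigError("effort_bias must be >= 0")
        if len(self.true_coefficients) != self.n_continuous_covariates:
            raise ConfigError("true_coefficients length must match n_continuous_covariates")

    @property
    def grid(self) -> GridSpec:
        rows, cols = self.grid_shape
        return GridSpec(x0=0.0, y0=rows * self.cell_size, cell=self.cell_size, nrows=rows, ncols=cols)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "true_coefficients", "trap_days_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthSurface:
    """Known suitability surface: inverse-logit of a linear predictor."""

    linear_predictor: np.ndarray
    suitability: np.ndarray = dc_field(init=False)

    def __post_init__(self) -> None:
        self.suitability = special.expit(self.linear_predictor)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Standardized, spatially autocorrelated Gaussian field."""
    noise = rng.standard_normal(shape)
    if sigma_cells > 0:
        fieldv = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    else:
        fieldv = noise
    fieldv = fieldv - fieldv.mean()
    sd = fieldv.std()
    return fieldv / sd if sd > 0 else fieldv


def generate_covariates(scenario: SyntheticScenario) -> CovariateStack:
    """Continuous layers, a protected mask and a vegetation-class layer.

    Continuous layers are standardized to mean 0 / sd 1 over the grid.
    Protected patches come from thresholding one extra smoothed field at
    the (1 - protected_fraction) quantile, giving contiguous reserves;
    vegetation classes are quantile bins of another smoothed field, hence
    also contiguous.
    """
    rows, cols = scenario.grid_shape
    if rows < 4 or cols < 4:
        raise DataError("grid too small: every dimension must be >= 4")
    rng = np.random.default_rng(scenario.seed)
    sigma = scenario.spatial_range / scenario.cell_size
    stack = CovariateStack(grid=scenario.grid)
    for i in range(scenario.n_continuous_covariates):
        stack.add(f"cov{i + 1}", _smooth_field(rng, (rows, cols), sigma), CONTINUOUS)
    # protected reserves
    pfield = _smooth_field(rng, (rows, cols), sigma)
    if scenario.protected_fraction <= 0:
        protected = np.zeros((rows, cols), dtype=int)
    else:
        cut = np.quantile(pfield, 1 - scenario.protected_fraction)
        protected = (pfield > cut).astype(int)
    stack.add("protected", protected, BINARY)
    # vegetation classes: quantile bins of one more smoothed field
    vfield = _smooth_field(rng, (rows, cols), sigma)
    edges = np.quantile(vfield, [0.25, 0.5, 0.75])
    vegetation = np.digitize(vfield, edges)
    stack.add("vegetation", vegetation, CATEGORICAL)
    return stack


def true_suitability(
    stack: CovariateStack, coefficients, protected_effect: float = 0.0
) -> TruthSurface:
    """Plant a known niche: logistic response to the continuous layers.

    ``linear_predictor = sum_i beta_i * cov_i + protected_effect * protected``.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    names = stack.continuous_names
    if len(coefficients) != len(names):
        raise DataError(f"{len(coefficients)} coefficients for {len(names)} continuous layers")
    lp = np.zeros(stack.grid.shape)
    for beta, name in zip(coefficients, names):
        lp = lp + beta * stack[name]
    if "protected" in stack.layers:
        lp = lp + protected_effect * stack["protected"]
    return TruthSurface(linear_predictor=lp)


def vegetation_label(code: int) -> str:
    return VEGETATION_CLASSES[int(code) % len(VEGETATION_CLASSES)]


def _distance_to_protected(stack: CovariateStack) -> np.ndarray:
    protected = stack["protected"].astype(bool)
    if not protected.any():
        return np.full(stack.grid.shape, np.inf)
    dist_cells = ndimage.distance_transform_edt(~protected)
    return dist_cells * stack.grid.cell


def simulate_traps(
    stack: CovariateStack,
    truth: TruthSurface | dict[str, TruthSurface],
    scenario: SyntheticScenario,
) -> list[TrapRecord]:
    """Effort-biased trap placement with negative-binomial catches.

    Trap cells are drawn with probability proportional to
    ``exp(effort_bias * protected)`` — surveys target areas of known or
    suspected presence, here proxied by reserves.  Deployment length is
    uniform over ``trap_days_range`` and each species' catch is
    NegBin(mean = ad_max * suitability * trap_days, size = dispersion).
    """
    if scenario.ad_max < 0:
        raise ConfigError("ad_max must be >= 0")
    truths = truth if isinstance(truth, dict) else {"sp1": truth}
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    grid = stack.grid
    protected_flat = stack["protected"].ravel().astype(float)
    weights = np.exp(scenario.effort_bias * protected_flat)
    weights /= weights.sum()
    cells = rng.choice(grid.n_cells, size=scenario.n_traps, replace=True, p=weights)
    row, col = np.divmod(cells, grid.ncols)
    # jitter within the cell so traps are not all at centres
    cx, cy = grid.cell_center(row, col)
    x = cx + (rng.uniform(-0.5, 0.5, scenario.n_traps)) * grid.cell * 0.98
    y = cy + (rng.uniform(-0.5, 0.5, scenario.n_traps)) * grid.cell * 0.98
    lo, hi = scenario.trap_days_range
    trap_days = rng.integers(lo, hi + 1, size=scenario.n_traps)
    dist_grid = _distance_to_protected(stack)
    vegetation = stack["vegetation"]
    block = max(1, scenario.site_block_cells)
    records = []
    for k in range(scenario.n_traps):
        r, c = int(row[k]), int(col[k])
        counts = {}
        for sp, t in truths.items():
            mean = scenario.ad_max * float(t.suitability[r, c]) * int(trap_days[k])
            if mean <= 0:
                counts[sp] = 0
            else:
                size = scenario.dispersion
                counts[sp] = int(rng.negative_binomial(size, size / (size + mean)))
        in_prot = bool(stack["protected"][r, c])
        records.append(
            TrapRecord(
                trap_id=f"T{k + 1:04d}",
                site_id=f"S{(r // block) * ((grid.ncols + block - 1) // block) + c // block:03d}",
                x=float(x[k]),
                y=float(y[k]),
                species_counts=counts,
                trap_days=int(trap_days[k]),
                vegetation_class=vegetation_label(vegetation[r, c]),
                in_protected=in_prot,
                distance_to_protected=0.0 if in_prot else float(dist_grid[r, c]),
            )
        )
    return records


def simulate_timeseries(
    scenario: SyntheticScenario,
    n_steps: int,
    outlier_rate: float = 0.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.2,
    outlier_magnitude: float = 10.0,
) -> np.ndarray:
    """Per-cell seasonal series with optional gross outliers.

    Returns an array of shape ``(n_steps, rows, cols)``: a sinusoidal
    seasonal template (random phase per cell) plus Gaussian noise, with a
    fraction ``outlier_rate`` of entries replaced by gross outliers of
    magnitude ``outlier_magnitude`` — the kind of contamination cloud and
    sensor artefacts leave in thermal remote-sensing series.
    """
    if n_steps < 4:
        raise ConfigError("n_steps must be >= 4")
    if not 0 <= outlier_rate < 1:
        raise ConfigError("outlier_rate must be in [0, 1)")
    rows, cols = scenario.grid_shape
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    t = np.arange(n_steps)[:, None, None]
    phase = rng.uniform(0, 2 * np.pi, (1, rows, cols))
    series = amplitude * np.sin(2 * np.pi * t / max(n_steps, 12) + phase)
    if noise_sd > 0:
        series = series + rng.normal(0, noise_sd, series.shape)
    if outlier_rate > 0:
        hit = rng.uniform(size=series.shape) < outlier_rate
        sign = rng.choice([-1.0, 1.0], size=series.shape)
        series = np.where(hit, sign * outlier_magnitude, series)
    return series
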