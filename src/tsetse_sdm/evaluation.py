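"""Ensemble fitting, model averaging, uncertainty and validation.

The effect of the stochastic pseudo-absence draw is assessed by refitting
the model over several background draws (submodels), averaging the
suitability grids cellwise, and mapping per-cell uncertainty as the
coefficient of variation (sd/mean) across submodels.  Predictive power is
measured as the exact rank-based AUC of held-out presences against the
retained true absences — the absences filtered out of training are kept
for exactly this purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    EffortKernel,
    SpeciesObservation,
    generate_pseudo_absences,
)
from .errors import ConfigError, DataError
from .maxent import FeatureExpansion, MaxEntModel, fit_maxent, stack_table
from .roc import RocResult, auc_value, roc
from .stack import CovariateStack

__all__ = [
    "EnsembleResult",
    "RocResult",
    "auc",
    "fit_ensemble",
    "validate_holdout",
    "split_holdout",
    "threshold_area",
    "summarize_timeseries",
]


def auc(scores_positive, scores_negative) -> RocResult:
    """Exact AUC (normalized U statistic, ties half) with the ROC curve."""
    return roc(scores_positive, scores_negative)


@dataclass
class EnsembleResult:
    submodels: list[MaxEntModel]
    submodel_grids: list[np.ndarray]
    submodel_aucs: list[float]  # training presence-vs-background AUC
    mean_grid: np.ndarray
    cv_grid: np.ndarray
    seeds: list[int]
    training_cells: set[int] = field(default_factory=set)
    # per-submodel (presence, background) feature matrices, for
    # permutation-importance and KKT inspection
    submodel_features: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def n_converged(self) -> int:
        return sum(m.converged for m in self.submodels)


def _cells_of(observations: list[SpeciesObservation], stack: CovariateStack) -> np.ndarray:
    xs = np.array([o.x for o in observations])
    ys = np.array([o.y for o in observations])
    row, col = stack.grid.cell_of(xs, ys)
    return np.asarray(stack.grid.flat_index(row, col))


def fit_ensemble(
    stack: CovariateStack,
    presences: list[SpeciesObservation],
    kernel: EffortKernel,
    n_submodels: int = 10,
    base_seed: int = 0,
    buffer_radius: float = 2000.0,
    n_background: int | None = None,
    beta0: float = 1.0,
    quadratic: bool = True,
    force_identical_backgrounds: bool = False,
    buffer_presences: list[SpeciesObservation] | None = None,
    exclude_cells: set[int] | None = None,
) -> EnsembleResult:
    """Fit ``n_submodels`` MaxEnt models over repeated pseudo-absence draws.

    Submodel k draws its background with seed ``base_seed + k``
    (``force_identical_backgrounds`` reuses ``base_seed`` for all, a
    degenerate setting useful to verify that the CV grid vanishes).  The
    ensemble proceeds if at least two submodels converge.
    """
    if n_submodels < 2:
        raise ConfigError("n_submodels must be >= 2")
    if not presences:
        raise DataError("no presences")
    pres_cells = _cells_of(presences, stack)
    pres_table = stack_table(stack, pres_cells)
    grids = []
    models = []
    aucs = []
    seeds = []
    features = []
    training_cells = set(int(c) for c in pres_cells)
    for k in range(n_submodels):
        seed = base_seed if force_identical_backgrounds else base_seed + k
        seeds.append(seed)
        pseudo = generate_pseudo_absences(
            kernel,
            buffer_presences if buffer_presences is not None else presences,
            n=n_background or len(presences),
            buffer_radius=buffer_radius,
            seed=seed,
            exclude_cells=exclude_cells,
        )
        bg_cells = _cells_of(pseudo, stack)
        bg_table = stack_table(stack, bg_cells)
        training_cells.update(int(c) for c in bg_cells)
        expansion = FeatureExpansion(kinds=dict(stack.kinds), quadratic=quadratic)
        expansion.fit(pd.concat([pres_table, bg_table], ignore_index=True))
        x_pres = expansion.transform(pres_table)
        x_bg = expansion.transform(bg_table)
        # presence samples join the background (the standard MaxEnt
        # convention): guarantees the presence feature means are attainable
        # by the Gibbs distribution, so the fit cannot diverge on separable
        # draws
        x_bg_fit = np.vstack([x_bg, x_pres])
        model = fit_maxent(x_pres, x_bg_fit, beta0=beta0, expansion=expansion)
        models.append(model)
        features.append((x_pres, x_bg_fit))
        grids.append(model.predict_stack(stack))
        aucs.append(auc_value(model.logistic(x_pres), model.logistic(x_bg)))
    if sum(m.converged for m in models) < 2:
        raise DataError("fewer than two submodels converged")
    stack_grids = np.stack(grids)
    mean_grid = stack_grids.mean(axis=0)
    sd_grid = stack_grids.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_grid = np.where(mean_grid > 0, sd_grid / mean_grid, np.nan)
    return EnsembleResult(
        submodels=models,
        submodel_grids=grids,
        submodel_aucs=aucs,
        mean_grid=mean_grid,
        cv_grid=cv_grid,
        seeds=seeds,
        training_cells=training_cells,
        submodel_features=features,
    )


def split_holdout(
    presences: list[SpeciesObservation],
    grid,
    frac: float = 0.3,
    block_cells: int = 10,
    seed: int = 0,
) -> tuple[list[SpeciesObservation], list[SpeciesObservation]]:
    """Block-stratified presence holdout split.

    Whole blocks of ``block_cells`` x ``block_cells`` grid cells are
    assigned to the holdout until about ``frac`` of the presences are
    covered, limiting spatial leakage between training and validation.
    """
    if not 0 < frac < 1:
        raise ConfigError("frac must be in (0, 1)")
    blocks: dict[int, list[SpeciesObservation]] = {}
    for o in presences:
        r, c = grid.cell_of(o.x, o.y)
        key = (r // block_cells) * 10_000 + c // block_cells
        blocks.setdefault(key, []).append(o)
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(blocks))
    target = frac * len(presences)
    holdout: list[SpeciesObservation] = []
    held_blocks = set()
    for key in order:
        if len(holdout) >= target:
            break
        holdout.extend(blocks[key])
        held_blocks.add(key)
    train = [o for key in sorted(blocks) if key not in held_blocks for o in blocks[key]]
    if not train or not holdout:
        raise DataError("degenerate holdout split: empty side")
    return train, holdout


def grid_scores_at(grid_values: np.ndarray, grid, observations: list[SpeciesObservation]) -> np.ndarray:
    xs = np.array([o.x for o in observations])
    ys = np.array([o.y for o in observations])
    row, col = grid.cell_of(xs, ys)
    return grid_values[row, col]


def validate_holdout(
    ensemble: EnsembleResult,
    holdout_presences: list[SpeciesObservation],
    holdout_absences: list[SpeciesObservation],
    stack: CovariateStack,
) -> RocResult:
    """AUC of mean-grid suitability: held-out presences vs retained absences.

    Holdout points must not share grid cells with any training point
    (presence or background); offenders are reported.
    """
    if not holdout_presences or not holdout_absences:
        raise DataError("both holdout classes must be nonempty")
    offenders = []
    for o in holdout_presences + holdout_absences:
        r, c = stack.grid.cell_of(o.x, o.y)
        cell = int(stack.grid.flat_index(r, c))
        if cell in ensemble.training_cells:
            offenders.append((o.x, o.y, cell))
    if offenders:
        raise DataError(f"holdout points share training cells: {offenders[:10]}")
    pos = grid_scores_at(ensemble.mean_grid, stack.grid, holdout_presences)
    neg = grid_scores_at(ensemble.mean_grid, stack.grid, holdout_absences)
    return roc(pos, neg)


def threshold_area(
    grid_values: np.ndarray,
    threshold: float = 0.5,
    cell_area_km2: float = 0.25,
    region_mask: np.ndarray | None = None,
) -> float:
    """Area (km^2) of cells with suitability strictly above the threshold."""
    if not 0 <= threshold <= 1:
        raise ConfigError("threshold must be in [0, 1]")
    values = np.asarray(grid_values, dtype=float)
    ok = ~np.isnan(values)
    if region_mask is not None:
        ok &= np.asarray(region_mask, dtype=bool)
    return float(np.sum(values[ok] > threshold) * cell_area_km2)


def summarize_timeseries(
    series: np.ndarray,
    statistics: tuple[str, ...] = ("mean", "min", "max", "range"),
    outlier_filter: str | None = "boxplot",
) -> dict[str, np.ndarray]:
    """Per-cell summary layers of a time-series stack with outlier filtering.

    With the boxplot filter, values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]
    (type-7 linear-interpolation quartiles) are dropped per cell before the
    statistics are computed; ``range = max - min`` after filtering.  Cells
    where every value is filtered come back as NaN.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 4:
        raise DataError("need at least 4 time steps per cell")
    known = {"mean", "min", "max", "range"}
    bad = set(statistics) - known
    if bad:
        raise ConfigError(f"unknown statistics {sorted(bad)}")
    if outlier_filter == "boxplot":
        q1 = np.percentile(series, 25, axis=0)
        q3 = np.percentile(series, 75, axis=0)
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        keep = (series >= lo) & (series <= hi)
    elif outlier_filter is None:
        keep = np.ones_like(series, dtype=bool)
    else:
        raise ConfigError(f"unknown outlier_filter {outlier_filter!r}")
    masked = np.ma.masked_array(series, mask=~keep)
    out: dict[str, np.ndarray] = {}
    mn = masked.min(axis=0).filled(np.nan)
    mx = masked.max(axis=0).filled(np.nan)
    if "mean" in statistics:
        out["mean"] = masked.mean(axis=0).filled(np.nan)
    if "min" in statistics:
        out["min"] = mn
    if "max" in statistics:
        out["max"] = mx
    if "range" in statistics:
        out["range"] = mx - mn
    return out
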