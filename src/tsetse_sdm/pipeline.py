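"""End-to-end pipeline: simulate/load -> filter -> design -> ENFA ->
ensemble MaxEnt -> validation -> export.

A :class:`RunConfig` captures every parameter and seed; running the same
config twice produces byte-identical outputs, and the manifest written
alongside the results is sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccur import CScoreResult, build_matrix, null_model_test
from .design import build_design, observations_from_traps, sampling_effort_kernel
from .enfa import ENFAResult, enfa_design_matrix, enfa_fit, standardize_global
from .errors import ConfigError, DataError, TsetseSdmError
from .evaluation import (
    EnsembleResult,
    fit_ensemble,
    split_holdout,
    threshold_area,
    validate_holdout,
)
from .fielddata import read_traps, summarize_ad, write_traps
from .grid import write_ascii_grid
from .maxent import variable_contribution
from .roc import RocResult
from .stack import CovariateStack
from .synthetic import (
    SyntheticScenario,
    generate_covariates,
    simulate_traps,
    true_suitability,
)

log = logging.getLogger("tsetse_sdm")


def _listify(obj):
    """Recursively turn tuples into lists so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    # inputs: either a synthetic scenario or paths to traps + stack
    scenario: SyntheticScenario | None = None
    traps_path: str | None = None
    stack_path: str | None = None
    species: str = "sp1"
    species_list: tuple[str, ...] = ("sp1", "sp2")
    # filtering
    buffer_radius: float = 2000.0
    mu0: float = 0.1
    alpha: float = 0.05
    # design; the 1.5 km bandwidth resolves trap clusters that Silverman's
    # rule (None) over-smooths on strongly clustered surveys
    bandwidth: float | None = 1500.0
    n_pseudo_absences: int | None = None
    n_submodels: int = 10
    seed: int = 0
    # maxent; linear + indicator features — quadratic terms are available
    # but add variance when covariate summaries are already smooth
    beta0: float = 1.0
    quadratic: bool = False
    # validation
    holdout_fraction: float = 0.3
    holdout_block_cells: int = 10
    # co-occurrence
    cscore_iterations: int = 1000
    # output
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario is None and (self.traps_path is None or self.stack_path is None):
            raise ConfigError("need either a synthetic scenario or traps_path + stack_path")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.mu0 <= 0:
            raise ConfigError("mu0 must be > 0")
        if self.buffer_radius <= 0:
            raise ConfigError("buffer_radius must be > 0")
        if self.n_submodels < 2:
            raise ConfigError("n_submodels must be >= 2")
        if not 0 < self.holdout_fraction < 1:
            raise ConfigError("holdout_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return _listify(asdict(self))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if raw.get("scenario") is not None:
            sc = dict(raw["scenario"])
            for key in ("grid_shape", "true_coefficients", "trap_days_range"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            raw["scenario"] = SyntheticScenario(**sc)
        if "species_list" in raw and raw["species_list"] is not None:
            raw["species_list"] = tuple(raw["species_list"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(raw)

    def parameter_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    stack: CovariateStack
    records: list
    design: object
    enfa: ENFAResult
    ensemble: EnsembleResult
    holdout_roc: RocResult | None
    cscore: CScoreResult | None
    contributions: pd.Series
    threshold_area_km2: float
    truth: object | None = None  # TruthSurface dict when synthetic


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except TsetseSdmError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the whole inference chain and (optionally) export artefacts."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    created = False
    if out_dir is not None:
        created = not out_dir.exists()
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        result = _run(config, out_dir)
    except Exception:
        if out_dir is not None:
            # remove partial outputs: a failed run must not look like a run
            shutil.rmtree(out_dir) if created else _clear_dir(out_dir)
        raise
    return result


def _clear_dir(path: Path) -> None:
    for child in path.iterdir():
        if child.is_dir():
            shutil.rmtree(child)
        else:
            child.unlink()


@_stage("inputs")
def _load_inputs(config: RunConfig):
    truths = None
    if config.scenario is not None:
        scenario = config.scenario
        stack = generate_covariates(scenario)
        coeffs = np.asarray(scenario.true_coefficients, dtype=float)
        truths = {}
        for i, sp in enumerate(config.species_list):
            # second and later species share the niche direction with damped
            # coefficients: overlapping but not identical distributions
            factor = 1.0 if i == 0 else 0.75**i
            truths[sp] = true_suitability(stack, coeffs * factor, scenario.protected_effect)
        records = simulate_traps(stack, truths, scenario)
    else:
        stack = CovariateStack.from_dir(config.stack_path)
        records = read_traps(config.traps_path)
    if not records:
        raise DataError("no trap records")
    return stack, records, truths


@_stage("design")
def _design(config: RunConfig, stack, records):
    observations = observations_from_traps(records, config.species)
    if not any(o.presence for o in observations):
        raise DataError(f"species {config.species!r} has no presences")
    trap_xy = np.array([[r.x, r.y] for r in records])
    return build_design(
        observations,
        stack.grid,
        trap_xy,
        n_pseudo_absences=config.n_pseudo_absences,
        buffer_radius=config.buffer_radius,
        mu0=config.mu0,
        alpha=config.alpha,
        bandwidth=config.bandwidth,
        mask=stack.mask,
        seed=config.seed,
    )


@_stage("enfa")
def _enfa(stack, design):
    matrix, names = enfa_design_matrix(stack)
    z, std = standardize_global(matrix, names)
    valid = stack.valid_indices()
    xs = np.array([o.x for o in design.presences])
    ys = np.array([o.y for o in design.presences])
    row, col = stack.grid.cell_of(xs, ys)
    flat = np.asarray(stack.grid.flat_index(row, col))
    pos = np.searchsorted(valid, flat)
    return enfa_fit(z, pos, names=names)


@_stage("ensemble")
def _ensemble(config: RunConfig, stack, design, records):
    train_pres, holdout_pres = split_holdout(
        design.presences,
        stack.grid,
        frac=config.holdout_fraction,
        block_cells=config.holdout_block_cells,
        seed=config.seed,
    )
    # validation cells are reserved from the background draw so the holdout
    # stays disjoint from every training cell
    reserve = set()
    for o in holdout_pres + design.retained_absences:
        r, c = stack.grid.cell_of(o.x, o.y)
        reserve.add(int(stack.grid.flat_index(r, c)))
    trap_xy = np.array([[r.x, r.y] for r in records])
    kernel = sampling_effort_kernel(trap_xy, stack.grid, bandwidth=config.bandwidth, mask=stack.mask)
    ensemble = fit_ensemble(
        stack,
        train_pres,
        kernel,
        n_submodels=config.n_submodels,
        base_seed=config.seed,
        buffer_radius=config.buffer_radius,
        n_background=config.n_pseudo_absences,
        beta0=config.beta0,
        quadratic=config.quadratic,
        buffer_presences=design.presences,
        exclude_cells=reserve,
    )
    holdout_roc = None
    if holdout_pres and design.retained_absences:
        holdout_roc = validate_holdout(ensemble, holdout_pres, design.retained_absences, stack)
    return ensemble, holdout_roc


@_stage("cooccurrence")
def _cscore(config: RunConfig, records):
    try:
        matrix = build_matrix(records, list(config.species_list))
    except DataError:
        return None
    # fixed-rows null: with two species the fixed-fixed swap chain cannot
    # change the number of shared sites, so the C-score would never vary
    algorithm = "fixed_rows" if len(config.species_list) == 2 else "fixed_fixed"
    return null_model_test(
        matrix, n_iterations=config.cscore_iterations, seed=config.seed, algorithm=algorithm
    )


def _run(config: RunConfig, out_dir: Path | None) -> PipelineResult:
    stack, records, truths = _load_inputs(config)
    design = _design(config, stack, records)
    enfa_result = _enfa(stack, design)
    ensemble, holdout_roc = _ensemble(config, stack, design, records)
    cscore = _cscore(config, records)

    # per-submodel variable contributions, averaged
    contribs = []
    for model, (x_pres, x_bg) in zip(ensemble.submodels, ensemble.submodel_features):
        if model.converged:
            contribs.append(
                variable_contribution(model, x_pres, x_bg, n_permutations=3, seed=config.seed)
            )
    contributions = (
        pd.concat(contribs, axis=1).mean(axis=1).sort_values(ascending=False)
        if contribs
        else pd.Series(dtype=float)
    )
    cell_area = (stack.grid.cell / 1000.0) ** 2
    area = threshold_area(ensemble.mean_grid, threshold=0.5, cell_area_km2=cell_area)

    result = PipelineResult(
        config=config,
        stack=stack,
        records=records,
        design=design,
        enfa=enfa_result,
        ensemble=ensemble,
        holdout_roc=holdout_roc,
        cscore=cscore,
        contributions=contributions,
        threshold_area_km2=area,
        truth=truths,
    )
    if out_dir is not None:
        _export(result, out_dir)
    return result


@_stage("export")
def _export(result: PipelineResult, out_dir: Path) -> None:
    config = result.config
    stack = result.stack
    write_traps(result.records, out_dir / "traps.csv")
    result.design.to_csv(out_dir / "design.csv")
    result.enfa.to_csv(out_dir / "enfa_loadings.csv")
    pd.DataFrame(
        {
            "submodel": range(len(result.ensemble.submodels)),
            "seed": result.ensemble.seeds,
            "training_auc": result.ensemble.submodel_aucs,
            "converged": [m.converged for m in result.ensemble.submodels],
        }
    ).to_csv(out_dir / "submodels.csv", index=False)
    result.contributions.rename("contribution_pct").to_csv(out_dir / "contributions.csv")
    write_ascii_grid(out_dir / "mean_suitability.asc", stack.grid, result.ensemble.mean_grid)
    write_ascii_grid(out_dir / "cv_uncertainty.asc", stack.grid, result.ensemble.cv_grid)
    for sp in config.species_list:
        try:
            summaries = summarize_ad(result.records, sp, "vegetation_class")
        except DataError:
            continue
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(
            out_dir / f"ad_by_vegetation_{sp}.csv", index=False
        )
    report = {
        "species": config.species,
        "threshold_area_km2": result.threshold_area_km2,
        "holdout_auc": result.holdout_roc.auc if result.holdout_roc else None,
        "mean_training_auc": float(np.mean(result.ensemble.submodel_aucs)),
        "cscore": None
        if result.cscore is None
        else {
            "observed": result.cscore.observed,
            "null_mean": result.cscore.null_mean,
            "ses": result.cscore.ses,
            "p_value": result.cscore.p_value,
            "direction": result.cscore.direction,
        },
    }
    (out_dir / "report.yml").write_text(yaml.safe_dump(report, sort_keys=False))
    manifest = {
        "package": "tsetse-sdm",
        "version": __version__,
        "parameter_hash": config.parameter_hash(),
        "config": config.to_dict(),
        "submodel_seeds": result.ensemble.seeds,
    }
    (out_dir / "manifest.yml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING if quiet else (logging.DEBUG if verbose else logging.INFO)
    logging.basicConfig(stream=sys.stderr, level=level, format="%(levelname)s %(message)s")
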