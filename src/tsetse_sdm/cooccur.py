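"""Species co-occurrence: presence-absence matrices and the checkerboard score.

The C-score of Stone & Roberts measures "checkerboardness": for a species
pair (i, j) with row totals R_i, R_j and S shared sites, the number of
checkerboard units is CU = (R_i - S)(R_j - S); the C-score is the mean CU
over all species pairs.  High values indicate spatial segregation, values
near zero aggregation.  A normalized variant CU / (R_i * R_j), bounded in
[0, 1], is reported alongside because the raw score depends on matrix fill.

Significance is assessed against a fixed-fixed null model: random matrices
with exactly the observed row and column totals, sampled by a sequential
2x2 checkerboard-swap Markov chain with burn-in and thinning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateNullError
from .fielddata import TrapRecord


@dataclass
class CooccurrenceMatrix:
    species: list[str]
    sites: list[str]
    values: np.ndarray  # binary, species x sites

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.species), len(self.sites)):
            raise DataError("matrix shape does not match labels")
        if not np.isin(self.values, (0, 1)).all():
            raise DataError("matrix entries must be 0/1")
        if len(self.species) < 2 or len(self.sites) < 2:
            raise DataError("need at least 2 species and 2 sites")
        self.values = self.values.astype(int)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.species, columns=self.sites).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CooccurrenceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class CScore:
    raw: float
    normalized: float
    pair_units: list[tuple[str, str, float, float]]  # (sp_i, sp_j, CU, CU_norm)


@dataclass
class CScoreResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_iterations: int
    seed: int
    direction: str = "none"  # "aggregation" | "segregation" | "none"
    null_scores: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def build_matrix(
    records: list[TrapRecord],
    species_list: list[str],
    presence_rule=None,
) -> CooccurrenceMatrix:
    """Site x species presence-absence matrix from trap records.

    Counts are summed over all records of a site before the presence rule
    (default: total count > 0) is applied.
    """
    if not records:
        raise DataError("no records")
    if presence_rule is None:
        presence_rule = lambda total: total > 0  # noqa: E731
    totals: dict[str, dict[str, int]] = {}
    for r in records:
        site = totals.setdefault(r.site_id, dict.fromkeys(species_list, 0))
        for sp in species_list:
            site[sp] += r.species_counts.get(sp, 0)
    sites = sorted(totals)
    values = np.array(
        [[1 if presence_rule(totals[s][sp]) else 0 for s in sites] for sp in species_list]
    )
    if len(species_list) < 2 or len(sites) < 2:
        raise DataError("need >= 2 species and >= 2 sites after aggregation")
    return CooccurrenceMatrix(list(species_list), sites, values)


def c_score(matrix: CooccurrenceMatrix | np.ndarray) -> CScore:
    """Mean checkerboard units over species pairs, raw and normalized."""
    if isinstance(matrix, CooccurrenceMatrix):
        values = matrix.values
        labels = matrix.species
    else:
        values = np.asarray(matrix, dtype=int)
        labels = [f"sp{i}" for i in range(values.shape[0])]
    pairs = []
    for i, j in combinations(range(values.shape[0]), 2):
        ri = int(values[i].sum())
        rj = int(values[j].sum())
        shared = int((values[i] & values[j]).sum())
        cu = float((ri - shared) * (rj - shared))
        norm = cu / (ri * rj) if ri > 0 and rj > 0 else 0.0
        pairs.append((labels[i], labels[j], cu, norm))
    raw = float(np.mean([p[2] for p in pairs]))
    normalized = float(np.mean([p[3] for p in pairs]))
    return CScore(raw=raw, normalized=normalized, pair_units=pairs)


def has_checkerboard(values: np.ndarray) -> bool:
    """True if any 2x2 submatrix is a checkerboard (i.e. a swap exists)."""
    values = np.asarray(values, dtype=int)
    for i, j in combinations(range(values.shape[0]), 2):
        a, b = values[i], values[j]
        # need one site with (1,0) and another with (0,1)
        if np.any((a == 1) & (b == 0)) and np.any((a == 0) & (b == 1)):
            return True
    return False


def _swap_step(values: np.ndarray, rng: np.random.Generator) -> None:
    """One attempted checkerboard swap (margins preserved)."""
    nr, nc = values.shape
    r1, r2 = rng.choice(nr, size=2, replace=False)
    c1, c2 = rng.choice(nc, size=2, replace=False)
    a, b = values[r1, c1], values[r1, c2]
    c, d = values[r2, c1], values[r2, c2]
    if a + d == 2 and b + c == 0 or a + d == 0 and b + c == 2:
        values[r1, c1], values[r1, c2] = b, a
        values[r2, c1], values[r2, c2] = d, c


def null_matrices(
    values: np.ndarray,
    n_iterations: int,
    rng: np.random.Generator,
    burn_in: int | None = None,
    thin: int | None = None,
):
    """Yield fixed-fixed null matrices from the swap chain."""
    current = np.array(values, dtype=int)
    n_cells = current.size
    burn_in = 10 * n_cells if burn_in is None else burn_in
    thin = n_cells if thin is None else thin
    for _ in range(burn_in):
        _swap_step(current, rng)
    for _ in range(n_iterations):
        for _ in range(thin):
            _swap_step(current, rng)
        yield current


def _fixed_rows_nulls(values: np.ndarray, n_iterations: int, rng: np.random.Generator):
    """Row totals preserved, ones placed equiprobably across sites."""
    nr, nc = values.shape
    row_sums = values.sum(axis=1)
    for _ in range(n_iterations):
        null = np.zeros_like(values)
        for i in range(nr):
            cols = rng.choice(nc, size=row_sums[i], replace=False)
            null[i, cols] = 1
        yield null


def null_model_test(
    matrix: CooccurrenceMatrix | np.ndarray,
    n_iterations: int = 1000,
    seed: int = 0,
    statistic: str = "normalized",
    algorithm: str = "fixed_fixed",
    strict: bool = False,
) -> CScoreResult:
    """Randomization test of the C-score.

    ``algorithm="fixed_fixed"`` (default) preserves both margins via
    sequential checkerboard swaps.  ``"fixed_rows"`` preserves row totals
    only, placing each species' occurrences equiprobably across sites —
    the appropriate null for two-species matrices, where fixed-fixed is
    combinatorially degenerate (swaps cannot change the number of shared
    sites when there are only two rows).

    The two-sided Monte-Carlo p-value uses the add-one correction
    (k + 1)/(n + 1).  A fixed-fixed matrix admitting no checkerboard swap
    is its own margins' unique completion; by default this returns p = 1
    with a warning (``strict=True`` raises :class:`DegenerateNullError`).
    """
    if n_iterations < 100:
        raise DataError("n_iterations must be >= 100")
    values = matrix.values if isinstance(matrix, CooccurrenceMatrix) else np.asarray(matrix, dtype=int)
    key = statistic
    if key not in ("raw", "normalized"):
        raise DataError(f"unknown statistic {statistic!r}")
    if algorithm not in ("fixed_fixed", "fixed_rows"):
        raise DataError(f"unknown algorithm {algorithm!r}")
    observed = getattr(c_score(values), key)
    if algorithm == "fixed_fixed" and not has_checkerboard(values):
        if strict:
            raise DegenerateNullError("no swappable 2x2 submatrix: null distribution is degenerate")
        warnings.warn("degenerate null: matrix is the unique completion of its margins")
        return CScoreResult(
            observed=observed,
            null_mean=observed,
            null_sd=0.0,
            ses=0.0,
            p_value=1.0,
            n_iterations=n_iterations,
            seed=seed,
            null_scores=np.full(n_iterations, observed),
        )
    rng = np.random.default_rng(seed)
    nulls = (
        null_matrices(values, n_iterations, rng)
        if algorithm == "fixed_fixed"
        else _fixed_rows_nulls(values, n_iterations, rng)
    )
    null = np.array([getattr(c_score(m), key) for m in nulls])
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    ses = (observed - null_mean) / null_sd if null_sd > 0 else 0.0
    k_ge = int(np.sum(null >= observed))
    k_le = int(np.sum(null <= observed))
    p = min(1.0, 2 * min(k_ge + 1, k_le + 1) / (n_iterations + 1))
    direction = "none"
    if ses < 0:
        direction = "aggregation"
    elif ses > 0:
        direction = "segregation"
    return CScoreResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=float(ses),
        p_value=float(p),
        n_iterations=n_iterations,
        seed=seed,
        direction=direction,
        null_scores=null,
    )
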