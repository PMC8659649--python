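"""Ecological Niche Factor Analysis (ENFA).

ENFA contrasts the environmental space *used* by a species (cells where it
occurs) with the space *available* in the study area.  With covariates
standardized to the available space (global mean 0, sd 1):

* the **marginality vector** m is the mean of the standardized covariates
  over presence cells — how far, in global-SD units, the niche barycentre
  sits from the average available conditions.  The marginality index is
  ||m|| / 1.96, so an index near 1 places the barycentre at the one-sided
  97.5% bound of the available space.
* **specialization** measures niche narrowness: eigenvalues of the
  available-space covariance relative to the used-space covariance,
  restricted to the orthogonal complement of the marginality axis.  An
  eigenvalue of 9 means the species occupies one ninth of the available
  variance along that axis; used == available gives eigenvalues ~1.

Categorical layers (vegetation class, protection) enter as 0/1 indicator
columns, since the factorization needs numeric input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .errors import DataError, NumericalError
from .stack import BINARY, CATEGORICAL, CONTINUOUS, CovariateStack

RIDGE = 1e-8


@dataclass
class Standardization:
    names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.sds + self.means


@dataclass
class ENFAResult:
    names: list[str]
    marginality_vector: np.ndarray  # per covariate, global-SD units
    marginality_index: float
    specialization_eigenvalues: np.ndarray  # nonincreasing, length p-1
    global_specialization: float
    axis_loadings: np.ndarray  # covariate x axis, unit-norm columns
    presence_scores: np.ndarray  # presences projected on axes 1-2
    global_scores: np.ndarray  # all cells projected on axes 1-2

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.axis_loadings,
            index=self.names,
            columns=[f"axis{i + 1}" for i in range(self.axis_loadings.shape[1])],
        )
        df.insert(0, "marginality", self.marginality_vector)
        df.to_csv(path)

    def marginality_percent(self) -> pd.Series:
        """|marginality component| as a percentage of the total, per covariate."""
        a = np.abs(self.marginality_vector)
        return pd.Series(100 * a / a.sum(), index=self.names)


def enfa_design_matrix(stack: CovariateStack) -> tuple[np.ndarray, list[str]]:
    """Valid-cell matrix with categorical layers expanded to indicators.

    The first level of each categorical layer is dropped as the reference,
    since a full indicator set is exactly collinear (sums to one).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    flat = stack.mask.ravel()
    for name in stack.names():
        kind = stack.kinds[name]
        vals = stack[name].ravel()[flat]
        if kind in (CONTINUOUS, BINARY):
            cols.append(vals.astype(float))
            names.append(name)
        elif kind == CATEGORICAL:
            for level in np.unique(vals)[1:]:
                cols.append((vals == level).astype(float))
                names.append(f"{name}={level}")
    return np.column_stack(cols), names


def standardize_global(
    matrix: np.ndarray, names: list[str]
) -> tuple[np.ndarray, Standardization]:
    """Centre and scale each covariate by its available-space mean and sd."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < 2:
        raise DataError("need at least 2 covariates")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise DataError(f"zero-variance covariate(s): {[names[i] for i in zero]}")
    z = (matrix - means) / sds
    return z, Standardization(names=list(names), means=means, sds=sds)


def enfa_fit(standardized_global: np.ndarray, presence_idx: np.ndarray,
             names: list[str] | None = None) -> ENFAResult:
    """Hirzel-style ENFA factorization of used vs available space."""
    z = np.asarray(standardized_global, dtype=float)
    presence_idx = np.asarray(presence_idx, dtype=int)
    n, p = z.shape
    if names is None:
        names = [f"cov{i + 1}" for i in range(p)]
    if presence_idx.size < p + 2:
        raise DataError(f"need at least {p + 2} presence cells for {p} covariates")
    zp = z[presence_idx]
    m = zp.mean(axis=0)
    rg = z.T @ z / n  # available-space covariance (correlation, data standardized)
    zc = zp - m
    rs = zc.T @ zc / len(zp)  # used-space covariance
    cond = np.linalg.cond(rs)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("near-singular used-space covariance; ridge-regularized")
    rs = rs + RIDGE * np.eye(p)
    # inverse square root of the used-space covariance
    evals, evecs = np.linalg.eigh(rs)
    if np.any(evals <= 0):
        raise NumericalError("used-space covariance not positive definite")
    rs12 = evecs @ np.diag(evals**-0.5) @ evecs.T
    w = rs12 @ m
    norm_w = np.linalg.norm(w)
    if norm_w == 0:
        # no marginality at all: pick an arbitrary unit direction
        zdir = np.zeros(p)
        zdir[0] = 1.0
    else:
        zdir = w / norm_w
    y = rs12 @ rg @ rs12
    proj = np.eye(p) - np.outer(zdir, zdir)
    h = proj @ y @ proj
    spec_vals, spec_vecs = np.linalg.eigh(h)
    order = np.argsort(spec_vals)[::-1]
    spec_vals = np.clip(spec_vals[order][: p - 1], 0, None)
    spec_vecs = spec_vecs[:, order][:, : p - 1]
    # map specialization axes back to covariate space and unit-normalize
    axes = [m / np.linalg.norm(m) if np.linalg.norm(m) > 0 else zdir]
    for k in range(p - 1):
        u = rs12 @ spec_vecs[:, k]
        axes.append(u / np.linalg.norm(u))
    loadings = np.column_stack(axes)
    scores_axes = loadings[:, :2]
    return ENFAResult(
        names=list(names),
        marginality_vector=m,
        marginality_index=float(np.linalg.norm(m) / 1.96),
        specialization_eigenvalues=spec_vals,
        global_specialization=float(np.sqrt(spec_vals.mean())),
        axis_loadings=loadings,
        presence_scores=zp @ scores_axes,
        global_scores=z @ scores_axes,
    )


@dataclass
class BiplotCoords:
    arrows: np.ndarray  # covariate x 2, axis-1/2 loadings scaled
    arrow_names: list[str]
    global_hull: np.ndarray  # hull vertices (k, 2)
    presence_hull: np.ndarray
    presence_barycentre: np.ndarray


def _hull(points: np.ndarray, quantile: float) -> np.ndarray:
    pts = np.asarray(points)
    if 0 < quantile < 1:
        center = pts.mean(axis=0)
        radius = np.linalg.norm(pts - center, axis=1)
        pts = pts[radius <= np.quantile(radius, quantile)]
    if len(pts) < 3:
        return pts
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def biplot_coords(result: ENFAResult, polygon_quantile: float = 1.0) -> BiplotCoords:
    """Variable arrows and used/available hulls for a niche biplot."""
    scale = np.array([max(result.marginality_index, 1e-12),
                      max(result.global_specialization, 1e-12)])
    arrows = result.axis_loadings[:, :2] * scale
    return BiplotCoords(
        arrows=arrows,
        arrow_names=list(result.names),
        global_hull=_hull(result.global_scores, polygon_quantile),
        presence_hull=_hull(result.presence_scores, polygon_quantile),
        presence_barycentre=result.presence_scores.mean(axis=0),
    )


def plot_biplot(result: ENFAResult, ax=None, polygon_quantile: float = 1.0):
    """Render the niche biplot (lazy matplotlib import)."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon

    coords = biplot_coords(result, polygon_quantile)
    if ax is None:
        _, ax = plt.subplots()
    for hull, color in ((coords.global_hull, "0.85"), (coords.presence_hull, "0.55")):
        if len(hull) >= 3:
            ax.add_patch(Polygon(hull, closed=True, facecolor=color, edgecolor="none"))
    for (dx, dy), name in zip(coords.arrows, coords.arrow_names):
        ax.annotate(name, (dx, dy), fontsize=8)
        ax.arrow(0, 0, dx, dy, head_width=0.02, color="black")
    bx, by = coords.presence_barycentre
    ax.plot([bx], [by], "o", mfc="white", mec="black")
    ax.set_xlabel("marginality axis")
    ax.set_ylabel("specialization axis 1")
    return ax
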