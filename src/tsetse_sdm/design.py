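"""Spatial filtering and effort-corrected pseudo-absence generation.

Presence-only niche models need a background sample representing the
environment actually surveyed, otherwise survey bias masquerades as habitat
preference.  The design stage therefore:

1. thins observations to one record per 500 m pixel (densest-effort record
   kept),
2. removes true absences within a 2 km closed buffer of any presence (the
   species' typical flight range),
3. drops "non-significant" absences — zero catches too short to rule out
   presence under a Poisson zero-catch model P(no catch) = exp(-mu0 * D),
   where mu0 is the minimum catch rate worth detecting (flies/trap/day) and
   D the trap-days; an absence is kept only when this false-absence
   probability is <= alpha,
4. builds a Gaussian kernel density of trapping effort over the grid, and
5. samples pseudo-absence cells proportionally to that effort kernel,
   excluding the presence buffer, at most one per cell.

Retained true absences are reserved for validation and never enter the
training background.  All distances are planar Euclidean metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError
from .fielddata import TrapRecord
from .grid import GridSpec

DEFAULT_BUFFER_M = 2000.0
DEFAULT_MU0 = 0.1  # flies/trap/day; order of the sparser species' observed AD


@dataclass(frozen=True)
class SpeciesObservation:
    x: float
    y: float
    species: str
    presence: bool
    trap_days: int = 1
    source: str = "observed"  # "observed" | "pseudo_absence"

    def __post_init__(self) -> None:
        if self.source == "pseudo_absence" and self.presence:
            raise DataError("pseudo-absences cannot be presences")
        if self.source == "observed" and self.trap_days < 1:
            raise DataError("observed records need trap_days >= 1")


def observations_from_traps(records: list[TrapRecord], species: str) -> list[SpeciesObservation]:
    """Presence/absence observations for one species (presence = count > 0)."""
    return [
        SpeciesObservation(
            x=r.x,
            y=r.y,
            species=species,
            presence=r.species_counts.get(species, 0) > 0,
            trap_days=r.trap_days,
        )
        for r in records
    ]


@dataclass
class EffortKernel:
    """Normalized sampling-effort density over grid cells."""

    grid: GridSpec
    density: np.ndarray  # (nrows, ncols), sums to 1 over valid cells
    bandwidth: float

    def __post_init__(self) -> None:
        if self.density.shape != self.grid.shape:
            raise DataError("density shape does not match grid")
        if np.any(self.density < 0):
            raise DataError("density must be nonnegative")
        total = float(np.nansum(self.density))
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"density must sum to 1, got {total}")


@dataclass
class PresenceBackgroundDesign:
    presences: list[SpeciesObservation]
    retained_absences: list[SpeciesObservation]
    pseudo_absences: list[SpeciesObservation]
    grid: GridSpec
    buffer_radius: float
    seed: int
    mu0: float = DEFAULT_MU0
    bandwidth: float | None = None

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for role, obs_list in (
            ("presence", self.presences),
            ("retained_absence", self.retained_absences),
            ("pseudo_absence", self.pseudo_absences),
        ):
            for o in obs_list:
                rows.append({"role": role, "x": o.x, "y": o.y, "species": o.species,
                             "trap_days": o.trap_days, "source": o.source})
        pd.DataFrame(rows).to_csv(path, index=False)


def _coords(observations: list[SpeciesObservation]) -> np.ndarray:
    return np.array([[o.x, o.y] for o in observations], dtype=float).reshape(-1, 2)


def thin_per_pixel(
    observations: list[SpeciesObservation], grid: GridSpec
) -> list[SpeciesObservation]:
    """One record per occupied pixel: greatest trap_days wins, first-come on ties."""
    best: dict[int, SpeciesObservation] = {}
    for obs in observations:
        r, c = grid.cell_of(obs.x, obs.y)
        key = int(grid.flat_index(r, c))
        incumbent = best.get(key)
        if incumbent is None or obs.trap_days > incumbent.trap_days:
            best[key] = obs
    # preserve input order of the retained records
    kept = set(id(o) for o in best.values())
    return [o for o in observations if id(o) in kept]


def remove_absences_near_presence(
    observations: list[SpeciesObservation], radius: float = DEFAULT_BUFFER_M
) -> list[SpeciesObservation]:
    """Drop absences within a closed ``radius`` buffer of any presence."""
    if radius <= 0:
        raise ConfigError("radius must be > 0")
    presences = [o for o in observations if o.presence]
    if not presences:
        return list(observations)
    pcoords = _coords(presences)
    out = []
    for obs in observations:
        if obs.presence:
            out.append(obs)
            continue
        d = np.sqrt(((pcoords - [obs.x, obs.y]) ** 2).sum(axis=1)).min()
        if d > radius:
            out.append(obs)
    return out


def min_significant_trap_days(mu0: float, alpha: float = 0.05) -> float:
    """Trap-days needed for a zero catch to be a significant absence."""
    return -np.log(alpha) / mu0


def significant_absences(
    observations: list[SpeciesObservation],
    mu0: float = DEFAULT_MU0,
    alpha: float = 0.05,
) -> list[SpeciesObservation]:
    """Keep absences whose false-absence probability exp(-mu0*D) is <= alpha.

    A zero catch over D trap-days is compatible with a true density mu0
    with Poisson probability exp(-mu0 * D); short deployments cannot
    distinguish absence from bad luck and are removed.  Presences pass
    through untouched.
    """
    if mu0 <= 0:
        raise ConfigError("mu0 must be > 0")
    if not 0 < alpha <= 1:
        raise ConfigError("alpha must be in (0, 1]")
    out = []
    for obs in observations:
        if obs.presence:
            out.append(obs)
        elif np.exp(-mu0 * obs.trap_days) <= alpha:
            out.append(obs)
    return out


def silverman_bandwidth(coords: np.ndarray) -> float:
    """Silverman's rule of thumb on trap coordinates (metres, isotropic)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return 1.0
    sd = float(np.mean(coords.std(axis=0, ddof=1)))
    if sd == 0:
        return 1.0
    return 1.06 * sd * n ** (-1 / 5)


def sampling_effort_kernel(
    trap_locations: np.ndarray,
    grid: GridSpec,
    bandwidth: float | None = None,
    mask: np.ndarray | None = None,
) -> EffortKernel:
    """Gaussian kernel density of trapping effort at cell centres.

    ``trap_locations`` is an (n, 2) array of x/y coordinates; the result is
    masked (if a validity mask is given) and renormalized to sum to 1.
    """
    trap_locations = np.asarray(trap_locations, dtype=float).reshape(-1, 2)
    if len(trap_locations) == 0:
        raise DataError("need at least one trap to build an effort kernel")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(trap_locations)
    if bandwidth <= 0:
        raise ConfigError("bandwidth must be > 0")
    xs, ys = grid.center_mesh()
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    d2 = cdist(centers, trap_locations, "sqeuclidean")
    density = np.exp(-d2 / (2 * bandwidth**2)).sum(axis=1).reshape(grid.shape)
    if mask is not None:
        density = np.where(mask, density, 0.0)
    total = density.sum()
    if total <= 0:
        raise DataError("effort kernel has zero mass over valid cells")
    return EffortKernel(grid=grid, density=density / total, bandwidth=float(bandwidth))


def generate_pseudo_absences(
    kernel: EffortKernel,
    presences: list[SpeciesObservation],
    n: int,
    buffer_radius: float = DEFAULT_BUFFER_M,
    seed: int = 0,
    species: str = "sp",
    exclude_cells: set[int] | None = None,
) -> list[SpeciesObservation]:
    """Sample background cells proportionally to sampling effort.

    Cells within ``buffer_radius`` (closed) of any presence are excluded;
    at most one pseudo-absence per cell, placed at the cell centre; exactly
    ``min(n, eligible)`` points are returned.  ``exclude_cells`` (flat
    indices) lets callers reserve cells — e.g. validation points — from
    the background draw.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    grid = kernel.grid
    xs, ys = grid.center_mesh()
    centers = np.column_stack([xs.ravel(), ys.ravel()])
    eligible = kernel.density.ravel() > 0
    if exclude_cells:
        eligible[np.fromiter(exclude_cells, dtype=int)] = False
    if presences:
        pcoords = _coords(presences)
        dmin = cdist(centers, pcoords).min(axis=1)
        eligible &= dmin > buffer_radius
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise DataError("no eligible cells for pseudo-absences after buffering")
    probs = kernel.density.ravel()[idx]
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    take = min(n, idx.size)
    chosen = rng.choice(idx, size=take, replace=False, p=probs)
    sp = presences[0].species if presences else species
    return [
        SpeciesObservation(
            x=float(centers[i, 0]),
            y=float(centers[i, 1]),
            species=sp,
            presence=False,
            trap_days=1,
            source="pseudo_absence",
        )
        for i in chosen
    ]


def build_design(
    observations: list[SpeciesObservation],
    grid: GridSpec,
    all_trap_locations: np.ndarray,
    n_pseudo_absences: int | None = None,
    buffer_radius: float = DEFAULT_BUFFER_M,
    mu0: float = DEFAULT_MU0,
    alpha: float = 0.05,
    bandwidth: float | None = None,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> PresenceBackgroundDesign:
    """Full design pipeline: thin -> buffer-remove -> significance-filter ->
    effort kernel -> pseudo-absences.

    ``n_pseudo_absences`` defaults to the number of retained presences.
    """
    thinned = thin_per_pixel(observations, grid)
    buffered = remove_absences_near_presence(thinned, radius=buffer_radius)
    filtered = significant_absences(buffered, mu0=mu0, alpha=alpha)
    presences = [o for o in filtered if o.presence]
    absences = [o for o in filtered if not o.presence]
    if not presences:
        raise DataError("no presences remain after filtering")
    kernel = sampling_effort_kernel(all_trap_locations, grid, bandwidth=bandwidth, mask=mask)
    n_pa = len(presences) if n_pseudo_absences is None else n_pseudo_absences
    pseudo = generate_pseudo_absences(
        kernel, presences, n_pa, buffer_radius=buffer_radius, seed=seed
    )
    return PresenceBackgroundDesign(
        presences=presences,
        retained_absences=absences,
        pseudo_absences=pseudo,
        grid=grid,
        buffer_radius=buffer_radius,
        seed=seed,
        mu0=mu0,
        bandwidth=kernel.bandwidth,
    )
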