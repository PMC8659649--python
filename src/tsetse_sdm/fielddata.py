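"""Trap records, apparent density and nonparametric group comparison.

The exposure unit is the trap-day; apparent density (AD) is flies per trap
per day.  Group summaries report the mean and sample (n-1) standard
deviation of per-record ADs, matching the "mean +/- sd" presentation common
in entomological surveys; a pooled variant (total catch over total
trap-days) is provided separately.

Group comparisons use the Kruskal-Wallis rank test with tie correction,
followed by Dunn's pairwise z-tests (Bonferroni-adjusted by default) when
the global test is significant — the appropriate choice for strongly
skewed, overdispersed catch data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DataError

#: schema version written in the trap CSV header comment column order
TRAP_CSV_COLUMNS = [
    "trap_id",
    "site_id",
    "x",
    "y",
    "trap_days",
    "vegetation_class",
    "in_protected",
    "distance_to_protected",
]
TRAP_CSV_SCHEMA_VERSION = "1"

DISTANCE_BANDS = ("inside", "0-5km", ">5km")
_BAND_EDGE_M = 5000.0


@dataclass
class TrapRecord:
    """One trap deployment with per-species catch totals."""

    trap_id: str
    site_id: str
    x: float
    y: float
    species_counts: dict[str, int]
    trap_days: int
    vegetation_class: str
    in_protected: bool
    distance_to_protected: float

    def __post_init__(self) -> None:
        if self.trap_days < 1:
            raise DataError(f"trap {self.trap_id}: trap_days must be >= 1")
        for sp, c in self.species_counts.items():
            if c < 0:
                raise DataError(f"trap {self.trap_id}: negative count for {sp}")
        if self.in_protected != (self.distance_to_protected == 0):
            raise DataError(
                f"trap {self.trap_id}: distance_to_protected == 0 must hold "
                "exactly when the trap is inside a protected area"
            )

    @property
    def distance_band(self) -> str:
        if self.in_protected:
            return DISTANCE_BANDS[0]
        return DISTANCE_BANDS[1] if self.distance_to_protected <= _BAND_EDGE_M else DISTANCE_BANDS[2]


@dataclass
class AdSummary:
    group: str
    n_records: int
    mean_ad: float
    sd_ad: float


def apparent_density(record: TrapRecord, species: str) -> float:
    """Flies per trap per day for one record."""
    if species not in record.species_counts:
        raise DataError(f"species {species!r} not recorded at trap {record.trap_id}")
    return record.species_counts[species] / record.trap_days


def pooled_ad(records: list[TrapRecord], species: str) -> float:
    """Pooled catch rate: total flies over total trap-days."""
    if not records:
        raise DataError("no records")
    total = sum(r.species_counts.get(species, 0) for r in records)
    days = sum(r.trap_days for r in records)
    return total / days


def summarize_ad(
    records: list[TrapRecord],
    species: str,
    group_by: str = "vegetation_class",
) -> list[AdSummary]:
    """Mean +/- sd of per-record AD by vegetation class, protection or distance band.

    ``group_by`` is one of ``"vegetation_class"``, ``"in_protected"`` or
    ``"distance_band"``.  Groups without records are omitted; the sd of a
    single-record group is 0.
    """
    if not records:
        raise DataError("no records to summarize")
    keyfun = {
        "vegetation_class": lambda r: r.vegetation_class,
        "in_protected": lambda r: "protected" if r.in_protected else "unprotected",
        "distance_band": lambda r: r.distance_band,
    }.get(group_by)
    if keyfun is None:
        raise DataError(f"unknown group_by {group_by!r}")
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(keyfun(r), []).append(apparent_density(r, species))
    out = []
    for label in sorted(groups):
        vals = np.asarray(groups[label])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append(AdSummary(label, len(vals), float(np.mean(vals)), sd))
    return out


# ---------------------------------------------------------------------------
# rank tests


@dataclass
class DunnComparison:
    group_a: int
    group_b: int
    z: float
    p_adjusted: float


@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    dunn: list[DunnComparison] = field(default_factory=list)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[int, int]]:
        return [(d.group_a, d.group_b) for d in self.dunn if d.p_adjusted < alpha]


def _kruskal_h(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Computed from rank arithmetic directly (not delegated) so it can be
    cross-checked against scipy in the test suite.
    """
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        k = len(g)
        rsum = ranks[start : start + k].sum()
        h += rsum * rsum / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie == 0:
        return 0.0, 1.0  # every observation identical
    h /= tie
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def kruskal_dunn(
    groups: list[list[float]] | list[np.ndarray],
    alpha: float = 0.05,
    adjustment: str = "bonferroni",
) -> KruskalDunnResult:
    """Kruskal-Wallis global test plus Dunn's pairwise z-tests.

    Dunn comparisons are run only when the global p-value is below ``alpha``
    and are multiplicity-adjusted (Bonferroni by default, ``"none"`` to
    disable).
    """
    if len(groups) < 2:
        raise DataError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise DataError("empty group")
    h, p = _kruskal_h(arrays)
    result = KruskalDunnResult(h_statistic=h, p_value=p)
    if p >= alpha:
        return result
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    for i, j in combinations(range(len(arrays)), 2):
        se = math.sqrt(base_var * (1 / len(arrays[i]) + 1 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_pair = 2 * stats.norm.sf(abs(z))
        if adjustment == "bonferroni":
            p_pair = min(1.0, p_pair * n_pairs)
        elif adjustment != "none":
            raise DataError(f"unknown adjustment {adjustment!r}")
        result.dunn.append(DunnComparison(i, j, float(z), float(p_pair)))
    return result


def anova_oneway(groups: list[list[float]]) -> tuple[float, float]:
    """Plain one-way ANOVA (F, p); provided as a cross-check only.

    Catch data are rarely normal, so the pipeline's reported comparisons are
    :func:`kruskal_dunn`.
    """
    res = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# CSV round-trip


def write_traps(records: list[TrapRecord], path: str | Path) -> None:
    """Write trap records with one column per observed species."""
    if not records:
        raise DataError("no records to write")
    species = sorted({sp for r in records for sp in r.species_counts})
    cols = TRAP_CSV_COLUMNS + [f"count_{sp}" for sp in species]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"#schema=trap-records-v{TRAP_CSV_SCHEMA_VERSION}"])
        writer.writerow(cols)
        for r in records:
            writer.writerow(
                [
                    r.trap_id,
                    r.site_id,
                    repr(r.x),
                    repr(r.y),
                    r.trap_days,
                    r.vegetation_class,
                    int(r.in_protected),
                    repr(r.distance_to_protected),
                ]
                + [r.species_counts.get(sp, 0) for sp in species]
            )


def read_traps(path: str | Path) -> list[TrapRecord]:
    """Read trap records; malformed rows are rejected with their line number."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        first = next(reader, None)
        if first and first[0].startswith("#schema="):
            header = next(reader, None)
        else:
            header = first
        if header is None:
            raise DataError(f"{path}: empty file")
        missing = [c for c in TRAP_CSV_COLUMNS if c not in header]
        if missing:
            raise DataError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        species_cols = [c for c in header if c.startswith("count_")]
        records = []
        for lineno, row in enumerate(reader, start=3 if first and first[0].startswith("#") else 2):
            if not row:
                continue
            try:
                counts = {c[len("count_") :]: int(row[idx[c]]) for c in species_cols}
                rec = TrapRecord(
                    trap_id=row[idx["trap_id"]],
                    site_id=row[idx["site_id"]],
                    x=float(row[idx["x"]]),
                    y=float(row[idx["y"]]),
                    species_counts=counts,
                    trap_days=int(row[idx["trap_days"]]),
                    vegetation_class=row[idx["vegetation_class"]],
                    in_protected=bool(int(row[idx["in_protected"]])),
                    distance_to_protected=float(row[idx["distance_to_protected"]]),
                )
            except (ValueError, IndexError, DataError) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records
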