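"""Multi-layer environmental covariate stack on a shared grid.

A :class:`CovariateStack` bundles continuous layers (vegetation indices,
temperatures, densities ...), binary layers (protected-area mask) and
categorical layers (vegetation class) on one :class:`~tsetse_sdm.grid.GridSpec`,
with a validity mask for nodata cells.  It persists as a directory of ESRI
ASCII grids plus a ``stack.yml`` sidecar recording layer kinds and the CRS
tag, so everything round-trips from plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import DataError
from .grid import GridSpec, read_ascii_grid, write_ascii_grid

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"
_KINDS = (CONTINUOUS, BINARY, CATEGORICAL)


@dataclass
class CovariateStack:
    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)
    mask: np.ndarray | None = None  # True where the cell is valid

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise DataError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            if self.kinds.get(name) not in _KINDS:
                raise DataError(f"layer {name!r} has unknown kind {self.kinds.get(name)!r}")

    # -- accessors ---------------------------------------------------------
    def names(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.layers)
        return [n for n, k in self.kinds.items() if k == kind]

    @property
    def continuous_names(self) -> list[str]:
        return self.names(CONTINUOUS)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def add(self, name: str, values: np.ndarray, kind: str = CONTINUOUS) -> None:
        values = np.asarray(values)
        if values.shape != self.grid.shape:
            raise DataError(f"layer {name!r} shape {values.shape} != grid {self.grid.shape}")
        if kind not in _KINDS:
            raise DataError(f"unknown layer kind {kind!r}")
        self.layers[name] = values
        self.kinds[name] = kind

    def valid_indices(self) -> np.ndarray:
        """Flat indices (row-major) of valid cells."""
        return np.flatnonzero(self.mask.ravel())

    def table(self, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Valid-cell values as an (n_valid, n_layers) matrix plus names."""
        names = list(self.layers) if names is None else names
        flat = self.mask.ravel()
        cols = [self.layers[n].ravel()[flat].astype(float) for n in names]
        return np.column_stack(cols), names

    def values_at(self, x, y, names: list[str] | None = None) -> np.ndarray:
        """Layer values sampled at point coordinates (n_points, n_layers)."""
        names = list(self.layers) if names is None else names
        row, col = self.grid.cell_of(np.atleast_1d(x), np.atleast_1d(y))
        return np.column_stack([self.layers[n][row, col].astype(float) for n in names])

    # -- persistence -------------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "crs": self.grid.crs,
            "cell": self.grid.cell,
            "layers": {n: self.kinds[n] for n in self.layers},
        }
        (path / "stack.yml").write_text(yaml.safe_dump(meta, sort_keys=False))
        for name, arr in self.layers.items():
            values = arr.astype(float).copy()
            values[~self.mask] = np.nan
            write_ascii_grid(path / f"{name}.asc", self.grid, values)

    @classmethod
    def from_dir(cls, path: str | Path) -> "CovariateStack":
        path = Path(path)
        meta = yaml.safe_load((path / "stack.yml").read_text())
        layers: dict[str, np.ndarray] = {}
        kinds: dict[str, str] = {}
        grid = None
        mask = None
        for name, kind in meta["layers"].items():
            g, values = read_ascii_grid(path / f"{name}.asc", crs=meta.get("crs", "local-metre"))
            if grid is None:
                grid = g
                mask = ~np.isnan(values)
            elif g != grid:
                raise DataError(f"layer {name!r} geometry differs from first layer")
            else:
                mask &= ~np.isnan(values)
            layers[name] = values
            kinds[name] = kind
        if grid is None:
            raise DataError("empty stack directory")
        for name, kind in kinds.items():
            if kind in (BINARY, CATEGORICAL):
                arr = layers[name]
                arr[np.isnan(arr)] = 0
                layers[name] = arr.astype(int)
        return cls(grid=grid, layers=layers, kinds=kinds, mask=mask)
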