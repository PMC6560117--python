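"""Planar analysis grid and the raster containers shared by every stage.

All analyses run on a single equal-area grid in kilometre coordinates.
Rasters are plain ``numpy`` arrays of shape ``(n_rows, n_cols)``; row 0 is
the *southern* edge (y increases with row index), so ``values[r, c]`` sits at
the cell centre returned by :meth:`GridSpec.rc_to_xy`.

Bathymetry is stored as **positive depth in metres** so habitat filters such
as "depth < 400 m" read naturally; oceanographic sources that are
negative-down must be negated at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Two rasters that must share a GridSpec do not."""


@dataclass(frozen=True)
class GridSpec:
    """Planar equal-area grid: origin (km), shape and square cell size (km)."""

    x_min: float
    y_min: float
    n_cols: int
    n_rows: int
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("grid must be at least 2x2")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        """Area of one cell in km^2."""
        return self.cell_size**2

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    def rc_to_xy(self, rows, cols):
        """Cell-centre coordinates (km) for row/col indices."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = self.x_min + (cols + 0.5) * self.cell_size
        y = self.y_min + (rows + 0.5) * self.cell_size
        return x, y

    def xy_to_rc(self, x, y):
        """Row/col indices containing planar points (clipped to the grid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.clip(((x - self.x_min) // self.cell_size).astype(int), 0, self.n_cols - 1)
        rows = np.clip(((y - self.y_min) // self.cell_size).astype(int), 0, self.n_rows - 1)
        return rows, cols

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of all cell-centre coordinates, shape (n_rows, n_cols)."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.rc_to_xy(rows, cols)


def check_same_grid(a: GridSpec, b: GridSpec, what: str = "rasters") -> None:
    if a != b:
        raise GridMismatchError(f"{what} are on different grids: {a} vs {b}")


@dataclass
class LandMask:
    """Boolean land/sea partition of a grid; True marks land."""

    grid: GridSpec
    is_land: np.ndarray

    def __post_init__(self) -> None:
        self.is_land = np.asarray(self.is_land, dtype=bool)
        if self.is_land.shape != self.grid.shape:
            raise GridMismatchError("land mask shape does not match grid")
        if self.is_land.all():
            raise ValueError("mask has no sea cells")
        if not self.is_land.any():
            raise ValueError("mask has no land cells")

    @property
    def is_sea(self) -> np.ndarray:
        return ~self.is_land

    def coastal_sea_cells(self) -> np.ndarray:
        """Boolean raster of sea cells 8-adjacent to at least one land cell."""
        near_land = ndimage.binary_dilation(self.is_land, structure=np.ones((3, 3), bool))
        return near_land & self.is_sea

    def distance_to_land_km(self) -> np.ndarray:
        """Euclidean distance (km) from each cell centre to the nearest land cell."""
        return ndimage.distance_transform_edt(self.is_sea, sampling=self.grid.cell_size)

    def sea_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.is_sea)


@dataclass
class EnvStack:
    """Static (bathymetry, slope) and daily dynamic (sst, sla, u, v, eke) layers.

    Bathymetry is positive depth (m); slope in degrees; sst degC; sla m;
    u, v geostrophic currents m/s; eke = (u^2 + v^2)/2 in m^2/s^2.
    """

    grid: GridSpec
    static: dict[str, np.ndarray]
    dynamic: dict[str, dict[Date, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.static.items():
            if arr.shape != self.grid.shape:
                raise GridMismatchError(f"static layer {name!r} shape mismatch")
        dates = None
        for name, by_date in self.dynamic.items():
            if dates is None:
                dates = set(by_date)
            elif set(by_date) != dates:
                raise GridMismatchError(f"dynamic layer {name!r} has a different date index")
            for d, arr in by_date.items():
                if arr.shape != self.grid.shape:
                    raise GridMismatchError(f"dynamic layer {name!r} @ {d} shape mismatch")

    @property
    def dates(self) -> list[Date]:
        if not self.dynamic:
            return []
        first = next(iter(self.dynamic.values()))
        return sorted(first)

    def static_layer(self, name: str) -> np.ndarray:
        return self.static[name]

    def dynamic_layer(self, name: str, date: Date) -> np.ndarray:
        return self.dynamic[name][date]

    def dynamic_mean(self, name: str, dates: Iterable[Date] | None = None) -> np.ndarray:
        """Time-mean of a dynamic layer over ``dates`` (default: all)."""
        by_date = self.dynamic[name]
        use = sorted(by_date) if dates is None else sorted(set(dates))
        return np.mean([by_date[d] for d in use], axis=0)


@dataclass(frozen=True)
class Colony:
    """A breeding colony on a coastal sea cell."""

    id: str
    species: str
    x: float
    y: float
    population_size: int

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")

    def cell(self, grid: GridSpec) -> tuple[int, int]:
        r, c = grid.xy_to_rc(self.x, self.y)
        return int(r), int(c)


def raster_like(grid: GridSpec, fill: float = 0.0, dtype=float) -> np.ndarray:
    return np.full(grid.shape, fill, dtype=dtype)


def layers_as_mapping(env: EnvStack) -> Mapping[str, np.ndarray]:
    """Static layers plus time-means of dynamic layers, for prediction surfaces."""
    out = dict(env.static)
    for name in env.dynamic:
        out[name] = env.dynamic_mean(name)
    return out
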