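"""File formats: track/colony CSV, ESRI ASCII grid rasters, GeoJSON, model JSON.

Rasters are written as ESRI ASCII grids (plain text, one value per cell),
which every GIS reads; all grids in an analysis must share one
:class:`~cpforage.grids.GridSpec` and reads are validated against it.
Timestamps are ISO-8601 and parsed timezone-aware (UTC).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grids import Colony, GridMismatchError, GridSpec, LandMask
from .habitat_model import FittedGAM, HabitatModel, SmoothTerm
from .space_use import IsoplethSet
from .synthetic_world import Track

TRACK_COLUMNS = [
    "individual_id",
    "species",
    "colony_id",
    "group",
    "timestamp",
    "x_km",
    "y_km",
    "source",
    "quality_class",
    "n_satellites",
]


def write_tracks_csv(tracks: list[Track], path) -> None:
    frames = []
    for t in tracks:
        df = t.fixes.copy()
        df.insert(0, "individual_id", t.individual_id)
        df.insert(1, "species", t.species)
        df.insert(2, "colony_id", t.colony_id)
        df.insert(3, "group", t.group)
        frames.append(df[TRACK_COLUMNS])
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path, dtype={"quality_class": "string"})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    tracks = []
    for (ind, sp, col, grp), sub in df.groupby(
        ["individual_id", "species", "colony_id", "group"], sort=True
    ):
        fixes = sub[["timestamp", "x_km", "y_km", "source", "quality_class", "n_satellites"]]
        fixes = fixes.sort_values("timestamp").reset_index(drop=True)
        tracks.append(Track(str(ind), str(sp), str(col), str(grp), fixes))
    return tracks


def write_colonies_csv(colonies: list[Colony], path) -> None:
    pd.DataFrame(
        [
            {"id": c.id, "species": c.species, "x_km": c.x, "y_km": c.y, "population_size": c.population_size}
            for c in colonies
        ]
    ).to_csv(path, index=False)


def read_colonies_csv(path) -> list[Colony]:
    df = pd.read_csv(path)
    required = ["id", "species", "x_km", "y_km", "population_size"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"colony CSV missing columns: {missing} (population_size is required for null density)")
    return [
        Colony(str(r.id), str(r.species), float(r.x_km), float(r.y_km), int(r.population_size))
        for r in df.itertuples()
    ]


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid; our row 0 is the southern edge, so rows are flipped on write."""
    if values.shape != grid.shape:
        raise GridMismatchError("raster shape does not match grid")
    vals = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_min}\n")
        fh.write(f"yllcorner {grid.y_min}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path, expected_grid: GridSpec | None = None) -> tuple[GridSpec, np.ndarray]:
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridSpec(
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
        cell_size=header["cellsize"],
    )
    values = np.atleast_2d(values)[::-1]
    values = np.where(values == header["nodata_value"], np.nan, values)
    if expected_grid is not None and grid != expected_grid:
        raise GridMismatchError(f"raster {path} grid {grid} != expected {expected_grid}")
    return grid, values


def isopleth_to_geojson(iso: IsoplethSet, path) -> None:
    """Polygonize the isopleth cell set (union of cell squares) to GeoJSON."""
    grid = iso.grid
    rows, cols = np.nonzero(iso.member_cells)
    cells = [
        box(
            grid.x_min + c * grid.cell_size,
            grid.y_min + r * grid.cell_size,
            grid.x_min + (c + 1) * grid.cell_size,
            grid.y_min + (r + 1) * grid.cell_size,
        )
        for r, c in zip(rows, cols)
    ]
    geom = unary_union(cells) if cells else None
    feature = {
        "type": "Feature",
        "properties": {"level": iso.level, "area_km2": iso.area_km2},
        "geometry": mapping(geom) if geom is not None else None,
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def isopleth_cells_csv(iso: IsoplethSet, path) -> None:
    rows, cols = np.nonzero(iso.member_cells)
    pd.DataFrame({"row": rows, "col": cols}).to_csv(path, index=False)


def model_to_json(model: HabitatModel, path) -> None:
    d = {
        "group": model.group,
        "terms": [
            {"covariate": list(t.covariate) if t.is_tensor else t.covariate, "k": t.k}
            for t in model.terms
        ],
        "p_absence": model.p_absence,
        "p_presence": model.p_presence,
        "standardization": {k: list(v) for k, v in model.standardization.items()},
        "cv_metrics": model.cv_metrics,
        "single_covariate_auc": model.single_covariate_auc,
        "gam": model.gam.to_dict() if model.gam is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)


def model_from_json(path) -> HabitatModel:
    with open(path) as fh:
        d = json.load(fh)
    terms = [
        SmoothTerm(tuple(t["covariate"]) if isinstance(t["covariate"], list) else t["covariate"], t["k"])
        for t in d["terms"]
    ]
    gam = FittedGAM.from_dict(d["gam"]) if d.get("gam") else None
    return HabitatModel(
        group=d["group"],
        terms=terms,
        gam=gam,
        p_absence=d["p_absence"],
        p_presence=d["p_presence"],
        standardization={k: tuple(v) for k, v in d["standardization"].items()},
        cv_metrics=d["cv_metrics"],
        single_covariate_auc=d.get("single_covariate_auc", {}),
    )


def write_landmask(mask: LandMask, path) -> None:
    write_ascii_grid(path, mask.grid, mask.is_land.astype(float))


def read_landmask(path, expected_grid: GridSpec | None = None) -> LandMask:
    grid, values = read_ascii_grid(path, expected_grid)
    return LandMask(grid, values > 0.5)
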