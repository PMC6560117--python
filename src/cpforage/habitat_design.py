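"""Case-control dataset construction for habitat-selection modelling.

Observed at-sea locations (cases) are contrasted with pseudo-absences
(controls) sampled uniformly from the water the colony's animals could
actually reach: sea cells within ``accessibility_factor`` (default 1.1) times
the group's maximum trip distance by least-cost at-sea travel. Each presence
contributes ``ratio`` (default 3) temporally matched controls whose dates are
drawn from the presence date pool. Covariates — least-cost distance to the
colony, a null-density competition index N/d^2 summed over the other
colonies, bathymetry, slope, SST, SLA and EKE — are extracted per row,
standardized to z-scores, and screened for collinearity by iterative VIF
elimination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distance import least_cost_distance
from .grids import Colony, EnvStack, GridSpec, LandMask

log = logging.getLogger(__name__)

STATIC_COVARIATES = ["distance", "density", "bathymetry", "slope"]
DYNAMIC_COVARIATES = ["sst", "sla", "eke"]
ALL_COVARIATES = STATIC_COVARIATES + DYNAMIC_COVARIATES


@dataclass
class DistanceRaster:
    """Least-cost at-sea distance (km) from one colony; land/unreachable = inf."""

    grid: GridSpec
    colony_id: str
    values: np.ndarray


@dataclass
class AccessibleRegion:
    """Sea cells within ``radius_used`` least-cost km of the colony."""

    colony_id: str
    cells: np.ndarray  # boolean raster
    radius_used_km: float
    grid: GridSpec


@dataclass
class CaseControlTable:
    """Labelled presence/pseudo-absence rows with raw and standardized covariates."""

    data: pd.DataFrame
    covariates: list[str]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    ratio: int = 3

    @property
    def p_absence(self) -> float:
        return float((self.data["label"] == 0).mean())

    @property
    def p_presence(self) -> float:
        return float((self.data["label"] == 1).mean())


def distance_raster(colony: Colony, mask: LandMask) -> DistanceRaster:
    """Least-cost at-sea distance raster from the colony cell (km)."""
    cell = colony.cell(mask.grid)
    if mask.is_land[cell]:
        raise ValueError(f"colony {colony.id} is on land")
    return DistanceRaster(mask.grid, colony.id, least_cost_distance(mask, cell))


def accessible_region(
    colony: Colony,
    max_trip_distance_km: float,
    mask: LandMask,
    accessibility_factor: float = 1.1,
    dist: DistanceRaster | None = None,
) -> AccessibleRegion:
    """Sea cells reachable within ``accessibility_factor`` x max trip distance."""
    if max_trip_distance_km <= 0:
        raise ValueError("max_trip_distance must be positive")
    if dist is None:
        dist = distance_raster(colony, mask)
    radius = accessibility_factor * max_trip_distance_km
    cells = mask.is_sea & (dist.values <= radius)
    if not cells.any():
        raise ValueError(f"accessible region for colony {colony.id} is empty")
    return AccessibleRegion(colony.id, cells, radius, mask.grid)


def sample_pseudo_absences(
    presences: pd.DataFrame,
    region: AccessibleRegion,
    ratio: int = 3,
    date_pool: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``ratio`` pseudo-absence rows per presence, uniform over the region.

    Positions are uniform over region cells and uniform within the cell;
    dates are drawn uniformly from the presence date pool (temporal matching).
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    if date_pool is None:
        date_pool = presences["date"].to_numpy()
    date_pool = np.asarray(date_pool)
    n = len(presences) * ratio
    rows, cols = np.nonzero(region.cells)
    pick = rng.integers(0, len(rows), size=n)
    grid = region.grid
    x, y = grid.rc_to_xy(rows[pick], cols[pick])
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * grid.cell_size
    dates = date_pool[rng.integers(0, len(date_pool), size=n)]
    return pd.DataFrame(
        {
            "label": 0,
            "x_km": x + jitter[:, 0],
            "y_km": y + jitter[:, 1],
            "date": dates,
            "colony_id": region.colony_id,
        }
    )


def null_density(
    colonies: list[Colony],
    dist_rasters: dict[str, DistanceRaster],
    focal_colony: str,
    min_distance_km: float | None = None,
) -> np.ndarray:
    """Competition raster for a focal colony: sum over other colonies of N/d^2.

    Distance is floored at half a cell size before squaring so the raster
    stays finite at the colony cell while preserving near-colony ordering.
    """
    missing = [c.id for c in colonies if c.id not in dist_rasters]
    if missing:
        raise ValueError(f"missing distance rasters for colonies {missing}")
    others = [c for c in colonies if c.id != focal_colony]
    grid = dist_rasters[colonies[0].id].grid
    if min_distance_km is None:
        min_distance_km = grid.cell_size / 2.0
    out = np.zeros(grid.shape)
    for c in others:
        d = np.maximum(dist_rasters[c.id].values, min_distance_km)
        with np.errstate(over="ignore"):
            out += np.where(np.isfinite(d), c.population_size / d**2, 0.0)
    return out


def single_colony_density(colony: Colony, dist: DistanceRaster, min_distance_km: float | None = None) -> np.ndarray:
    grid = dist.grid
    if min_distance_km is None:
        min_distance_km = grid.cell_size / 2.0
    d = np.maximum(dist.values, min_distance_km)
    return np.where(np.isfinite(d), colony.population_size / d**2, 0.0)


def extract_covariates(
    rows: pd.DataFrame,
    env: EnvStack,
    dist: DistanceRaster,
    competition: np.ndarray,
) -> tuple[pd.DataFrame, int]:
    """Attach static and date-matched dynamic covariates to each row.

    Static layers are read at the row's cell; dynamic layers at the layer
    whose date matches the row's date. Rows with any missing covariate
    (off-grid, land, date outside coverage, non-finite value) are dropped
    and counted, with a warning.
    """
    grid = env.grid
    out = rows.copy().reset_index(drop=True)
    r, c = grid.xy_to_rc(out["x_km"].to_numpy(), out["y_km"].to_numpy())
    out["distance"] = dist.values[r, c]
    out["density"] = competition[r, c]
    out["bathymetry"] = env.static["bathymetry"][r, c]
    out["slope"] = env.static["slope"][r, c]
    dates_avail = set(env.dates)
    for name in DYNAMIC_COVARIATES:
        vals = np.full(len(out), np.nan)
        for d, sub in out.groupby("date").groups.items():
            key = d.date() if isinstance(d, pd.Timestamp) else d
            if key in dates_avail:
                idx = np.asarray(sub)
                layer = env.dynamic[name][key]
                vals[idx] = layer[r[idx], c[idx]]
        out[name] = vals
    ok = np.isfinite(out[ALL_COVARIATES].to_numpy()).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("extract_covariates: dropped %d rows with missing covariates", n_dropped)
    return out[ok].reset_index(drop=True), n_dropped


def standardize(
    table: pd.DataFrame,
    covariates: list[str] = ALL_COVARIATES,
    params: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score covariates: (x - mean) / SD with sample SD (n-1 denominator).

    Standardized values go to ``<name>_std`` columns; the raw columns stay.
    The (mean, sd) pairs are returned for prediction-time reuse; passing
    ``params`` applies a stored transform instead of refitting. Zero-variance
    covariates are excluded with a warning.
    """
    out = table.copy()
    fitted: dict[str, tuple[float, float]] = {}
    for name in covariates:
        if params is not None:
            if name not in params:
                continue
            mu, sd = params[name]
        else:
            mu = float(out[name].mean())
            sd = float(out[name].std(ddof=1))
            if not np.isfinite(sd) or sd <= 0:
                log.warning("standardize: covariate %r has zero variance, excluded", name)
                continue
        fitted[name] = (mu, sd)
        out[name + "_std"] = (out[name] - mu) / sd
    return out, fitted


def vif_screen(
    table: pd.DataFrame,
    covariates: list[str],
    threshold: float = 3.0,
) -> list[str]:
    """Iteratively drop the covariate with the largest VIF until all <= threshold.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression of covariate j on the
    others (with intercept).
    """
    if len(covariates) < 2:
        return list(covariates)
    kept = list(covariates)
    while len(kept) > 1:
        vifs = {}
        X = table[kept].to_numpy().astype(float)
        for j, name in enumerate(kept):
            others = np.delete(X, j, axis=1)
            model = sm.OLS(X[:, j], sm.add_constant(others)).fit()
            r2 = min(model.rsquared, 1.0 - 1e-12)
            vifs[name] = 1.0 / (1.0 - r2)
        worst = max(vifs, key=vifs.get)
        if vifs[worst] <= threshold:
            break
        log.info("vif_screen: dropping %r (VIF=%.2f)", worst, vifs[worst])
        kept.remove(worst)
    return kept


def build_case_control(
    presences: pd.DataFrame,
    colony: Colony,
    max_trip_distance_km: float,
    env: EnvStack,
    mask: LandMask,
    colonies: list[Colony],
    dist_rasters: dict[str, DistanceRaster],
    ratio: int = 3,
    accessibility_factor: float = 1.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Presence + pseudo-absence rows with covariates for one colony (unstandardized)."""
    dist = dist_rasters[colony.id]
    region = accessible_region(colony, max_trip_distance_km, mask, accessibility_factor, dist)
    pres = presences.copy()
    pres["label"] = 1
    pres["colony_id"] = colony.id
    pseudo = sample_pseudo_absences(pres, region, ratio=ratio, seed=seed)
    rows = pd.concat([pres[["label", "x_km", "y_km", "date", "colony_id"]], pseudo], ignore_index=True)
    competition = null_density(colonies, dist_rasters, focal_colony=colony.id)
    table, _ = extract_covariates(rows, env, dist, competition)
    return table
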