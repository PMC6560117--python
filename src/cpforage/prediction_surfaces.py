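"""Probability-of-use surfaces from fitted case-control habitat models.

A fitted logistic case-control model over-represents presences by design
(1 presence : ratio pseudo-absences), so its raw predictions are not
probabilities of use. The correction adds the offset
log[(1 - P_a) P_u / P_a] to the linear predictor before the logistic
transform, where P_a and P_u are the absence and presence proportions of the
training design:

    tau(x) = logistic( log[(1 - P_a) P_u / P_a] + b0 + f1(x1) + ... + fp(xp) )

Surfaces are computed per colony — tracked or not — using that colony's own
distance and competition covariates, restricted to its accessible region,
then aggregated to species maps (cell-wise maximum, or a colony-size-weighted
mean), and finally combined across groups into cumulative and overlap maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Colony, EnvStack, GridSpec, LandMask, check_same_grid
from .habitat_design import DistanceRaster, accessible_region, null_density
from .habitat_model import HabitatModel


@dataclass
class PredictionSurface:
    """Probability-of-use tau per sea cell, zero outside the accessible region."""

    grid: GridSpec
    group: str
    colony_id: str
    tau: np.ndarray

    def __post_init__(self) -> None:
        if self.tau.shape != self.grid.shape:
            raise ValueError("surface shape mismatch")


def case_control_offset(p_absence: float, p_presence: float) -> float:
    """log[(1 - P_a) P_u / P_a], the case-control intercept correction."""
    if not np.isclose(p_absence + p_presence, 1.0):
        raise ValueError("P_a + P_u must equal 1")
    return float(np.log((1.0 - p_absence) * p_presence / p_absence))


def tau_predict(
    model: HabitatModel,
    covariate_rasters: dict[str, np.ndarray],
    mask: LandMask,
    p_absence: float | None = None,
    p_presence: float | None = None,
    group: str | None = None,
    colony_id: str = "all-colonies",
) -> PredictionSurface:
    """Evaluate the corrected probability-of-use equation on covariate rasters.

    ``covariate_rasters`` hold *raw* covariate values; they are standardized
    here with the model's stored parameters (a model without stored
    parameters is an error — predicting through an unstandardized model
    silently misplaces every smooth).
    """
    if not model.standardization:
        raise ValueError("model has no stored standardization parameters")
    p_a = model.p_absence if p_absence is None else p_absence
    p_u = model.p_presence if p_presence is None else p_presence
    offset = case_control_offset(p_a, p_u)
    grid = mask.grid
    sea = mask.is_sea
    data = {}
    for term in model.terms:
        names = term.covariate if term.is_tensor else (term.covariate,)
        for name in names:
            mu, sd = model.standardization[name]
            data[name] = (covariate_rasters[name][sea] - mu) / sd
    if model.gam is None or not model.terms:
        eta = np.zeros(int(sea.sum()))
    else:
        eta = model.gam.predict_eta(data)
    tau = np.zeros(grid.shape)
    tau[sea] = 1.0 / (1.0 + np.exp(-(offset + eta)))
    return PredictionSurface(grid, group or model.group, colony_id, tau)


def colony_surfaces(
    model: HabitatModel,
    colonies: list[Colony],
    env: EnvStack,
    mask: LandMask,
    dist_rasters: dict[str, DistanceRaster],
    max_trip_distance_km: float,
    accessibility_factor: float = 1.1,
    date_window=None,
) -> dict[str, PredictionSurface]:
    """One tau surface per colony (tracked or untracked).

    Each colony gets its own distance and competition covariates; dynamic
    covariates are averaged over the tracked date window; cells beyond the
    colony's accessible region are set to zero.
    """
    if not colonies:
        raise ValueError("colony registry is empty")
    static = dict(env.static)
    dyn_means = {name: env.dynamic_mean(name, date_window) for name in env.dynamic}
    out: dict[str, PredictionSurface] = {}
    for colony in colonies:
        dist = dist_rasters[colony.id]
        check_same_grid(dist.grid, mask.grid, "distance raster and mask")
        rasters = dict(static)
        rasters.update(dyn_means)
        rasters["distance"] = np.where(np.isfinite(dist.values), dist.values, 0.0)
        rasters["density"] = null_density(colonies, dist_rasters, focal_colony=colony.id)
        surf = tau_predict(model, rasters, mask, colony_id=colony.id)
        region = accessible_region(colony, max_trip_distance_km, mask, accessibility_factor, dist)
        surf.tau = np.where(region.cells, surf.tau, 0.0)
        out[colony.id] = surf
    return out


def species_surface(
    surfaces: list[PredictionSurface],
    weights: list[float] | None = None,
    group: str | None = None,
) -> PredictionSurface:
    """Aggregate per-colony surfaces: cell-wise max, or weighted mean by colony size."""
    if not surfaces:
        raise ValueError("no surfaces to aggregate")
    grid = surfaces[0].grid
    for s in surfaces[1:]:
        check_same_grid(grid, s.grid, "prediction surfaces")
    stack = np.stack([s.tau for s in surfaces])
    if weights is None:
        tau = stack.max(axis=0)
    else:
        if len(weights) != len(surfaces):
            raise ValueError("weight vector length mismatch")
        w = np.asarray(weights, dtype=float)
        tau = np.tensordot(w / w.sum(), stack, axes=1)
    return PredictionSurface(grid, group or surfaces[0].group, "all-colonies", tau)


def _standardize_surface(tau: np.ndarray) -> np.ndarray | None:
    peak = tau.max()
    if peak <= 0:
        return None
    return tau / peak


def cumulative_surface(group_surfaces: list[PredictionSurface]) -> np.ndarray:
    """Sum of divide-by-maximum standardized group surfaces (each peaks at 1)."""
    if not group_surfaces:
        raise ValueError("no group surfaces")
    grid = group_surfaces[0].grid
    out = np.zeros(grid.shape)
    for s in group_surfaces:
        check_same_grid(grid, s.grid, "group surfaces")
        std = _standardize_surface(s.tau)
        if std is None:
            import logging

            logging.getLogger(__name__).warning("cumulative_surface: all-zero surface excluded (%s)", s.group)
            continue
        out += std
    return out


def overlap_surface(
    group_surfaces: list[PredictionSurface],
    presence_threshold: float = 0.5,
) -> np.ndarray:
    """Count per cell of groups whose standardized tau reaches ``presence_threshold``."""
    if not 0 < presence_threshold < 1:
        raise ValueError("presence_threshold must be in (0, 1)")
    grid = group_surfaces[0].grid
    count = np.zeros(grid.shape, dtype=int)
    for s in group_surfaces:
        check_same_grid(grid, s.grid, "group surfaces")
        std = _standardize_surface(s.tau)
        if std is None:
            continue
        count += (std >= presence_threshold).astype(int)
    return count
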