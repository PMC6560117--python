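"""Seeded synthetic archipelago, environment and central-place foraging tracks.

The generator produces the statistical structure the downstream analysis
assumes rather than realistic oceanography: an island coastline on a planar
equal-area grid, bathymetry deepening offshore, smooth slowly-varying dynamic
fields (SST, SLA, geostrophic currents), colonies of varying population size
on coastal cells, and multi-trip central-place tracks whose step selection is
biased by a *known* habitat preference (distance decay from the colony plus a
tabulated bathymetry response).  Observed fixes degrade the true path with
isotropic Gaussian positional error and per-fix dropout, and carry the source
tags (argos / gps / fastloc, with satellite counts) the cleaning stage needs.

Because the preference that generated the data is known, parameter-recovery
tests can compare fitted habitat responses against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy import ndimage

from .distance import least_cost_distance
from .grids import Colony, EnvStack, GridMismatchError, GridSpec, LandMask, check_same_grid

ARGOS_CLASSES = ["3", "2", "1", "0", "A", "B"]


@dataclass
class TruthPreference:
    """Known habitat preference used to bias simulated movement.

    The linear predictor at a sea cell is

        eta = distance_coef * d_colony_km + bathy_response(depth_m)

    with per-step Gaussian selection noise of standard deviation ``noise_sd``.
    ``distance_coef`` must be negative: use must decline with distance from
    the colony for a central-place forager.
    """

    distance_coef: float
    bathy_depths_m: np.ndarray
    bathy_values: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.distance_coef >= 0:
            raise ValueError("distance_coef must be negative")
        self.bathy_depths_m = np.asarray(self.bathy_depths_m, dtype=float)
        self.bathy_values = np.asarray(self.bathy_values, dtype=float)
        if self.bathy_depths_m.shape != self.bathy_values.shape:
            raise ValueError("bathymetry response table lengths differ")

    def bathy_response(self, depth_m) -> np.ndarray:
        return np.interp(np.asarray(depth_m, dtype=float), self.bathy_depths_m, self.bathy_values)

    @classmethod
    def unimodal(
        cls,
        distance_coef: float = -0.03,
        peak_depth_m: float = 150.0,
        width_m: float = 120.0,
        amplitude: float = 2.0,
        noise_sd: float = 0.5,
    ) -> "TruthPreference":
        """Distance decay plus a Gaussian-bump depth preference around a shelf depth."""
        depths = np.linspace(0.0, 2000.0, 201)
        values = amplitude * np.exp(-0.5 * ((depths - peak_depth_m) / width_m) ** 2)
        return cls(distance_coef, depths, values, noise_sd)


@dataclass
class Track:
    """Fixes for one tagged individual, with generator ground truth attached."""

    individual_id: str
    species: str
    colony_id: str
    group: str
    fixes: pd.DataFrame
    n_true_trips: int = 0
    true_fixes: pd.DataFrame | None = field(default=None, repr=False)


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def eke_from_currents(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Eddy kinetic energy (m^2/s^2) from geostrophic current components.

    EKE = (u^2 + v^2) / 2, cell-wise.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise GridMismatchError(f"u and v grids differ: {u.shape} vs {v.shape}")
    return 0.5 * (u**2 + v**2)


def make_world(
    grid: GridSpec,
    n_islands: int,
    seed: int,
    *,
    n_days: int = 30,
    start_date: Date = Date(2016, 1, 1),
) -> tuple[LandMask, EnvStack]:
    """Generate an island land mask and a conforming environmental stack.

    Bathymetry (positive depth, m) deepens with distance from land; slope
    (degrees) comes from finite differences of depth; SST, SLA and currents
    are smooth AR(1)-in-time random fields over ``n_days`` daily steps, and
    EKE is computed from the current components.
    """
    if n_islands < 1:
        raise ValueError("n_islands must be >= 1")
    n_cells = grid.n_rows * grid.n_cols
    if n_islands * 64 > n_cells // 2:
        raise ValueError(f"grid {grid.n_rows}x{grid.n_cols} too small to host {n_islands} islands")

    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    bump = np.zeros(grid.shape)
    span_r, span_c = grid.n_rows, grid.n_cols
    for _ in range(n_islands):
        cr = rng.uniform(0.2 * span_r, 0.8 * span_r)
        cc = rng.uniform(0.2 * span_c, 0.8 * span_c)
        ar = rng.uniform(0.04, 0.10) * span_r
        ac = rng.uniform(0.04, 0.10) * span_c
        theta = rng.uniform(0, np.pi)
        dr = (rows - cr) * np.cos(theta) + (cols - cc) * np.sin(theta)
        dc = -(rows - cr) * np.sin(theta) + (cols - cc) * np.cos(theta)
        bump = np.maximum(bump, np.exp(-0.5 * ((dr / ar) ** 2 + (dc / ac) ** 2)))
    # ragged coastline
    bump *= 1.0 + 0.15 * _smooth_field(rng, grid.shape, sigma_cells=max(2, span_r // 30))
    is_land = bump > 0.55
    if not is_land.any() or is_land.all():
        raise ValueError("degenerate world: adjust grid size or n_islands")
    mask = LandMask(grid, is_land)

    dist_km = mask.distance_to_land_km()
    noise = 4.0 * _smooth_field(rng, grid.shape, sigma_cells=max(2, span_r // 25))
    depth = np.where(mask.is_sea, 15.0 + 9.0 * dist_km + 0.9 * dist_km**1.5 + noise, 0.0)
    depth = np.clip(depth, 0.0, None)
    depth[mask.is_land] = 0.0

    gy, gx = np.gradient(depth, grid.cell_size * 1000.0)  # m per m
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope[mask.is_land] = 0.0

    dates = [start_date + timedelta(days=i) for i in range(n_days)]
    yfrac = (rows - 0) / max(span_r - 1, 1)
    sst_base = 5.0 + 5.0 * yfrac  # warmer toward the high-y (northern) edge
    rho = 0.9
    sigma = max(3, span_r // 15)
    dyn: dict[str, dict[Date, np.ndarray]] = {k: {} for k in ("sst", "sla", "u", "v", "eke")}
    f_sst = _smooth_field(rng, grid.shape, sigma)
    f_sla = _smooth_field(rng, grid.shape, sigma)
    f_u = _smooth_field(rng, grid.shape, sigma)
    f_v = _smooth_field(rng, grid.shape, sigma)
    for i, d in enumerate(dates):
        if i:
            w = np.sqrt(1 - rho**2)
            f_sst = rho * f_sst + w * _smooth_field(rng, grid.shape, sigma)
            f_sla = rho * f_sla + w * _smooth_field(rng, grid.shape, sigma)
            f_u = rho * f_u + w * _smooth_field(rng, grid.shape, sigma)
            f_v = rho * f_v + w * _smooth_field(rng, grid.shape, sigma)
        u = 0.10 + 0.15 * f_u
        v = 0.05 + 0.15 * f_v
        dyn["sst"][d] = sst_base + 1.5 * f_sst
        dyn["sla"][d] = 0.12 * f_sla
        dyn["u"][d] = u
        dyn["v"][d] = v
        dyn["eke"][d] = eke_from_currents(u, v)

    env = EnvStack(grid, static={"bathymetry": depth, "slope": slope}, dynamic=dyn)
    return mask, env


def place_colonies(
    mask: LandMask,
    n: int,
    size_range: tuple[int, int],
    seed: int,
    *,
    species: str = "synthetic_predator",
) -> list[Colony]:
    """Place ``n`` colonies on distinct coastal sea cells with sizes in ``size_range``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    coastal = np.argwhere(mask.coastal_sea_cells())
    if len(coastal) < n:
        raise ValueError(f"only {len(coastal)} coastal sea cells for {n} colonies")
    rng = np.random.default_rng(seed)
    # spread colonies: greedy farthest-point pick from a shuffled pool
    pool = coastal[rng.permutation(len(coastal))]
    chosen = [pool[0]]
    for cand in pool[1:]:
        if len(chosen) == n:
            break
        d = min(np.hypot(*(cand - c)) for c in chosen)
        if d >= max(2.0, np.sqrt(mask.is_sea.sum()) / (2 * n)):
            chosen.append(cand)
    i = 0
    while len(chosen) < n:  # fall back to any remaining distinct cells
        cand = pool[i]
        if not any((cand == c).all() for c in chosen):
            chosen.append(cand)
        i += 1
    lo, hi = size_range
    out = []
    for k, (r, c) in enumerate(chosen):
        x, y = mask.grid.rc_to_xy(r, c)
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        out.append(Colony(id=f"C{k:02d}", species=species, x=float(x), y=float(y), population_size=size))
    return out


def _neighbours(r: int, c: int, shape) -> list[tuple[int, int]]:
    nr, nc = shape
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc:
                out.append((rr, cc))
    return out


def simulate_tracks(
    colonies: list[Colony],
    env: EnvStack,
    mask: LandMask,
    truth: TruthPreference,
    n_individuals: int,
    trips_per_individual: int,
    error_model: dict,
    seed: int,
    *,
    step_hours: float = 1.0,
    outbound_steps: tuple[int, int] = (8, 30),
    sources: tuple[str, ...] = ("argos", "gps", "fastloc"),
    species: str | None = None,
    group: str = "synthetic",
) -> list[Track]:
    """Simulate habitat-biased central-place foraging tracks.

    Movement is a discrete-time biased random walk over sea cells: each step
    moves to an 8-neighbour sea cell with probability proportional to
    exp(eta_truth + noise); after a random outbound phase the walker follows
    the least-cost distance gradient home, so every trip starts and ends on
    its colony cell.  Observed fixes add isotropic Gaussian error (km) and
    per-fix dropout per ``error_model``:

        {"argos_sd": km, "gap_prob": fraction, "fastloc_sat_range": (lo, hi)}

    gps fixes are error-free; fastloc error is one tenth of argos.
    """
    check_same_grid(env.grid, mask.grid, "environment and mask")
    rng = np.random.default_rng(seed)
    argos_sd = float(error_model.get("argos_sd", 0.0))
    gap_prob = float(error_model.get("gap_prob", 0.0))
    sat_lo, sat_hi = error_model.get("fastloc_sat_range", (4, 12))
    depth = env.static["bathymetry"]
    dates = env.dates
    grid = mask.grid

    # per-colony selection field eta (least-cost distance keeps walkers off land)
    eta_by_colony: dict[str, np.ndarray] = {}
    dist_by_colony: dict[str, np.ndarray] = {}
    for col in colonies:
        if not bool(grid.contains(col.x, col.y)):
            raise ValueError(f"colony {col.id} outside the grid")
        cell = col.cell(grid)
        if mask.is_land[cell]:
            raise ValueError(f"colony {col.id} cell is on land")
        d = least_cost_distance(mask, cell)
        dist_by_colony[col.id] = d
        eta = truth.distance_coef * np.where(np.isfinite(d), d, 1e6) + truth.bathy_response(depth)
        eta_by_colony[col.id] = eta

    tracks: list[Track] = []
    sd_by_source = {"argos": argos_sd, "gps": 0.0, "fastloc": 0.1 * argos_sd}
    for i in range(n_individuals):
        col = colonies[i % len(colonies)]
        source = sources[i % len(sources)]
        eta = eta_by_colony[col.id]
        dist = dist_by_colony[col.id]
        home = col.cell(grid)
        t0 = datetime.combine(dates[0] if dates else Date(2016, 1, 1), datetime.min.time(), timezone.utc)
        t0 = t0 + timedelta(hours=float(rng.integers(0, 12)))
        rows_true: list[tuple[datetime, float, float]] = []
        t = t0
        for _trip in range(trips_per_individual):
            cell = home
            path = [cell]
            n_out = int(rng.integers(outbound_steps[0], outbound_steps[1] + 1))
            # outbound avoids re-entering the near-colony zone so trips stay distinct
            near_colony = 3.0 * grid.cell_size
            for step in range(n_out):
                cands = [p for p in _neighbours(*cell, grid.shape) if mask.is_sea[p]]
                if dist[cell] <= near_colony:
                    away = [p for p in cands if dist[p] > dist[cell]]  # force the departure
                else:
                    away = [p for p in cands if dist[p] > near_colony]
                if away:
                    cands = away
                if not cands:
                    break
                w = np.array([eta[p] for p in cands])
                if truth.noise_sd > 0:
                    w = w + truth.noise_sd * rng.standard_normal(len(cands))
                w = np.exp(w - w.max())
                cell = cands[int(rng.choice(len(cands), p=w / w.sum()))]
                path.append(cell)
            while cell != home:  # inbound: descend the least-cost distance field
                cands = [p for p in _neighbours(*cell, grid.shape) if mask.is_sea[p] and dist[p] < dist[cell]]
                if not cands:
                    break
                cell = min(cands, key=lambda p: dist[p])
                path.append(cell)
            for p in path:
                x, y = grid.rc_to_xy(*p)
                rows_true.append((t, float(x), float(y)))
                t += timedelta(hours=step_hours)
            t += timedelta(hours=float(rng.integers(2, 8)))  # haul-out between trips

        true_df = pd.DataFrame(rows_true, columns=["timestamp", "x_km", "y_km"])
        n_fix = len(true_df)
        err = rng.normal(0.0, sd_by_source[source] or 0.0, size=(n_fix, 2)) if sd_by_source[source] > 0 else np.zeros((n_fix, 2))
        obs = true_df.copy()
        obs["x_km"] = obs["x_km"] + err[:, 0]
        obs["y_km"] = obs["y_km"] + err[:, 1]
        obs["source"] = source
        obs["quality_class"] = (
            rng.choice(ARGOS_CLASSES, size=n_fix) if source == "argos" else None
        )
        obs["n_satellites"] = (
            rng.integers(sat_lo, sat_hi + 1, size=n_fix) if source == "fastloc" else np.nan
        )
        if gap_prob > 0:
            keep = rng.random(n_fix) >= gap_prob
            obs = obs[keep].reset_index(drop=True)
        tracks.append(
            Track(
                individual_id=f"ind{i:03d}",
                species=species or col.species,
                colony_id=col.id,
                group=group,
                fixes=obs.reset_index(drop=True),
                n_true_trips=trips_per_individual,
                true_fixes=true_df,
            )
        )
    return tracks
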