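"""Utilization distributions, first-passage-time bandwidth and core areas.

The kernel bandwidth h is not a free knob: it is set to the mean
area-restricted-search (ARS) scale, the radius at which the variance of
log first-passage time across trip positions peaks, averaged over a group's
foraging trips.  Kernel UDs are masked to sea cells and normalized to unit
mass; core areas are the minimal highest-density cell sets holding 50% of
that mass; representativeness measures how close the observed core area is
to the asymptote of a trip-subsampling saturation curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .grids import GridSpec, GridMismatchError, LandMask, check_same_grid
from .track_processing import Trip

DEFAULT_FPT_RADII_KM = np.concatenate([np.arange(1.0, 30.0, 2.0), np.arange(30.0, 151.0, 10.0)])


class SingleIndividualColonyError(ValueError):
    """Colony tracked for a single individual: excluded from colony UDs."""


class NoARSScaleError(ValueError):
    """No trip shows an interior var(log FPT) maximum; fall back to a fixed h."""


@dataclass
class UD:
    """Utilization distribution: nonnegative density on sea cells, unit mass."""

    grid: GridSpec
    density: np.ndarray
    h_km: float
    n_individuals: int = 1
    n_trips: int = 0

    def __post_init__(self) -> None:
        if self.density.shape != self.grid.shape:
            raise GridMismatchError("UD density shape mismatch")
        total = self.density.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"UD mass {total} != 1")


@dataclass
class IsoplethSet:
    """Smallest highest-density cell set whose cumulative mass reaches ``level``."""

    level: float
    member_cells: np.ndarray  # boolean raster
    area_km2: float
    grid: GridSpec


@dataclass
class RepresentativenessResult:
    curve: pd.DataFrame  # n_trips, mean_area, ci_lo, ci_hi
    asymptote_area_km2: float | None
    observed_area_km2: float
    value_percent: float | None

    @property
    def representative(self) -> bool | None:
        if self.value_percent is None:
            return None
        return self.value_percent >= 75.0


def first_passage_time(trip: Trip, radius_km: float) -> np.ndarray:
    """First passage time (hours) through a circle of ``radius_km`` at each position.

    For every position the forward time to first leave the circle centred
    there and the backward time since last entering it are summed; crossing
    instants are linearly interpolated between the bracketing positions.
    Positions whose circle is never exited in a direction are NaN (undefined),
    never zero.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    pos = trip.positions
    t = (pos["timestamp"] - pos["timestamp"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    x = pos["x_km"].to_numpy().astype(float)
    y = pos["y_km"].to_numpy().astype(float)
    n = len(x)
    out = np.full(n, np.nan)
    for i in range(n):
        d = np.hypot(x - x[i], y - y[i])
        fwd = np.nan
        for j in range(i + 1, n):
            if d[j] > radius_km:
                frac = (radius_km - d[j - 1]) / (d[j] - d[j - 1])
                fwd = t[j - 1] + frac * (t[j] - t[j - 1]) - t[i]
                break
        bwd = np.nan
        for j in range(i - 1, -1, -1):
            if d[j] > radius_km:
                frac = (radius_km - d[j + 1]) / (d[j] - d[j + 1])
                bwd = t[i] - (t[j + 1] + frac * (t[j] - t[j + 1]))
                break
        out[i] = fwd + bwd  # NaN if either side never crosses
    return out


def ars_scale(
    trips: list[Trip],
    radii_km: np.ndarray = DEFAULT_FPT_RADII_KM,
) -> tuple[float, pd.DataFrame]:
    """Mean ARS scale (km) across trips: per trip, the radius maximizing var(log FPT).

    Trips whose variance profile has no interior maximum (e.g. straight-line
    transits) are excluded and counted. Raises :class:`NoARSScaleError` when
    no trip yields a scale, directing the caller to a fallback bandwidth.
    """
    radii_km = np.asarray(radii_km, dtype=float)
    rows = []
    for trip in trips:
        var_log = np.full(len(radii_km), np.nan)
        for k, r in enumerate(radii_km):
            fpt = first_passage_time(trip, r)
            ok = np.isfinite(fpt) & (fpt > 0)
            if ok.sum() >= 2:
                var_log[k] = np.var(np.log(fpt[ok]))
        finite = np.isfinite(var_log)
        scale = np.nan
        if finite.sum() >= 3:
            vals = var_log[finite]
            rads = radii_km[finite]
            k = int(np.nanargmax(vals))
            if 0 < k < len(vals) - 1:  # interior maximum only
                scale = rads[k]
        rows.append({"trip_id": trip.trip_id, "ars_scale_km": scale})
    table = pd.DataFrame(rows)
    scales = table["ars_scale_km"].dropna()
    if scales.empty:
        raise NoARSScaleError("no trip produced an interior var(log FPT) maximum")
    return float(scales.mean()), table


def kernel_ud(
    positions: pd.DataFrame,
    h_km: float,
    mask: LandMask,
    n_individuals: int = 1,
    n_trips: int = 0,
) -> UD:
    """Gaussian kernel UD of positions on the analysis grid, masked to sea.

    Positions are binned to cells and convolved with an isotropic Gaussian of
    standard deviation ``h_km`` (truncated at 5h); land cells are zeroed and
    the density renormalized to unit mass.
    """
    if h_km <= 0:
        raise ValueError("h must be positive")
    if len(positions) == 0:
        raise ValueError("no positions")
    field = _smoothed_counts(positions, h_km, mask.grid)
    field[mask.is_land] = 0.0
    total = field.sum()
    if total <= 0:
        raise ValueError("all kernel mass fell on land")
    return UD(mask.grid, field / total, h_km, n_individuals=n_individuals, n_trips=n_trips)


def _smoothed_counts(positions: pd.DataFrame, h_km: float, grid: GridSpec) -> np.ndarray:
    r, c = grid.xy_to_rc(positions["x_km"].to_numpy(), positions["y_km"].to_numpy())
    counts = np.zeros(grid.shape)
    np.add.at(counts, (r, c), 1.0)
    sigma_cells = h_km / grid.cell_size
    return ndimage.gaussian_filter(counts, sigma_cells, truncate=5.0, mode="constant")


def colony_ud(individual_uds: list[UD]) -> UD:
    """Cell-wise mean of individual UDs for one colony, renormalized.

    Colonies with a single tracked individual are excluded from colony-level
    estimates; passing fewer than two UDs raises
    :class:`SingleIndividualColonyError`.
    """
    if len(individual_uds) < 2:
        raise SingleIndividualColonyError("colony UD needs >= 2 tracked individuals")
    grid = individual_uds[0].grid
    for ud in individual_uds[1:]:
        check_same_grid(grid, ud.grid, "individual UDs")
    dens = np.mean([ud.density for ud in individual_uds], axis=0)
    dens = dens / dens.sum()
    return UD(
        grid,
        dens,
        h_km=float(np.mean([ud.h_km for ud in individual_uds])),
        n_individuals=sum(ud.n_individuals for ud in individual_uds),
        n_trips=sum(ud.n_trips for ud in individual_uds),
    )


def isopleth(ud: UD, level: float = 0.5) -> IsoplethSet:
    """Minimal highest-density cell set enclosing ``level`` of the UD mass.

    Cells are ranked by density descending and the shortest prefix with
    cumulative mass >= level is taken; cells tied with the cut density are all
    included (so a uniform UD returns every nonzero cell).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12))  # first index reaching level
    cut = flat[order[k]]
    member = ud.density >= cut if cut > 0 else ud.density > 0
    area = float(member.sum()) * ud.grid.cell_area
    return IsoplethSet(level=level, member_cells=member, area_km2=area, grid=ud.grid)


def merge_isopleths(sets: list[IsoplethSet]) -> np.ndarray:
    """Integer raster counting how many isopleth sets contain each cell."""
    if not sets:
        raise ValueError("no isopleth sets")
    grid = sets[0].grid
    for s in sets[1:]:
        check_same_grid(grid, s.grid, "isopleth sets")
    return np.sum([s.member_cells.astype(int) for s in sets], axis=0)


def _area_saturation(n, a_inf, c):
    return a_inf * (1.0 - np.exp(-np.asarray(n, dtype=float) / c))


def representativeness(
    trips: list[Trip],
    mask: LandMask,
    h_km: float,
    n_iter: int = 500,
    seed: int = 0,
    level: float = 0.5,
) -> RepresentativenessResult:
    """Trip-subsampling saturation analysis of core-area size.

    The subsampling is an accumulation curve over ``n_iter`` random
    permutations of the trips: for each permutation the core-area (``level``
    isopleth) size of the first n trips is computed for n = 1..N, and the
    curve reports the mean and 2.5/97.5 percentile bounds per n (nested
    subsets share sampling noise across n, as in standard accumulation-curve
    practice). The curve is fitted with the negative-exponential saturating
    form A(n) = A_inf (1 - exp(-n/c)) and the representative value is
    100 x A(N) / A_inf, flagged representative at >= 75%.
    """
    n_total = len(trips)
    if n_total < 3:
        raise ValueError("representativeness needs >= 3 trips")
    rng = np.random.default_rng(seed)
    grid = mask.grid
    # Smoothing is linear, so per-trip smoothed fields let any subset's UD be a sum.
    fields = np.stack(
        [_smoothed_counts(t.positions, h_km, grid) for t in trips]
    ).reshape(n_total, -1)
    fields[:, mask.is_land.ravel()] = 0.0
    cell_area = grid.cell_area

    def nested_areas(order: np.ndarray) -> np.ndarray:
        dens = np.cumsum(fields[order], axis=0)  # row n-1: UD of the first n trips
        dens = dens / dens.sum(axis=1, keepdims=True)
        srt = np.sort(dens, axis=1)[:, ::-1]
        csum = np.cumsum(srt, axis=1)
        ks = (csum < level - 1e-12).sum(axis=1)
        counts = np.empty(n_total)
        for i, k in enumerate(ks):
            cut = srt[i, k]
            counts[i] = (dens[i] >= cut).sum() if cut > 0 else (dens[i] > 0).sum()
        return counts * cell_area

    areas = np.stack([nested_areas(rng.permutation(n_total)) for _ in range(n_iter)])
    curve = pd.DataFrame(
        {
            "n_trips": np.arange(1, n_total + 1),
            "mean_area": areas.mean(axis=0),
            "ci_lo": np.percentile(areas, 2.5, axis=0),
            "ci_hi": np.percentile(areas, 97.5, axis=0),
        }
    )
    observed = float(curve["mean_area"].iloc[-1])
    if np.allclose(curve["mean_area"], observed, rtol=0, atol=1e-9):
        # saturated from n=1 (e.g. identical trips): asymptote is the observed area
        return RepresentativenessResult(
            curve=curve, asymptote_area_km2=observed, observed_area_km2=observed, value_percent=100.0
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _area_saturation,
                curve["n_trips"],
                curve["mean_area"],
                p0=(curve["mean_area"].max(), n_total / 3.0),
                maxfev=10000,
            )
        a_inf = float(popt[0])
        value = 100.0 * observed / a_inf if a_inf > 0 else None
    except RuntimeError:
        a_inf, value = None, None
    return RepresentativenessResult(
        curve=curve, asymptote_area_km2=a_inf, observed_area_km2=observed, value_percent=value
    )
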