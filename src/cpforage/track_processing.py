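"""Cleaning, trip delineation and hourly regularization of tracking fixes.

The pre-processing chain mirrors standard biotelemetry practice for
central-place foragers: drop low-quality Fastloc GPS fixes (< 4 satellites),
speed-filter implausible locations (3 m/s for swimmers, 20 m/s for flying
seabirds), split tracks into foraging trips by distance to the colony, split
gap-prone trips where the animal could have returned to land unseen, and
regularize each trip to an hourly time grid either linearly or with a
continuous-time correlated random walk (CTCRW) state-space smoother.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .grids import Colony, LandMask

KMH_PER_MS = 3.6  # 1 m/s = 3.6 km/h


class UnusableTrackError(ValueError):
    """Cleaning removed every fix; the track cannot be analysed."""


@dataclass
class Trip:
    """At-sea segment of a track between colony departure and return."""

    trip_id: str
    individual_id: str
    species: str
    colony_id: str
    group: str
    fixes: pd.DataFrame
    regular: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]

    @property
    def positions(self) -> pd.DataFrame:
        """Regularized positions when available, raw fixes otherwise."""
        return self.regular if self.regular is not None else self.fixes


def filter_fastloc(fixes: pd.DataFrame, min_satellites: int = 4) -> pd.DataFrame:
    """Drop fastloc fixes with fewer than ``min_satellites`` satellites.

    Non-fastloc fixes pass through untouched. A fastloc fix without a
    satellite count is an error, never silently kept.
    """
    is_fl = fixes["source"] == "fastloc"
    if is_fl.any():
        nsat = fixes.loc[is_fl, "n_satellites"]
        if nsat.isna().any():
            raise ValueError("fastloc fixes missing n_satellites")
        keep = ~is_fl | (fixes["n_satellites"] >= min_satellites)
        return fixes[keep].reset_index(drop=True)
    return fixes.copy()


def implied_speeds_kmh(fixes: pd.DataFrame) -> np.ndarray:
    """Speed (km/h) implied by each consecutive fix pair."""
    dt_h = fixes["timestamp"].diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    dx = np.diff(fixes["x_km"].to_numpy())
    dy = np.diff(fixes["y_km"].to_numpy())
    dist = np.hypot(dx, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt_h > 0, dist / dt_h, np.inf)


def speed_filter(fixes: pd.DataFrame, vmax_ms: float) -> pd.DataFrame:
    """Iteratively remove fixes implying speeds above ``vmax_ms``.

    At each pass the pair with the largest implied speed is found and the
    member fix whose removal better reduces local speed violations is
    deleted; ties keep the earlier fix. Deterministic and idempotent.
    """
    if vmax_ms <= 0:
        raise ValueError("vmax must be positive")
    if len(fixes) < 2:
        return fixes.copy()
    vmax_kmh = vmax_ms * KMH_PER_MS
    t = fixes["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
    x = fixes["x_km"].to_numpy().astype(float)
    y = fixes["y_km"].to_numpy().astype(float)
    idx = list(range(len(fixes)))

    def seg_speed(i: int, j: int) -> float:
        dt = t[j] - t[i]
        d = np.hypot(x[j] - x[i], y[j] - y[i])
        return d / dt if dt > 0 else np.inf

    def local_max(ids: list[int], around: int) -> float:
        """Max speed of segments touching position ``around`` after a removal."""
        out = 0.0
        for k in range(max(0, around - 1), min(len(ids) - 1, around + 1)):
            out = max(out, seg_speed(ids[k], ids[k + 1]))
        return out

    while len(idx) >= 2:
        speeds = [seg_speed(idx[k], idx[k + 1]) for k in range(len(idx) - 1)]
        worst = int(np.argmax(speeds))
        if speeds[worst] <= vmax_kmh:
            break
        without_first = idx[:worst] + idx[worst + 1 :]
        without_second = idx[: worst + 1] + idx[worst + 2 :]
        m1 = local_max(without_first, worst)  # removed the earlier fix
        m2 = local_max(without_second, worst)  # removed the later fix
        idx = without_second if m2 <= m1 else without_first
    if not idx:
        raise UnusableTrackError("speed filter removed every fix")
    return fixes.iloc[idx].reset_index(drop=True)


def delineate_trips(
    track,
    mask: LandMask,
    colony: Colony,
    return_radius_km: float = 2.0,
    min_trip_fixes: int = 3,
) -> list[Trip]:
    """Split a cleaned track into foraging trips by distance to the colony.

    Fixes within ``return_radius_km`` of the colony, or on land, bound the
    trips; a trip keeps its bounding at-colony fixes and needs at least
    ``min_trip_fixes`` at-sea fixes. A track that never leaves the radius
    yields zero trips.
    """
    fixes = track.fixes
    if len(fixes) == 0:
        return []
    d = np.hypot(fixes["x_km"] - colony.x, fixes["y_km"] - colony.y).to_numpy()
    r, c = mask.grid.xy_to_rc(fixes["x_km"].to_numpy(), fixes["y_km"].to_numpy())
    on_land = mask.is_land[r, c]
    home = (d <= return_radius_km) | on_land
    trips: list[Trip] = []
    i = 0
    n = len(fixes)
    while i < n:
        if home[i]:
            i += 1
            continue
        j = i
        while j < n and not home[j]:
            j += 1
        # at-sea run is fixes[i:j]; bounding home fixes are i-1 and j (if they exist)
        if i > 0 and j < n and (j - i) >= min_trip_fixes:
            seg = fixes.iloc[i - 1 : j + 1].reset_index(drop=True)
            trips.append(
                Trip(
                    trip_id=f"{track.individual_id}_t{len(trips):03d}",
                    individual_id=track.individual_id,
                    species=track.species,
                    colony_id=track.colony_id,
                    group=track.group,
                    fixes=seg,
                )
            )
        i = j
    return trips


def split_gappy_trips(
    trips: list[Trip],
    mask: LandMask,
    mean_speed_kmh: float = 6.0,
    min_trip_fixes: int = 3,
) -> list[Trip]:
    """Split trips at temporal gaps long enough for an unseen land return.

    A gap between consecutive fixes splits the trip when its duration exceeds
    the time to swim to the nearest coast and back out at ``mean_speed_kmh``
    (coast distance of the fix before plus that of the fix after, divided by
    the mean speed). Split pieces are re-checked against ``min_trip_fixes``.
    """
    if mean_speed_kmh <= 0:
        raise ValueError("mean_speed must be positive")
    d_land = mask.distance_to_land_km()
    out: list[Trip] = []
    for trip in trips:
        fixes = trip.fixes
        r, c = mask.grid.xy_to_rc(fixes["x_km"].to_numpy(), fixes["y_km"].to_numpy())
        coast = d_land[r, c]
        dt_h = fixes["timestamp"].diff().dt.total_seconds().to_numpy()[1:] / 3600.0
        feasible_h = (coast[:-1] + coast[1:]) / mean_speed_kmh
        cut_after = np.nonzero(dt_h > feasible_h)[0]  # gap between k and k+1
        if len(cut_after) == 0:
            out.append(trip)
            continue
        bounds = [0] + [int(k) + 1 for k in cut_after] + [len(fixes)]
        part = 0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = fixes.iloc[a:b].reset_index(drop=True)
            if len(seg) >= min_trip_fixes:
                out.append(
                    Trip(
                        trip_id=f"{trip.trip_id}_g{part}",
                        individual_id=trip.individual_id,
                        species=trip.species,
                        colony_id=trip.colony_id,
                        group=trip.group,
                        fixes=seg,
                    )
                )
                part += 1
    return out


def _hour_grid(t0: pd.Timestamp, t1: pd.Timestamp, interval_h: float) -> pd.DatetimeIndex:
    n = int(np.floor((t1 - t0).total_seconds() / 3600.0 / interval_h))
    return pd.DatetimeIndex([t0 + pd.Timedelta(hours=interval_h * k) for k in range(n + 1)])


def _ctcrw_smooth(th: np.ndarray, xy: np.ndarray, obs_sd: np.ndarray, th_out: np.ndarray) -> np.ndarray:
    """Kalman filter–smoother for an integrated Ornstein–Uhlenbeck velocity model.

    State per axis is (position, velocity); velocity mean-reverts at rate
    beta with diffusion sigma; observations are positions with isotropic
    Gaussian error. beta and sigma are fitted by maximum likelihood on both
    axes jointly; smoothed position means are returned at ``th_out``.
    """
    t_all = np.unique(np.concatenate([th, th_out]))
    obs_idx = np.searchsorted(t_all, th)

    def run(log_params, want_smooth=False):
        beta = np.exp(np.clip(log_params[0], -8.0, 8.0))
        sigma = np.exp(np.clip(log_params[1], -8.0, 8.0))
        m = len(t_all)
        xs = np.zeros((m, 2, 2))  # filtered mean per axis
        Ps = np.zeros((m, 2, 2, 2))
        x_pred = np.zeros((m, 2, 2))
        P_pred = np.zeros((m, 2, 2, 2))
        Ts = np.zeros((m, 2, 2))
        x = np.zeros((2, 2))
        x[:, 0] = xy[0]
        P = np.array([np.diag([1.0, sigma**2 / (2 * beta)])] * 2)
        nll = 0.0
        j = 0
        obs_at = {int(i): k for k, i in enumerate(obs_idx)}
        for i in range(m):
            if i > 0:
                dt = t_all[i] - t_all[i - 1]
                eb = np.exp(-beta * dt)
                T = np.array([[1.0, (1 - eb) / beta], [0.0, eb]])
                s2 = sigma**2
                qvv = s2 / (2 * beta) * (1 - eb**2)
                qxv = s2 / (2 * beta**2) * (1 - 2 * eb + eb**2)
                qxx = s2 / beta**2 * (dt - 2 * (1 - eb) / beta + (1 - eb**2) / (2 * beta))
                Q = np.array([[qxx, qxv], [qxv, qvv]])
                for ax in range(2):
                    x[ax] = T @ x[ax]
                    P[ax] = T @ P[ax] @ T.T + Q
                Ts[i] = T
            x_pred[i], P_pred[i] = x.copy(), P.copy()
            if i in obs_at:
                k = obs_at[i]
                r2 = obs_sd[k] ** 2
                for ax in range(2):
                    S = max(P[ax][0, 0] + r2, 1e-12)
                    innov = xy[k, ax] - x[ax][0]
                    nll += 0.5 * (np.log(2 * np.pi * S) + innov**2 / S)
                    K = P[ax][:, 0] / S
                    x[ax] = x[ax] + K * innov
                    P[ax] = P[ax] - np.outer(K, P[ax][0, :])
            xs[i], Ps[i] = x.copy(), P.copy()
        if not want_smooth:
            return nll
        # RTS smoother
        xsm = xs.copy()
        Psm = Ps.copy()
        for i in range(m - 2, -1, -1):
            T = Ts[i + 1]
            for ax in range(2):
                G = Ps[i, ax] @ T.T @ np.linalg.inv(P_pred[i + 1, ax])
                xsm[i, ax] = xs[i, ax] + G @ (xsm[i + 1, ax] - x_pred[i + 1, ax])
                Psm[i, ax] = Ps[i, ax] + G @ (Psm[i + 1, ax] - P_pred[i + 1, ax]) @ G.T
        out_idx = np.searchsorted(t_all, th_out)
        return xsm[out_idx, :, 0]  # (n_out, 2) positions

    span = max(th[-1] - th[0], 1e-6)
    scale = np.hypot(*(xy[-1] - xy[0])) / span + 1.0
    x0 = np.log([1.0, max(scale, 1e-3)])
    res = minimize(run, x0, method="Nelder-Mead", options={"maxiter": 120, "xatol": 1e-3, "fatol": 1e-4})
    sm = run(res.x, want_smooth=True)
    return np.asarray(sm).reshape(len(th_out), 2)


def regularize(
    trip: Trip,
    interval_h: float = 1.0,
    method: str = "linear",
    obs_sd_km: dict[str, float] | None = None,
) -> Trip:
    """Resample a trip to a fixed time grid between departure and return.

    ``linear`` interpolates positions piecewise-linearly in time (the default
    for effectively error-free gps fixes); ``ctcrw`` runs the CTCRW Kalman
    smoother with per-source isotropic observation noise (km; gps defaults to
    0, argos 1.0, fastloc 0.1) and returns the smoothed means on the grid.
    """
    fixes = trip.fixes
    if len(fixes) < 2:
        raise ValueError("trip needs at least 2 fixes to regularize")
    t0, t1 = fixes["timestamp"].iloc[0], fixes["timestamp"].iloc[-1]
    if (t1 - t0).total_seconds() < interval_h * 3600.0:
        raise ValueError("trip span shorter than the regularization interval")
    grid_t = _hour_grid(t0, t1, interval_h)
    th = (fixes["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    th_out = (grid_t - t0).total_seconds().to_numpy() / 3600.0
    xy = fixes[["x_km", "y_km"]].to_numpy().astype(float)
    if method == "linear":
        x = np.interp(th_out, th, xy[:, 0])
        y = np.interp(th_out, th, xy[:, 1])
    elif method == "ctcrw":
        sd_map = {"gps": 0.0, "argos": 1.0, "fastloc": 0.1}
        if obs_sd_km:
            sd_map.update(obs_sd_km)
        obs_sd = fixes["source"].map(sd_map).fillna(0.5).to_numpy() + 1e-6
        pos = _ctcrw_smooth(th, xy, obs_sd, th_out)
        x, y = pos[:, 0], pos[:, 1]
    else:
        raise ValueError(f"unknown regularization method {method!r}")
    reg = pd.DataFrame({"timestamp": grid_t, "x_km": x, "y_km": y})
    return Trip(
        trip_id=trip.trip_id,
        individual_id=trip.individual_id,
        species=trip.species,
        colony_id=trip.colony_id,
        group=trip.group,
        fixes=trip.fixes,
        regular=reg,
    )


def trip_max_distance(trip: Trip, colony: Colony) -> float:
    """Maximum straight-line distance (km) from the colony over the trip."""
    pos = trip.positions
    if len(pos) == 0:
        raise ValueError("empty trip")
    return float(np.hypot(pos["x_km"] - colony.x, pos["y_km"] - colony.y).max())


def trip_cumulative_distance(trip: Trip) -> float:
    """Cumulative along-path length (km) of the trip."""
    pos = trip.positions
    return float(np.hypot(np.diff(pos["x_km"]), np.diff(pos["y_km"])).sum())


def trip_summary(trips: list[Trip], colony: Colony) -> pd.DataFrame:
    """Per-trip summary table (ids, span, fix count, max and mean distance km)."""
    rows = []
    for t in trips:
        d = np.hypot(t.positions["x_km"] - colony.x, t.positions["y_km"] - colony.y)
        rows.append(
            {
                "trip_id": t.trip_id,
                "individual_id": t.individual_id,
                "colony_id": t.colony_id,
                "start": t.start,
                "end": t.end,
                "n_fixes": len(t.fixes),
                "max_distance_km": float(d.max()),
                "mean_distance_km": float(d.mean()),
                "cumulative_km": trip_cumulative_distance(t),
            }
        )
    return pd.DataFrame(rows)
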