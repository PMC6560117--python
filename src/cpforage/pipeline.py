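"""End-to-end pipeline stages wiring the library together.

Each stage reads the previous stage's artifacts from the output directory and
writes its own, plus a machine-readable manifest (inputs, config hash, seeds,
row/cell counts). The synthetic world itself is regenerated deterministically
from the config seed at every stage rather than serialized, which keeps all
artifacts plain text and bitwise-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import RunConfig
from .grids import GridSpec, LandMask
from .habitat_design import (
    ALL_COVARIATES,
    build_case_control,
    distance_raster,
    standardize,
    vif_screen,
)
from .habitat_model import FoldScheme, forward_stepwise
from .prediction_surfaces import (
    colony_surfaces,
    cumulative_surface,
    overlap_surface,
    species_surface,
)
from .space_use import (
    NoARSScaleError,
    SingleIndividualColonyError,
    ars_scale,
    colony_ud,
    isopleth,
    kernel_ud,
    merge_isopleths,
    representativeness,
)
from .synthetic_world import TruthPreference, make_world, place_colonies, simulate_tracks
from .track_processing import (
    Trip,
    delineate_trips,
    filter_fastloc,
    regularize,
    speed_filter,
    split_gappy_trips,
    trip_summary,
)

log = logging.getLogger(__name__)


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(f"{path} not found: run the {produced_by!r} stage first")
    return path


def _manifest(outdir: Path, stage: str, cfg: RunConfig, counts: dict) -> None:
    payload = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": counts,
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def build_world(cfg: RunConfig):
    """Deterministically regenerate the world, colonies and truth from the config."""
    grid = GridSpec(**vars(cfg.world.grid))
    mask, env = make_world(grid, cfg.world.n_islands, cfg.seed, n_days=cfg.world.n_days)
    colonies = place_colonies(mask, cfg.colonies.n, cfg.colonies.size_range, cfg.seed + 1)
    return mask, env, colonies


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    mask, env, colonies = build_world(cfg)
    all_tracks = []
    for gi, g in enumerate(cfg.groups):
        truth = TruthPreference.unimodal(
            distance_coef=g.truth.distance_coef,
            peak_depth_m=g.truth.peak_depth_m,
            width_m=g.truth.width_m,
            amplitude=g.truth.amplitude,
            noise_sd=g.truth.noise_sd,
        )
        tracks = simulate_tracks(
            colonies,
            env,
            mask,
            truth,
            n_individuals=g.n_individuals,
            trips_per_individual=g.trips_per_individual,
            error_model=vars(cfg.error_model),
            seed=cfg.seed + 100 + gi,
            group=g.name,
            species=g.species,
        )
        for t in tracks:
            t.individual_id = f"{g.name}_{t.individual_id}"
        all_tracks.extend(tracks)
    cio.write_tracks_csv(all_tracks, outdir / "tracks.csv")
    cio.write_colonies_csv(colonies, outdir / "colonies.csv")
    cio.write_landmask(mask, outdir / "landmask.asc")
    cio.write_ascii_grid(outdir / "bathymetry.asc", mask.grid, env.static["bathymetry"])
    cio.write_ascii_grid(outdir / "slope.asc", mask.grid, env.static["slope"])
    n_fixes = sum(len(t.fixes) for t in all_tracks)
    log.info("simulate: %d tracks, %d fixes, %d colonies", len(all_tracks), n_fixes, len(colonies))
    _manifest(outdir, "simulate", cfg, {"tracks": len(all_tracks), "fixes": n_fixes, "colonies": len(colonies)})


def _group_cfg(cfg: RunConfig, name: str):
    for g in cfg.groups:
        if g.name == name:
            return g
    raise KeyError(name)


def stage_preprocess(cfg: RunConfig, outdir: Path) -> None:
    mask, env, colonies = build_world(cfg)
    tracks = cio.read_tracks_csv(_require(outdir / "tracks.csv", "simulate"))
    col_by_id = {c.id: c for c in colonies}
    a = cfg.analysis
    all_positions = []
    summaries = []
    for track in tracks:
        g = _group_cfg(cfg, track.group)
        fixes = filter_fastloc(track.fixes)
        fixes = speed_filter(fixes, g.vmax_ms)
        track.fixes = fixes
        colony = col_by_id[track.colony_id]
        trips = delineate_trips(track, mask, colony, a.return_radius_km, a.min_trip_fixes)
        if g.gap_prone:
            trips = split_gappy_trips(trips, mask, a.gap_mean_speed_kmh, a.min_trip_fixes)
        regs = []
        for trip in trips:
            try:
                regs.append(regularize(trip, 1.0, g.regularize))
            except ValueError:
                continue
        if regs:
            summaries.append(trip_summary(regs, colony))
        for trip in regs:
            pos = trip.regular.copy()
            pos.insert(0, "trip_id", trip.trip_id)
            pos.insert(1, "individual_id", trip.individual_id)
            pos.insert(2, "colony_id", trip.colony_id)
            pos.insert(3, "group", trip.group)
            pos.insert(4, "species", trip.species)
            all_positions.append(pos)
    if not all_positions:
        raise ValueError("preprocessing produced no trips")
    positions = pd.concat(all_positions, ignore_index=True)
    positions.to_csv(outdir / "positions.csv", index=False)
    pd.concat(summaries, ignore_index=True).to_csv(outdir / "trips.csv", index=False)
    log.info("preprocess: %d trips, %d hourly positions", positions["trip_id"].nunique(), len(positions))
    _manifest(outdir, "preprocess", cfg, {"trips": int(positions["trip_id"].nunique()), "positions": len(positions)})


def load_trips(outdir: Path) -> list[Trip]:
    pos = pd.read_csv(_require(outdir / "positions.csv", "preprocess"))
    pos["timestamp"] = pd.to_datetime(pos["timestamp"], utc=True)
    trips = []
    for trip_id, sub in pos.groupby("trip_id", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        reg = sub[["timestamp", "x_km", "y_km"]]
        trips.append(
            Trip(
                trip_id=str(trip_id),
                individual_id=str(sub["individual_id"].iloc[0]),
                species=str(sub["species"].iloc[0]),
                colony_id=str(sub["colony_id"].iloc[0]),
                group=str(sub["group"].iloc[0]),
                fixes=reg,
                regular=reg,
            )
        )
    return trips


def stage_spaceuse(cfg: RunConfig, outdir: Path) -> None:
    mask, env, colonies = build_world(cfg)
    trips = load_trips(outdir)
    a = cfg.analysis
    radii = cfg.fpt_radii()
    rep_rows = []
    level_sets = []
    for g in cfg.groups:
        gtrips = [t for t in trips if t.group == g.name]
        if not gtrips:
            continue
        try:
            h, _ = ars_scale(gtrips, radii)
        except NoARSScaleError:
            h = a.fallback_h_km
            log.warning("spaceuse %s: no ARS scale, falling back to h=%.1f km", g.name, h)
        by_colony: dict[str, list] = {}
        for t in gtrips:
            by_colony.setdefault(t.colony_id, []).append(t)
        colony_uds = []
        for cid, ctrips in sorted(by_colony.items()):
            by_ind: dict[str, list] = {}
            for t in ctrips:
                by_ind.setdefault(t.individual_id, []).append(t)
            ind_uds = []
            for ind, itrips in sorted(by_ind.items()):
                positions = pd.concat([t.positions for t in itrips], ignore_index=True)
                ind_uds.append(kernel_ud(positions, h, mask, n_trips=len(itrips)))
            try:
                cud = colony_ud(ind_uds)
            except SingleIndividualColonyError:
                log.warning("spaceuse %s: colony %s has one individual, excluded", g.name, cid)
                continue
            colony_uds.append((cid, cud))
            level_sets.append(isopleth(cud, a.isopleth_level))
            cio.write_ascii_grid(outdir / f"ud_{g.name}_{cid}.asc", mask.grid, cud.density)
            rep = representativeness(ctrips, mask, h, n_iter=a.rep_iters, seed=cfg.seed + 7, level=a.isopleth_level)
            rep_rows.append(
                {
                    "group": g.name,
                    "colony_id": cid,
                    "h_km": h,
                    "n_trips": len(ctrips),
                    "observed_area_km2": rep.observed_area_km2,
                    "asymptote_area_km2": rep.asymptote_area_km2,
                    "value_percent": rep.value_percent,
                    "representative": rep.representative,
                }
            )
        for cid, cud in colony_uds:
            iso = isopleth(cud, a.isopleth_level)
            cio.isopleth_to_geojson(iso, outdir / f"isopleth_{g.name}_{cid}.geojson")
    if level_sets:
        counts = merge_isopleths(level_sets)
        cio.write_ascii_grid(outdir / "core_overlap_count.asc", mask.grid, counts.astype(float))
    pd.DataFrame(rep_rows).to_csv(outdir / "representativeness.csv", index=False)
    _manifest(outdir, "spaceuse", cfg, {"colony_uds": len(level_sets)})


def stage_design(cfg: RunConfig, outdir: Path) -> None:
    mask, env, colonies = build_world(cfg)
    trips = load_trips(outdir)
    trips_table = pd.read_csv(_require(outdir / "trips.csv", "preprocess"))
    a = cfg.analysis
    dist_rasters = {c.id: distance_raster(c, mask) for c in colonies}
    col_by_id = {c.id: c for c in colonies}
    for g in cfg.groups:
        gtrips = [t for t in trips if t.group == g.name]
        if not gtrips:
            continue
        gmax = float(
            trips_table[trips_table["trip_id"].isin([t.trip_id for t in gtrips])]["max_distance_km"].max()
        )
        tables = []
        for cid in sorted({t.colony_id for t in gtrips}):
            ctrips = [t for t in gtrips if t.colony_id == cid]
            pres = pd.concat([t.positions for t in ctrips], ignore_index=True)
            pres = pres.rename(columns={"timestamp": "ts"})
            pres["date"] = pres["ts"].dt.date
            pres = pres[["x_km", "y_km", "date"]]
            tables.append(
                build_case_control(
                    pres,
                    col_by_id[cid],
                    gmax,
                    env,
                    mask,
                    colonies,
                    dist_rasters,
                    ratio=a.ratio,
                    accessibility_factor=a.accessibility_factor,
                    seed=cfg.seed + 13,
                )
            )
        table = pd.concat(tables, ignore_index=True)
        table, params = standardize(table)
        table.to_csv(outdir / f"casecontrol_{g.name}.csv", index=False)
        meta = {
            "group": g.name,
            "ratio": a.ratio,
            "accessibility_factor": a.accessibility_factor,
            "max_trip_distance_km": gmax,
            "seed": cfg.seed + 13,
            "standardization": {k: list(v) for k, v in params.items()},
        }
        with open(outdir / f"casecontrol_{g.name}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        log.info("design %s: %d rows (%d presences)", g.name, len(table), int((table["label"] == 1).sum()))
    _manifest(outdir, "design", cfg, {"groups": len(cfg.groups)})


def stage_fit(cfg: RunConfig, outdir: Path) -> None:
    a = cfg.analysis
    for g in cfg.groups:
        path = _require(outdir / f"casecontrol_{g.name}.csv", "design")
        table = pd.read_csv(path)
        with open(outdir / f"casecontrol_{g.name}.meta.json") as fh:
            meta = json.load(fh)
        params = {k: tuple(v) for k, v in meta["standardization"].items()}
        # model fits operate on standardized values under the covariate names
        fit_table = table[["label", "colony_id"]].copy()
        for name in ALL_COVARIATES:
            if name + "_std" in table:
                fit_table[name] = table[name + "_std"]
        candidates = vif_screen(fit_table, [c for c in ALL_COVARIATES if c in fit_table], a.vif_threshold)
        if fit_table["colony_id"].nunique() >= 2:
            scheme = FoldScheme.by_colony(fit_table)
        else:
            scheme = FoldScheme.random_split(fit_table, seed=cfg.seed + 17)
        model = forward_stepwise(
            fit_table,
            candidates,
            scheme,
            group=g.name,
            k=a.knots,
            tie_epsilon=a.tie_epsilon,
            standardization=params,
        )
        cio.model_to_json(model, outdir / f"model_{g.name}.json")
        log.info("fit %s: terms=%s CV AUC=%.3f", g.name, [t.name for t in model.terms], model.cv_metrics["auc"])
    _manifest(outdir, "fit", cfg, {"groups": len(cfg.groups)})


def stage_predict(cfg: RunConfig, outdir: Path) -> None:
    mask, env, colonies = build_world(cfg)
    trips_table = pd.read_csv(_require(outdir / "trips.csv", "preprocess"))
    a = cfg.analysis
    dist_rasters = {c.id: distance_raster(c, mask) for c in colonies}
    group_maps = []
    for g in cfg.groups:
        model = cio.model_from_json(_require(outdir / f"model_{g.name}.json", "fit"))
        pos = pd.read_csv(outdir / "positions.csv")
        gmax = float(trips_table["max_distance_km"].max())
        surfs = colony_surfaces(
            model, colonies, env, mask, dist_rasters, gmax, a.accessibility_factor
        )
        weighted = species_surface(
            list(surfs.values()), weights=[c.population_size for c in colonies], group=g.name
        )
        combined = species_surface(list(surfs.values()), group=g.name)
        cio.write_ascii_grid(outdir / f"tau_{g.name}.asc", mask.grid, combined.tau)
        cio.write_ascii_grid(outdir / f"tau_{g.name}_weighted.asc", mask.grid, weighted.tau)
        group_maps.append(combined)
    cum = cumulative_surface(group_maps)
    ovl = overlap_surface(group_maps, a.presence_threshold)
    cio.write_ascii_grid(outdir / "cumulative.asc", mask.grid, cum)
    cio.write_ascii_grid(outdir / "overlap_count.asc", mask.grid, ovl.astype(float))
    _render_png(outdir / "cumulative.png", cum, mask)
    _render_png(outdir / "overlap_count.png", ovl.astype(float), mask)
    _manifest(outdir, "predict", cfg, {"groups": len(group_maps)})


def _render_png(path: Path, values: np.ndarray, mask: LandMask) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.where(mask.is_land, np.nan, values)
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(shown, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("col")
    ax.set_ylabel("row")
    fig.savefig(path, dpi=100)
    plt.close(fig)


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "spaceuse": stage_spaceuse,
    "design": stage_design,
    "fit": stage_fit,
    "predict": stage_predict,
}


def run_pipeline(cfg: RunConfig, command: str = "all") -> Path:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if command == "all":
        for name, fn in STAGES.items():
            log.info("stage %s", name)
            fn(cfg, outdir)
    elif command in STAGES:
        STAGES[command](cfg, outdir)
    else:
        raise ValueError(f"unknown command {command!r}")
    return outdir
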