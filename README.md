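# cpforage

Colony-based habitat-use analysis for central-place foraging marine
predators — seabirds and pinnipeds that breed at fixed colonies and forage at
sea. From raw tracking fixes the package builds foraging trips, kernel
utilization distributions with a first-passage-time bandwidth, case-control
habitat-selection GAMs validated by leave-one-colony-out ROC, and corrected
probability-of-use surfaces for **both tracked and untracked colonies**,
including multi-species cumulative and overlap maps. A seeded synthetic-world
generator with a known habitat preference makes every stage testable without
any tracking data.

## The model

Habitat selection is a case-control logistic GAM: each observed at-sea
location (case) is contrasted with `ratio = 3` pseudo-absences (controls)
sampled uniformly from the water the colony's animals can reach — sea cells
within 1.1 × the group's maximum trip distance by least-cost (land-avoiding)
travel — and temporally matched to the tracking dates. Smooth terms are
cubic regression splines with shrinkage (k = 3 knots, raised when residuals
misbehave), over up to seven covariates: least-cost distance to the colony,
an intraspecific competition index (Σ N/d² over other colonies), bathymetry,
slope, SST, SLA and eddy kinetic energy ½(U² + V²). Covariates enter by
forward stepwise selection ordered and validated by cross-validated AUC.

Because the fitted model sees one presence per three pseudo-absences, its
raw output is not a probability of use. The prediction surface applies the
case-control correction

    tau(x) = exp{ log[(1 − P_a) P_u / P_a] + beta_0 + f_1(x_1) + ... + f_p(x_p) }
             -----------------------------------------------------------------
             1 + exp{ ... }

where P_a and P_u are the absence/presence proportions of the design (3:1
gives an offset of log(1/12), so tau = 1/13 where the linear predictor is
zero). Space use is summarized by kernel UDs whose bandwidth h is the mean
area-restricted-search scale (the radius maximizing the variance of log
first-passage time, 1–150 km), 50% isopleth core areas, and trip-subsampling
representativeness curves (≥ 75% of the fitted asymptote is considered
representative).

## Worked example

Simulate four colonies on a synthetic archipelago with a known preference
(use declining with distance from the colony, peaking over ~180 m depths),
run the full chain, and fit the habitat model:

```python
import numpy as np, pandas as pd
import cpforage as cf
from cpforage.habitat_design import (ALL_COVARIATES, build_case_control,
                                     distance_raster, standardize, vif_screen)
from cpforage.habitat_model import FoldScheme, forward_stepwise
from cpforage.track_processing import (delineate_trips, filter_fastloc,
                                       regularize, speed_filter, trip_summary)

grid = cf.GridSpec(0, 0, 80, 80, 2.0)                      # 160 x 160 km, 2-km cells
mask, env = cf.make_world(grid, n_islands=3, seed=101, n_days=15)
colonies = cf.place_colonies(mask, 4, (500, 20000), seed=102)
truth = cf.TruthPreference.unimodal(distance_coef=-0.035, peak_depth_m=180,
                                    amplitude=4.0, width_m=90, noise_sd=0.5)
tracks = cf.simulate_tracks(colonies, env, mask, truth, n_individuals=28,
                            trips_per_individual=7,
                            error_model={"argos_sd": 0.5, "gap_prob": 0.05,
                                         "fastloc_sat_range": (3, 12)}, seed=103)

by_id = {c.id: c for c in colonies}
trips = []
for track in tracks:
    track.fixes = speed_filter(filter_fastloc(track.fixes), vmax_ms=3.0)
    for trip in delineate_trips(track, mask, by_id[track.colony_id]):
        trips.append(regularize(trip, interval_h=1.0, method="linear"))
summary = pd.concat([trip_summary([t], by_id[t.colony_id]) for t in trips],
                    ignore_index=True)
gmax = float(summary["max_distance_km"].max())
print(f"{len(trips)} trips from {len(tracks)} individuals; "
      f"max trip distance {gmax:.1f} km")

dist = {c.id: distance_raster(c, mask) for c in colonies}
tables = []
for cid in sorted({t.colony_id for t in trips}):
    pres = pd.concat([t.positions for t in trips if t.colony_id == cid],
                     ignore_index=True)
    pres["date"] = pres["timestamp"].dt.date
    tables.append(build_case_control(pres[["x_km", "y_km", "date"]], by_id[cid],
                                     gmax, env, mask, colonies, dist,
                                     ratio=3, seed=104))
table, params = standardize(pd.concat(tables, ignore_index=True))
fit_table = table[["label", "colony_id"]].copy()
for name in ALL_COVARIATES:
    fit_table[name] = table[name + "_std"]
candidates = vif_screen(fit_table, ALL_COVARIATES, threshold=3.0)
model = forward_stepwise(fit_table, candidates, FoldScheme.by_colony(fit_table),
                         group="demo", standardization=params, try_tensor=None)
print("selected terms:", [t.name for t in model.terms])
print(f"leave-one-colony-out AUC {model.cv_metrics['auc']:.3f} "
      f"+- {model.cv_metrics['auc_sd']:.3f}")
print(f"case-control offset log[(1-Pa)Pu/Pa] = {model.offset:.3f}  "
      f"(tau = {1/(1+np.exp(-model.offset)):.4f} at eta = 0)")
```

Output:

```
192 trips from 28 individuals; max trip distance 26.4 km
selected terms: ['distance', 'bathymetry']
leave-one-colony-out AUC 0.906 +- 0.008
case-control offset log[(1-Pa)Pu/Pa] = -2.486  (tau = 0.0768 at eta = 0)
```

The stepwise search recovered exactly the two covariates that generated the
data (distance from the colony and bathymetry) and discriminates held-out
colonies' presences from availability at AUC ≈ 0.91. The offset shows the
3:1 correction at work: where habitat is indifferent (eta = 0), the
probability of use is 1/13, not 1/2. From here,
`cpforage.colony_surfaces(...)` produces a tau raster per colony — including
colonies never tracked — and `cumulative_surface` / `overlap_surface`
combine groups into multi-species maps.

The same pipeline runs from a YAML config via the CLI:

```sh
cpforage all --config demo.yaml      # or: simulate, preprocess, spaceuse,
                                     #     design, fit, predict stage by stage
```

Each stage writes plain-text artifacts (CSV tables, ESRI ASCII grid rasters,
GeoJSON isopleths, JSON models and manifests) into the configured output
directory, and reruns with the same config and seed are bitwise-identical.

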