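# Methods

`cpforage` turns central-place-foraging tracking data into colony-level
utilization distributions, case-control habitat-selection models, and
probability-of-use surfaces for both tracked and untracked colonies. This
note records the models, their assumptions, the tunable parameters, and the
design choices made where the procedure was genuinely open.

## Analysis frame

All computation happens on a single planar equal-area grid in kilometre
coordinates (`GridSpec`). Synthetic worlds are natively planar; real data
would be projected to an equal-area system before entering the pipeline, an
I/O concern kept outside the analysis modules. Bathymetry is stored as
**positive depth in metres** so depth filters read naturally; negative-down
sources must be negated at the boundary.

## Synthetic world and movement model

The generator produces the statistical structure the analysis assumes, not
realistic oceanography:

- **Land** — elliptical island bumps with a smooth ragged-coast perturbation.
- **Bathymetry** — deepens with distance from land
  (`15 + 9 d + 0.9 d^1.5` m at `d` km offshore, plus smooth noise of ~4 m
  amplitude), so depth and offshore distance are strongly but not perfectly
  related. Slope is the finite-difference gradient of depth in degrees.
- **Dynamic layers** — SST (south–north gradient plus smooth anomalies), SLA,
  and geostrophic currents evolve as daily AR(1) smooth Gaussian fields;
  EKE = (u² + v²)/2 cell-wise.
- **Movement** — a discrete-time biased random walk over sea cells. The
  per-cell selection weight is `exp(eta)` with
  `eta = distance_coef * d_colony + f(depth) + noise`, where `d_colony` is
  the least-cost at-sea distance and `f` a tabulated depth response
  (default: Gaussian bump around a shelf depth). After a random outbound
  phase the walker descends the least-cost distance field home, so every
  trip starts and ends on the colony cell. The outbound phase is kept out of
  the immediate colony neighbourhood so simulated trips are cleanly
  separated — a generator convenience, not an inference assumption.
- **Observation model** — Gaussian positional error per source (argos at
  `argos_sd` km, fastloc at a tenth of that, gps error-free), per-fix
  dropout with probability `gap_prob`, Argos quality classes, and fastloc
  satellite counts drawn from `fastloc_sat_range`.

The generator does **not** emulate behavioural state switching, eddy
dynamics, tidal fronts, or multi-species interactions, and its positional
error is isotropic. Passing tests therefore demonstrate that the estimators
recover the structure they assume; they say nothing about robustness to,
e.g., anisotropic Argos error ellipses or strongly autocorrelated
preferences.

## Track processing

- **Fastloc screening** drops fixes with fewer than 4 satellites; a fastloc
  fix without a satellite count is an error rather than a silent keep.
- **Speed filter** (3 m/s for swimmers, 20 m/s for flying seabirds):
  the filter iteratively finds the consecutive pair implying the largest
  speed and removes whichever member's deletion better reduces local
  violations, keeping the earlier fix on ties. This rule is deterministic
  and idempotent, which makes it testable; other published filters differ in
  details but share the worst-violator structure.
- **Trip delineation** bounds trips by fixes within `return_radius_km`
  (default 2 km) of the colony or on land, and requires `min_trip_fixes`
  (default 3) at-sea fixes. Both defaults are config-exposed; neither is a
  principled constant.
- **Gap splitting** (for gap-prone groups such as winter penguin Argos
  data): a temporal gap splits a trip when it exceeds the time to reach the
  nearest coast and return at a mean swim speed (default 6 km/h), computed
  as `(d_coast_before + d_coast_after) / speed`.
- **Regularization** to hourly positions: piecewise-linear interpolation
  (appropriate for effectively error-free gps), or a continuous-time
  correlated random walk smoother — a Kalman filter–smoother on an
  integrated Ornstein–Uhlenbeck velocity state per axis, with isotropic
  per-source observation noise and (beta, sigma) fitted by maximum
  likelihood. This is a simplified isotropic version of the standard CTCRW
  state-space model; per-Argos-class error ellipses are out of scope.

## Space use

- **Bandwidth** h is the mean area-restricted-search scale: per trip, the
  radius maximizing var(log FPT) over positions (first-passage times through
  circles of 1–150 km, crossing instants linearly interpolated, forward and
  backward half-times summed; positions whose circle is never exited are
  undefined, not zero). Trips without an interior variance maximum are
  excluded; if no trip yields a scale the caller falls back to a configured
  h. The per-group scale pools trips across colonies (per-colony pooling is
  a config switch).
- **Kernel UD** — positions are binned to grid cells and convolved with an
  isotropic Gaussian (sigma = h, truncated at 5h); land cells are zeroed and
  the density renormalized. Binned convolution is exact for cell-centre
  positions and within half a cell otherwise, which is below the smoothing
  scale in any sensible configuration.
- **Colony UD** — the cell-wise mean of individual UDs, renormalized;
  colonies with a single tracked individual are excluded (enforced by an
  explicit error).
- **Core areas** — the 50% isopleth is the smallest highest-density cell set
  holding half the mass; density ties at the cut are all included, so a
  uniform UD returns every nonzero cell (conservative).
- **Representativeness** — an accumulation curve over 500 random
  permutations of the trips: mean 50%-core area of the first n trips,
  n = 1..N. Nested subsets share sampling noise across n, which is standard
  accumulation-curve practice and keeps the empirical means nearly monotone;
  independent draws per n would add avoidable Monte-Carlo inversions. The
  curve is fitted with the negative-exponential saturating form
  A(n) = A_inf (1 − exp(−n/c)) (two parameters; initialized at the maximum
  observed area and N/3), and the representative value is
  100 × A(N) / A_inf, with ≥ 75% flagged representative. Confidence bounds
  are 2.5/97.5 percentiles over permutations. A constant curve (e.g.
  identical trips) short-circuits to exactly 100%. Note that pooling
  heavily overlapping trips can make the empirical core area non-monotone in
  n (density concentration); the saturating fit is still well-defined there.

## Case-control design

- **Distance** is the least-cost at-sea distance over the 8-connected
  sea-cell graph (orthogonal steps cost one cell, diagonal steps √2 cells),
  computed by Dijkstra's algorithm. The same least-cost distance is used for
  presences, pseudo-absences and prediction rasters, keeping model and
  prediction spaces consistent.
- **Accessibility** — pseudo-absences are confined to sea cells within
  1.1 × the group's maximum trip distance by least-cost travel.
- **Pseudo-absences** — 3 per presence (config `ratio`), uniform over the
  accessible region's cells and uniform within a cell, with dates drawn
  uniformly from the presence date pool (temporal matching).
- **Null density** — competition at a cell is Σ N_c / d_c² over all other
  colonies (population size over squared least-cost distance, in
  individuals·km⁻²). The distance is floored at half a cell before squaring
  so the raster stays finite at the colony cell without reordering values
  near it.
- **Covariates** — distance, null density, bathymetry, slope, SST, SLA, EKE;
  dynamic values matched to the row's date; rows with any missing covariate
  are dropped and counted. Standardization is (x − mean)/SD with the
  **sample** SD (n − 1); the parameters are stored with the model and reused
  at prediction time. Collinearity is screened by iteratively removing the
  covariate with the largest VIF until all VIF ≤ 3 (threshold
  config-exposed; the choice of 3 is an assumption).

## Habitat model

Binomial GAMs of presence vs pseudo-absence with shrinkage smooths:

- **Basis** — natural cubic regression splines on quantile knots (default
  k = 3, raised to at most 5 when fit is poor), with the exact integrated
  squared-second-derivative penalty and a sum-to-zero constraint per term.
- **Shrinkage** — the penalty's null space (the linear trend) is given a
  small positive eigenvalue (a tenth of the largest penalty eigenvalue), so
  a large smoothing parameter drives a term's effective df to zero and
  uninformative covariates vanish from the fit. On label-independent data,
  per-term edf < 0.05 in practice.
- **Fitting** — penalized IRLS; smoothing parameters are selected per term
  by coordinate descent on the GCV score n·Dev/(n − edf)² over a log-spaced
  grid (two sweeps). Possible complete separation is detected and flagged.
- **Validation** — ROC AUC in the rank (Mann–Whitney) form with ties counted
  one half; sensitivity and specificity at the threshold maximizing
  Youden's J (the operating-point rule is an assumption and affects
  sensitivity/specificity comparability across studies, not AUC).
  Cross-validation is leave-one-colony-out (k = number of tracked colonies);
  groups with a single colony fall back to a random 75/25 split. Folds with
  a single class are skipped with a warning.
- **Selection** — forward stepwise: each candidate is scored alone by CV
  AUC; candidates enter in descending order and are kept only when mean CV
  AUC improves by at least `tie_epsilon` (default 0.01). If the top two
  single-covariate AUCs are within `tie_epsilon`, the procedure reruns from
  each start and the higher final AUC wins. A distance × bathymetry tensor
  smooth (marginal penalties summed, one smoothing parameter) replaces the
  two marginal smooths if it improves CV AUC. A kept term's knots are raised
  3 → 4 → 5 when its deviance residuals fail a Wald–Wolfowitz runs test
  (alpha = 0.05) against the covariate. At most 7 covariates enter a model.
  After selection the model is refit on all data for prediction; reported CV
  metrics come from the selection-time folds.

## Prediction surfaces

The fitted case-control model over-represents presences by design, so the
probability-of-use surface applies the offset correction

    tau(x) = logistic( log[(1 − P_a) P_u / P_a] + eta(x) )

with P_a, P_u the absence/presence proportions (3:1 design: offset
log(1/12), tau = 1/13 at eta = 0). Surfaces are computed per colony —
tracked or untracked — with that colony's own distance and competition
rasters, dynamic covariates averaged over the tracked window, and cells
beyond the accessible region set to zero. Aggregations:

- **Species surface** — cell-wise maximum across colonies (a cell is used if
  animals from any colony use it), or a colony-size-weighted mean.
- **Cumulative map** — each group surface divided by its maximum (so each
  group peaks at 1; config-switchable to sum-to-one) and summed.
- **Overlap map** — per group, presence where the standardized surface
  reaches `presence_threshold` (default 0.5 — the cutoff is an assumption
  and overlap maps are sensitive to it); the map counts groups present per
  cell. Standardization happens after multi-colony aggregation.

## Numerical choices and degenerate inputs

- Isopleth ties: all cells at the cut density are included.
- `N/d²` at the colony cell: distance floored at half a cell.
- GCV grid: log10 lambda in [−4, 8], 13 points, two coordinate sweeps.
- CTCRW parameters optimized by Nelder–Mead on log(beta), log(sigma) with
  bounds at e^±8; observation noise floored at 1e-12 for stability.
- UD mass is validated to 1 ± 1e-9 after every UD-producing operation.
- Zero-variance covariates are excluded from standardization with a warning.

## Problem sizes

The packaged demonstration and verification runs use worlds of 60–80 cells
per side at 2 km resolution, 3–4 colonies, ~20–30 tracked individuals
(≈ 5,000 hourly fixes) and case-control tables of ~20,000 rows; the
saturation analysis uses 60 trips × 500 permutations. These sizes give
stable estimates for every quantity the tests check while keeping a full
run in well under a minute on one core; all of them scale up through the
configuration file.

## Known limitations

- The speed filter and the CTCRW smoother are simplified relative to the
  published tools they stand in for (no per-class Argos error ellipses).
- The GAM's smoothing selection is GCV on a fixed grid, not full REML; edf
  values are approximate at grid resolution.
- Mixed-model trip-distance comparisons, behavioural-state classification,
  spatial/temporal autocorrelation structures and real environmental data
  acquisition are out of scope.
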