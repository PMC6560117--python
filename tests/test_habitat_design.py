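"""Case-control construction: least-cost distances, pseudo-absences, covariates."""

import heapq

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from cpforage import (
    Colony,
    GridSpec,
    LandMask,
    accessible_region,
    distance_raster,
    extract_covariates,
    null_density,
    sample_pseudo_absences,
    standardize,
    vif_screen,
)
from cpforage.habitat_design import ALL_COVARIATES, single_colony_density


def dijkstra_oracle(is_land: np.ndarray, src: tuple, cell: float) -> np.ndarray:
    """Independent binary-heap Dijkstra over the 8-connected sea graph."""
    nr, nc = is_land.shape
    dist = np.full(is_land.shape, np.inf)
    dist[src] = 0.0
    pq = [(0.0, src)]
    while pq:
        d, (r, c) = heapq.heappop(pq)
        if d > dist[r, c]:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and not is_land[rr, cc]:
                    w = cell * (np.sqrt(2.0) if dr and dc else 1.0)
                    if d + w < dist[rr, cc]:
                        dist[rr, cc] = d + w
                        heapq.heappush(pq, (d + w, (rr, cc)))
    return dist


def random_world(rng, n=20, land_frac=0.2):
    grid = GridSpec(0, 0, n, n, 1.0)
    while True:
        is_land = rng.random((n, n)) < land_frac
        if is_land.any() and not is_land.all() and (~is_land).sum() > 4:
            break
    return LandMask(grid, is_land)


class TestDistanceRaster:
    def test_matches_independent_dijkstra_on_random_worlds(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(8, 30))
            mask = random_world(rng, n)
            sea = np.argwhere(mask.is_sea)
            r, c = sea[rng.integers(len(sea))]
            x, y = mask.grid.rc_to_xy(r, c)
            col = Colony("C", "sp", float(x), float(y), 100)
            got = distance_raster(col, mask).values
            want = dijkstra_oracle(mask.is_land, (int(r), int(c)), mask.grid.cell_size)
            assert np.allclose(got[mask.is_sea], want[mask.is_sea], equal_nan=True)

    def test_never_undercuts_euclidean(self):
        rng = np.random.default_rng(1)
        mask = random_world(rng, 25)
        sea = np.argwhere(mask.is_sea)
        r, c = sea[0]
        x, y = mask.grid.rc_to_xy(r, c)
        d = distance_raster(Colony("C", "sp", float(x), float(y), 100), mask).values
        X, Y = mask.grid.cell_centres()
        eu = np.hypot(X - x, Y - y)
        finite = np.isfinite(d) & mask.is_sea
        assert (d[finite] >= eu[finite] - 1e-9).all()

    def test_straight_open_path_exact(self):
        grid = GridSpec(0, 0, 10, 10, 1.0)
        is_land = np.zeros(grid.shape, bool)
        is_land[9, 9] = True
        mask = LandMask(grid, is_land)
        x, y = grid.rc_to_xy(5, 1)
        d = distance_raster(Colony("C", "sp", float(x), float(y), 10), mask).values
        assert np.isclose(d[5, 6], 5.0)
        # diagonal-mix case from a (3,4)-offset cell
        assert np.isclose(d[8, 5], 3 * np.sqrt(2.0) + 1.0)

    def test_detour_longer_than_euclidean_behind_wall(self):
        grid = GridSpec(0, 0, 12, 12, 1.0)
        is_land = np.zeros(grid.shape, bool)
        is_land[2:10, 6] = True  # wall
        mask = LandMask(grid, is_land)
        x, y = grid.rc_to_xy(5, 2)
        d = distance_raster(Colony("C", "sp", float(x), float(y), 10), mask).values
        X, Y = grid.cell_centres()
        eu = np.hypot(X - x, Y - y)
        assert d[5, 9] > eu[5, 9] + 1.0

    def test_colony_on_land_fails(self):
        grid = GridSpec(0, 0, 8, 8, 1.0)
        is_land = np.zeros(grid.shape, bool)
        is_land[4, 4] = True
        mask = LandMask(grid, is_land)
        x, y = grid.rc_to_xy(4, 4)
        with pytest.raises(ValueError):
            distance_raster(Colony("C", "sp", float(x), float(y), 10), mask)


class TestAccessibleRegion:
    def test_radius_is_factor_times_max_distance(self, world, colonies):
        mask, _ = world
        region = accessible_region(colonies[0], 100.0, mask)
        assert np.isclose(region.radius_used_km, 110.0)

    def test_members_verified_against_distance_raster(self, world, colonies):
        mask, _ = world
        dist = distance_raster(colonies[0], mask)
        region = accessible_region(colonies[0], 40.0, mask, 1.0, dist)
        assert (dist.values[region.cells] <= 40.0 + 1e-9).all()
        outside = mask.is_sea & ~region.cells & np.isfinite(dist.values)
        assert (dist.values[outside] > 40.0).all()


class TestPseudoAbsences:
    def make_presences(self, n, rng):
        dates = pd.to_datetime(rng.choice(pd.date_range("2016-01-01", periods=10), size=n)).date
        return pd.DataFrame({"x_km": rng.uniform(0, 10, n), "y_km": rng.uniform(0, 10, n), "date": dates})

    def test_exactly_ratio_rows_and_dates_from_pool(self, world, colonies):
        mask, _ = world
        rng = np.random.default_rng(2)
        region = accessible_region(colonies[0], 60.0, mask)
        pres = self.make_presences(100, rng)
        pseudo = sample_pseudo_absences(pres, region, ratio=3, seed=5)
        assert len(pseudo) == 300
        assert set(pseudo["date"]).issubset(set(pres["date"]))
        r, c = mask.grid.xy_to_rc(pseudo["x_km"].to_numpy(), pseudo["y_km"].to_numpy())
        assert region.cells[r, c].all()
        assert mask.is_sea[r, c].all()

    def test_uniform_over_region_cells(self):
        grid = GridSpec(0, 0, 10, 10, 1.0)
        is_land = np.ones(grid.shape, bool)
        is_land.ravel()[:50] = False
        mask = LandMask(grid, is_land)
        cells = mask.is_sea.copy()
        from cpforage.habitat_design import AccessibleRegion

        region = AccessibleRegion("C", cells, 10.0, grid)
        rng = np.random.default_rng(3)
        pres = self.make_presences(2500, rng)
        pseudo = sample_pseudo_absences(pres, region, ratio=4, seed=6)  # 10,000 draws
        r, c = grid.xy_to_rc(pseudo["x_km"].to_numpy(), pseudo["y_km"].to_numpy())
        flat = r * grid.n_cols + c
        counts = np.bincount(flat, minlength=100)[np.nonzero(cells.ravel())[0]]
        stat, p = chisquare(counts)
        assert p > 0.001

    def test_deterministic_per_seed(self, world, colonies):
        mask, _ = world
        rng = np.random.default_rng(4)
        region = accessible_region(colonies[0], 60.0, mask)
        pres = self.make_presences(50, rng)
        a = sample_pseudo_absences(pres, region, seed=9)
        b = sample_pseudo_absences(pres, region, seed=9)
        assert a.equals(b)


class TestNullDensity:
    def test_direct_formula(self, world):
        mask, _ = world
        grid = mask.grid
        sea = np.argwhere(mask.is_sea)
        r0, c0 = sea[10]
        x, y = grid.rc_to_xy(r0, c0)
        colony = Colony("A", "sp", float(x), float(y), 1000)
        dist = distance_raster(colony, mask)
        dens = single_colony_density(colony, dist)
        at10 = np.isclose(dist.values, 10.0, atol=1e-9)
        if at10.any():
            assert np.allclose(dens[at10], 1000.0 / 100.0)
        # additivity & permutation invariance & linearity with two colonies
        r1, c1 = sea[-10]
        x1, y1 = grid.rc_to_xy(r1, c1)
        colony2 = Colony("B", "sp", float(x1), float(y1), 500)
        rasters = {"A": dist, "B": distance_raster(colony2, mask)}
        comp_a = null_density([colony, colony2], rasters, "A")
        assert np.allclose(comp_a, single_colony_density(colony2, rasters["B"]))
        comp_b = null_density([colony2, colony], rasters, "B")
        assert np.allclose(comp_b, single_colony_density(colony, rasters["A"]))
        doubled = [Colony("A", "sp", float(x), float(y), 2000), Colony("B", "sp", float(x1), float(y1), 1000)]
        assert np.allclose(null_density(doubled, rasters, "A"), 2 * comp_a)

    def test_missing_raster_fails(self, world, colonies):
        mask, _ = world
        with pytest.raises(ValueError):
            null_density(colonies, {}, colonies[0].id)


class TestExtractCovariates:
    def test_lookup_and_drop_count(self, world, colonies):
        mask, env = world
        dist = distance_raster(colonies[0], mask)
        comp = np.ones(mask.grid.shape)
        sea = np.argwhere(mask.is_sea)
        rng = np.random.default_rng(5)
        pick = sea[rng.integers(0, len(sea), 40)]
        x, y = mask.grid.rc_to_xy(pick[:, 0], pick[:, 1])
        good_date = env.dates[0]
        bad_date = pd.Timestamp("1999-01-01").date()
        dates = [good_date] * 30 + [bad_date] * 10
        rows = pd.DataFrame({"label": 1, "x_km": x, "y_km": y, "date": dates, "colony_id": "C00"})
        out, dropped = extract_covariates(rows, env, dist, comp)
        assert dropped == 10
        assert len(out) == 30
        i = 5
        r, c = mask.grid.xy_to_rc(out["x_km"].iloc[i], out["y_km"].iloc[i])
        assert out["bathymetry"].iloc[i] == env.static["bathymetry"][r, c]
        assert out["sst"].iloc[i] == env.dynamic["sst"][good_date][r, c]


class TestStandardize:
    def test_hand_computed_sample_sd(self):
        df = pd.DataFrame({"distance": [1.0, 2.0, 3.0]})
        out, params = standardize(df, ["distance"])
        assert np.allclose(out["distance_std"], [-1.0, 0.0, 1.0])  # sample SD = 1
        mu, sd = params["distance"]
        assert np.isclose(sd, 1.0)

    def test_population_vs_sample_convention_on_known_column(self):
        # {1,2,3} with population SD gives +-1.2247; sample SD (ddof=1) gives +-1
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, _ = standardize(df, ["x"])
        pop = (df["x"] - 2.0) / np.std(df["x"])
        assert np.allclose(np.abs(pop.iloc[0]), 1.2247, atol=1e-4)
        assert np.allclose(out["x_std"].std(ddof=1), 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(3, 5, 100)})
        once, _ = standardize(df, ["x"])
        again, _ = standardize(once.rename(columns={"x_std": "y"})[["y"]], ["y"])
        assert np.allclose(again["y_std"], once["x_std"], atol=1e-12)

    def test_constant_column_excluded(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0], "y": [1.0, 2.0, 4.0]})
        out, params = standardize(df, ["x", "y"])
        assert "x" not in params and "x_std" not in out
        assert "y_std" in out

    def test_stored_params_reused_for_prediction(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.normal(10, 2, 50)})
        _, params = standardize(df, ["x"])
        new = pd.DataFrame({"x": [10.0]})
        out, _ = standardize(new, ["x"], params=params)
        assert np.isclose(out["x_std"].iloc[0], (10.0 - params["x"][0]) / params["x"][1])


class TestVIF:
    def test_perfect_correlation_drops_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=200)})
        kept = vif_screen(df, ["a", "b", "c"], threshold=3.0)
        assert len(kept) == 2 and "c" in kept

    def test_orthogonal_covariates_all_kept(self):
        n = 400
        rng = np.random.default_rng(9)
        df = pd.DataFrame({f"v{i}": rng.normal(size=n) for i in range(4)})
        kept = vif_screen(df, list(df.columns), threshold=3.0)
        assert kept == list(df.columns)

    def test_vif_values_match_explicit_regression(self):
        rng = np.random.default_rng(10)
        n = 300
        a = rng.normal(size=n)
        b = 0.7 * a + rng.normal(size=n)
        c = rng.normal(size=n)
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        # brute-force VIF for 'a'
        import statsmodels.api as sm

        r2 = sm.OLS(a, sm.add_constant(np.column_stack([b, c]))).fit().rsquared
        vif_a = 1 / (1 - r2)
        kept = vif_screen(df, ["a", "b", "c"], threshold=vif_a - 1e-6)
        assert "a" not in kept or "b" not in kept  # the larger-VIF one of the pair dropped


def test_pseudo_absence_label_proportions(world, colonies):
    """3:1 design gives P_a = 3/4 and P_u = 1/4 exactly."""
    mask, _ = world
    rng = np.random.default_rng(11)
    region = accessible_region(colonies[0], 60.0, mask)
    dates = pd.to_datetime(rng.choice(pd.date_range("2016-01-01", periods=5), 80)).date
    pres = pd.DataFrame({"x_km": rng.uniform(0, 5, 80), "y_km": rng.uniform(0, 5, 80), "date": dates, "label": 1})
    pseudo = sample_pseudo_absences(pres, region, ratio=3, seed=12)
    table = pd.concat([pres[["label"]], pseudo[["label"]]], ignore_index=True)
    assert (table["label"] == 0).mean() == 0.75
    assert (table["label"] == 1).mean() == 0.25
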