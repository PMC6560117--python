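import numpy as np
import pandas as pd
import pytest

from cpforage import GridSpec, TruthPreference, make_world, place_colonies, simulate_tracks
from cpforage.track_processing import Trip


@pytest.fixture(scope="session")
def world():
    grid = GridSpec(0.0, 0.0, 80, 80, 2.0)
    mask, env = make_world(grid, n_islands=3, seed=1, n_days=15)
    return mask, env


@pytest.fixture(scope="session")
def colonies(world):
    mask, _ = world
    return place_colonies(mask, 4, (500, 20000), seed=2)


@pytest.fixture(scope="session")
def truth():
    return TruthPreference.unimodal(distance_coef=-0.04, noise_sd=0.5)


@pytest.fixture(scope="session")
def noiseless_tracks(world, colonies, truth):
    mask, env = world
    return simulate_tracks(
        colonies, env, mask, truth,
        n_individuals=8, trips_per_individual=3,
        error_model={"argos_sd": 0.0, "gap_prob": 0.0}, seed=3,
    )


def make_trip(x, y, trip_id="t0", hours_step=1.0, colony_id="C00", individual_id="i0"):
    """Hand-built trip with hourly (or custom) spacing; used across test modules."""
    t0 = pd.Timestamp("2016-01-01", tz="UTC")
    ts = [t0 + pd.Timedelta(hours=hours_step * i) for i in range(len(x))]
    fixes = pd.DataFrame(
        {"timestamp": ts, "x_km": np.asarray(x, float), "y_km": np.asarray(y, float), "source": "gps"}
    )
    return Trip(trip_id, individual_id, "sp", colony_id, "grp", fixes)


@pytest.fixture
def trip_factory():
    return make_trip
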