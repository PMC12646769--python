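import numpy as np
import pandas as pd
import pytest

from wayfarer import synthetic_data as sd
from wayfarer.rasters import LandscapeStack, Raster
from wayfarer.terrain import add_terrain
from wayfarer.tracks import Track


@pytest.fixture(scope="session")
def uniform_config():
    """All-scrub, flat, featureless landscape config."""
    return sd.LandscapeConfig(
        n_cells=300,
        resolution=10.0,
        cover_weights={"scrub": 1.0},
        n_roads=0,
        n_rivers=0,
        dem_amplitude=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def uniform_stack(uniform_config):
    return sd.generate_landscape(uniform_config)


@pytest.fixture(scope="session")
def road_stack():
    """Flat landscape crossed by a single straight road corridor."""
    cfg = sd.LandscapeConfig(
        n_cells=150,
        resolution=10.0,
        cover_weights={"scrub": 0.7, "glade": 0.3},
        n_roads=1,
        n_rivers=0,
        dem_amplitude=0.0,
        seed=3,
    )
    return sd.generate_landscape(cfg)


@pytest.fixture(scope="session")
def default_stack():
    return sd.generate_landscape(sd.LandscapeConfig(n_cells=300, seed=1))


def make_track(
    seconds, xs, ys, individual="bird01", start="2019-09-07 06:00:00", flag="hi"
):
    """Track from second offsets and coordinates."""
    t0 = pd.Timestamp(start)
    df = pd.DataFrame(
        {
            "timestamp": t0 + pd.to_timedelta(np.asarray(seconds), unit="s"),
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
            "resolution_flag": flag,
        }
    )
    return Track(individual_id=individual, df=df)


@pytest.fixture
def straight_track_factory():
    """Straight-line 1 Hz track along +x at constant speed."""

    def _make(speed, n_seconds, **kwargs):
        sec = np.arange(n_seconds + 1)
        return make_track(sec, 600.0 + speed * sec, 600.0, **kwargs)

    return _make


@pytest.fixture
def flat_stack_factory():
    """Small flat single-cover stack for constructed-track energetics."""

    def _make(extent=5000.0, res=10.0):
        n = int(extent / res)
        z = np.zeros((n, n))
        mk = lambda d: Raster(d, 0.0, extent, res)
        stack = LandscapeStack(
            cover=mk(np.zeros((n, n), dtype=int)),
            road=mk(np.zeros((n, n), dtype=int)),
            water=mk(np.zeros((n, n), dtype=int)),
            elevation=mk(z),
        )
        return add_terrain(stack)

    return _make
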