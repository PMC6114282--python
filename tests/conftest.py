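import datetime as dt

import numpy as np
import pytest

from premolt.argos_io import ArgosFix
from premolt.daily_track import daily_aggregate
from premolt.synthetic_data import SimConfig, make_synthetic_coast, simulate_cohort
from premolt.track_filter import sda_filter
from premolt.trips import TripConfig, load_table1, summarize_trip, table1_to_trips


def make_fix(bird="b1", t="2016-12-01T00:00:00", lon=168.0, lat=-44.0, cls="1"):
    ts = dt.datetime.fromisoformat(t).replace(tzinfo=dt.timezone.utc)
    return ArgosFix(bird, ts, lon, lat, cls)


def straight_track(n=10, speed_ms=1.0, lat=-44.0, start_lon=168.0, gap_s=3600,
                   cls="1"):
    """Straight eastward track at constant speed, hourly fixes by default."""
    km_per_deg = 111.3194908 * np.cos(np.radians(lat))
    base = dt.datetime(2016, 12, 1, tzinfo=dt.timezone.utc)
    return [
        ArgosFix(
            "b1",
            base + dt.timedelta(seconds=i * gap_s),
            start_lon + (speed_ms * gap_s * i / 1000.0) / km_per_deg,
            lat,
            cls,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_trips():
    return table1_to_trips()


@pytest.fixture(scope="session")
def cohort20():
    """Seeded 20-bird all-complete cohort with 5% injected outliers,
    filtered, aggregated and segmented once for the whole session."""
    cfg = SimConfig(
        n_birds=20, seed=7, outlier_rate=0.05, censoring_proportions=(20, 0, 0)
    )
    cohort = simulate_cohort(cfg)
    coast = make_synthetic_coast(cfg.colony)
    tcfg = TripConfig(colony=cfg.colony)
    filtered = {b: sda_filter(fixes) for b, fixes in cohort.birds.items()}
    daily = {b: daily_aggregate(r) for b, r in filtered.items()}
    trips = {
        b: summarize_trip(d, tcfg, coastline=coast, metadata=cohort.metadata[b])
        for b, d in daily.items()
    }
    return {
        "config": cfg,
        "cohort": cohort,
        "coast": coast,
        "trip_config": tcfg,
        "filtered": filtered,
        "daily": daily,
        "trips": trips,
    }
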