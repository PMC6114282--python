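"""Trip segmentation and per-bird / cohort trip statistics.

A daily track is segmented into pre-departure coastal sorties, the final
departure, the outward leg (departure to the day of maximum distance from the
deployment site, the "trip reversal"), and the inbound leg ending at landfall
(first day back within a buffer of the coast).  Trip length is the cumulative
sum of daily great-circle steps; maximum range the largest distance from the
deployment location.  Destinations are labelled by a front boundary latitude:
birds whose apex lies south of it are assigned to the Subantarctic Front
(SAF), the rest to the Subtropical Front (STF).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .argos_io import (
    AzimuthalEquidistant,
    Coastline,
    DEFAULT_GEODESY,
    GeodesyConfig,
    great_circle_km,
)
from .daily_track import DailyPosition, daily_steps

GORGE_RIVER_COLONY = (168.188, -44.188)  # lon, lat of the deployment site


@dataclass(frozen=True)
class TripConfig:
    colony: tuple[float, float] = GORGE_RIVER_COLONY
    coast_buffer_km: float = 5.0
    departure_dist_km: float = 20.0
    front_boundary_lat: float = -52.0
    min_away_days: int = 3

    def __post_init__(self) -> None:
        if min(self.coast_buffer_km, self.departure_dist_km, self.min_away_days) <= 0:
            raise ValueError("thresholds must be positive")
        if not (-90.0 < self.front_boundary_lat < 0.0):
            raise ValueError("front boundary latitude must be in (-90, 0)")


@dataclass
class TripSummary:
    bird_id: str
    sex: str | None
    body_mass_kg: float | None
    departure_date: dt.date
    reversal_date: dt.date | None
    landfall_date: dt.date | None
    end_date: dt.date
    trip_length_km: float
    max_range_km: float
    destination: str | None
    daily_dist_median_km: float | None = None
    daily_dist_min_km: float | None = None
    daily_dist_max_km: float | None = None

    @property
    def duration_days(self) -> int:
        """Whole-day calendar difference end - departure."""
        return (self.end_date - self.departure_date).days

    @property
    def outward_days(self) -> int | None:
        if self.reversal_date is None:
            return None
        return (self.reversal_date - self.departure_date).days

    @property
    def inbound_days(self) -> int | None:
        if self.reversal_date is None or self.landfall_date is None:
            return None
        return (self.landfall_date - self.reversal_date).days

    @property
    def status(self) -> str:
        if self.reversal_date is None:
            return "outward_incomplete"
        if self.landfall_date is None:
            return "inbound_incomplete"
        return "complete"

    def to_row(self) -> dict:
        return {
            "bird_id": self.bird_id,
            "sex": self.sex,
            "body_mass_kg": self.body_mass_kg,
            "departure_date": self.departure_date,
            "reversal_date": self.reversal_date,
            "landfall_date": self.landfall_date,
            "end_date": self.end_date,
            "duration_days": self.duration_days,
            "outward_days": self.outward_days,
            "inbound_days": self.inbound_days,
            "trip_length_km": self.trip_length_km,
            "max_range_km": self.max_range_km,
            "destination": self.destination,
            "status": self.status,
            "daily_dist_median_km": self.daily_dist_median_km,
            "daily_dist_min_km": self.daily_dist_min_km,
            "daily_dist_max_km": self.daily_dist_max_km,
        }


def colony_distances(
    daily: Sequence[DailyPosition],
    colony: tuple[float, float],
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> np.ndarray:
    return np.array(
        [great_circle_km((d.lon, d.lat), colony, geodesy) for d in daily]
    )


def detect_final_departure(
    daily: Sequence[DailyPosition],
    config: TripConfig,
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> dt.date:
    """First day of the last away-run lasting >= min_away_days.

    An away-run is a maximal sequence of records further than
    departure_dist_km from the colony.  The final departure is the start of
    the last such run of sufficient span: shorter earlier runs are
    pre-departure foraging sorties, and any return to within coast_buffer_km
    of the colony after a qualifying run is the trip-ending landfall (runs
    after it would themselves qualify and take precedence).
    """
    dist = colony_distances(daily, config.colony, geodesy)
    away = dist > config.departure_dist_km
    runs: list[tuple[int, int]] = []  # [start, end) index ranges of away-runs
    i = 0
    n = len(daily)
    while i < n:
        if away[i]:
            j = i
            while j < n and away[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    for start, end in reversed(runs):
        span = (daily[end - 1].date - daily[start].date).days + 1
        if span >= config.min_away_days:
            return daily[start].date
    raise ValueError("no departure detected")


def detect_reversal(
    daily: Sequence[DailyPosition],
    colony: tuple[float, float],
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> dt.date | None:
    """Date of maximum distance from the deployment site (earliest on ties).

    Returns None when the track is still receding at its last fix, i.e. the
    maximum falls in the final three records and the mean distance over those
    records exceeds the mean over the three before them.
    """
    dist = colony_distances(daily, colony, geodesy)
    imax = int(np.argmax(dist))  # argmax returns the first maximal index
    if len(daily) >= 6 and imax >= len(daily) - 3:
        if dist[-3:].mean() > dist[-6:-3].mean():
            return None
    elif imax == len(daily) - 1:
        return None
    return daily[imax].date


def detect_landfall(
    daily: Sequence[DailyPosition],
    reversal_date: dt.date,
    coastline: Coastline,
    config: TripConfig,
) -> dt.date | None:
    """First post-reversal day within coast_buffer_km of the coastline.

    Distances are evaluated in a local azimuthal-equidistant plane centred on
    the colony; near-coast distortion is negligible at this scale.
    """
    if coastline is None:
        raise ValueError("coastline required for landfall detection")
    from shapely.geometry import Point
    from shapely.ops import transform

    proj = AzimuthalEquidistant(*config.colony)

    def fwd(x, y, z=None):
        return proj.forward(np.asarray(x), np.asarray(y))

    coast_km = transform(fwd, coastline.lines)
    for d in daily:
        if d.date <= reversal_date:
            continue
        x, y = proj.forward(d.lon, d.lat)
        if coast_km.distance(Point(float(x), float(y))) < config.coast_buffer_km:
            return d.date
    return None


def classify_destination(
    max_range_position: tuple[float, float], config: TripConfig
) -> str:
    return "SAF" if max_range_position[1] < config.front_boundary_lat else "STF"


def summarize_trip(
    daily: Sequence[DailyPosition],
    config: TripConfig,
    coastline: Coastline | None = None,
    metadata: Mapping[str, object] | None = None,
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> TripSummary:
    """Segment one bird's daily track and compute its trip statistics."""
    meta = dict(metadata or {})
    departure = detect_final_departure(daily, config, geodesy)
    trip_days = [d for d in daily if d.date >= departure]
    reversal = detect_reversal(trip_days, config.colony, geodesy)
    landfall = None
    if reversal is not None and coastline is not None:
        landfall = detect_landfall(trip_days, reversal, coastline, config)
    end_date = landfall if landfall is not None else trip_days[-1].date

    seg = [d for d in trip_days if d.date <= end_date]
    dist = colony_distances(seg, config.colony, geodesy)
    imax = int(np.argmax(dist))
    steps = daily_steps(seg, geodesy) if len(seg) >= 2 else []
    kmday = np.array([s.km_per_day for s in steps])
    destination = None
    if reversal is not None:
        destination = classify_destination((seg[imax].lon, seg[imax].lat), config)
    return TripSummary(
        bird_id=seg[0].bird_id,
        sex=meta.get("sex"),
        body_mass_kg=meta.get("body_mass_kg"),
        departure_date=departure,
        reversal_date=reversal,
        landfall_date=landfall,
        end_date=end_date,
        trip_length_km=float(sum(s.distance_km for s in steps)),
        max_range_km=float(dist.max()),
        destination=destination,
        daily_dist_median_km=float(np.median(kmday)) if len(kmday) else None,
        daily_dist_min_km=float(kmday.min()) if len(kmday) else None,
        daily_dist_max_km=float(kmday.max()) if len(kmday) else None,
    )


def relative_trip_time(
    dates: Sequence[dt.date], departure: dt.date, landfall: dt.date
) -> np.ndarray:
    """Map dates of a complete trip to fractions of trip duration in [0, 1]."""
    if landfall is None or landfall <= departure:
        raise ValueError("relative trip time needs a complete trip")
    total = (landfall - departure).days
    return np.array([(d - departure).days / total for d in dates])


# ---------------------------------------------------------------------------
# cohort statistics


@dataclass
class Stat:
    median: object
    min: object
    max: object
    n: int


@dataclass
class CohortSummary:
    stats: dict[str, Stat] = field(default_factory=dict)


def _median_date(dates: Sequence[dt.date]) -> dt.date:
    origin = min(dates)
    offs = np.array([(d - origin).days for d in dates], float)
    return origin + dt.timedelta(days=float(np.median(offs)))


def _stat(values: Sequence) -> Stat | None:
    vals = [v for v in values if v is not None and not (isinstance(v, float) and np.isnan(v))]
    if not vals:
        return None
    if isinstance(vals[0], dt.date):
        return Stat(_median_date(vals), min(vals), max(vals), len(vals))
    arr = np.asarray(vals, float)
    return Stat(float(np.median(arr)), float(arr.min()), float(arr.max()), len(arr))


def cohort_summary(trips: Sequence[TripSummary]) -> CohortSummary:
    """Medians and ranges per statistic over the subsets where it is defined.

    Undefined subsets yield no entry rather than a zero.
    """
    if not trips:
        raise ValueError("need at least one trip")
    with_rev = [t for t in trips if t.reversal_date is not None]
    complete = [t for t in trips if t.status == "complete"]
    spec = {
        "departure_date": [t.departure_date for t in trips],
        "reversal_date": [t.reversal_date for t in with_rev],
        "outward_days": [t.outward_days for t in with_rev],
        "inbound_days": [t.inbound_days for t in complete],
        "max_range_km": [t.max_range_km for t in with_rev],
        "trip_length_km": [t.trip_length_km for t in complete],
        "duration_days": [t.duration_days for t in complete],
        "daily_dist_median_km": [t.daily_dist_median_km for t in trips],
    }
    out = CohortSummary()
    for name, values in spec.items():
        s = _stat(values)
        if s is not None:
            out.stats[name] = s
    return out


# ---------------------------------------------------------------------------
# packaged worked-example table


def load_table1() -> pd.DataFrame:
    """Published per-bird trip statistics for the 17 tracked birds.

    Used for regression tests and fixture-mode model fits when no raw tracks
    are available.
    """
    with resources.files("premolt.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in ("trip_start", "trip_end", "reversal_date"):
        df[col] = pd.to_datetime(df[col]).dt.date
    return df


def table1_to_trips(df: pd.DataFrame | None = None) -> list[TripSummary]:
    """Re-express the published per-bird table as TripSummary objects."""
    if df is None:
        df = load_table1()
    trips = []
    for r in df.itertuples():
        reversal = r.reversal_date if pd.notna(r.reversal_date) else None
        landfall = r.trip_end if r.status == "complete" else None
        trips.append(
            TripSummary(
                bird_id=r.bird_id,
                sex=r.sex,
                body_mass_kg=float(r.body_mass_kg),
                departure_date=r.trip_start,
                reversal_date=reversal,
                landfall_date=landfall,
                end_date=r.trip_end,
                trip_length_km=float(r.trip_length_km),
                max_range_km=float(r.max_range_km),
                destination=r.destination if isinstance(r.destination, str) else None,
                daily_dist_median_km=float(r.daily_dist_median_km),
                daily_dist_min_km=float(r.daily_dist_min_km),
                daily_dist_max_km=float(r.daily_dist_max_km),
            )
        )
    return trips
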