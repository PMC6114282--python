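"""Daily aggregation of filtered fixes and daily distances/speeds.

Each bird-day (UTC calendar date) is collapsed to a single representative
record: the arithmetic mean of the day's fix times (as epoch seconds) and the
spherical geographic mean of the day's positions.  Consecutive daily records
then yield great-circle step distances and travel speeds.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .argos_io import (
    ArgosFix,
    DEFAULT_GEODESY,
    GeodesyConfig,
    great_circle_km,
)
from .track_filter import FilterResult


@dataclass(frozen=True)
class DailyPosition:
    bird_id: str
    date: dt.date
    mean_time: dt.datetime
    lon: float
    lat: float
    n_fixes: int


@dataclass(frozen=True)
class DailyStep:
    bird_id: str
    from_date: dt.date
    to_date: dt.date
    distance_km: float
    elapsed_h: float

    @property
    def speed_kmh(self) -> float:
        return self.distance_km / self.elapsed_h

    @property
    def km_per_day(self) -> float:
        """Step distance normalised by elapsed calendar days (gap-safe)."""
        return self.distance_km / (self.to_date - self.from_date).days


def mean_epoch_time(timestamps: Sequence[dt.datetime]) -> dt.datetime:
    """Arithmetic mean of epoch seconds, back-converted to UTC datetime."""
    if not timestamps:
        raise ValueError("need at least one timestamp")
    dates = {t.date() for t in timestamps}
    if len(dates) > 1:
        raise ValueError(f"timestamps span multiple UTC dates: {sorted(dates)}")
    epochs = [t.timestamp() for t in timestamps]
    return dt.datetime.fromtimestamp(float(np.mean(epochs)), tz=dt.timezone.utc)


def geographic_mean(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Spherical mean of (lon, lat) points via unit 3-vectors.

    Antimeridian-safe; raises for degenerate sets whose vector resultant is
    (numerically) zero, e.g. pairs of antipodes.
    """
    if not points:
        raise ValueError("need at least one point")
    lon = np.radians([p[0] for p in points])
    lat = np.radians([p[1] for p in points])
    v = np.array(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    ).mean(axis=1)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("degenerate point set: zero resultant vector")
    v /= norm
    out_lat = np.degrees(np.arcsin(np.clip(v[2], -1, 1)))
    out_lon = np.degrees(np.arctan2(v[1], v[0]))
    if out_lon <= -180.0:
        out_lon += 360.0
    return float(out_lon), float(out_lat)


def daily_aggregate(filtered: FilterResult | Sequence[ArgosFix]) -> list[DailyPosition]:
    """Collapse one bird's filtered fixes to one record per UTC date."""
    fixes = filtered.retained if isinstance(filtered, FilterResult) else list(filtered)
    by_day: dict[dt.date, list[ArgosFix]] = {}
    for f in fixes:
        by_day.setdefault(f.timestamp.date(), []).append(f)
    out = []
    for day in sorted(by_day):
        group = by_day[day]
        lon, lat = geographic_mean([(f.lon, f.lat) for f in group])
        out.append(
            DailyPosition(
                bird_id=group[0].bird_id,
                date=day,
                mean_time=mean_epoch_time([f.timestamp for f in group]),
                lon=lon,
                lat=lat,
                n_fixes=len(group),
            )
        )
    return out


def daily_steps(
    daily: Sequence[DailyPosition],
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> list[DailyStep]:
    if len(daily) < 2:
        raise ValueError("need at least two daily positions")
    steps = []
    for a, b in zip(daily, daily[1:]):
        elapsed = (b.mean_time - a.mean_time).total_seconds() / 3600.0
        if elapsed <= 0:
            raise ValueError(f"non-increasing mean_time at {a.date} -> {b.date}")
        steps.append(
            DailyStep(
                bird_id=a.bird_id,
                from_date=a.date,
                to_date=b.date,
                distance_km=great_circle_km((a.lon, a.lat), (b.lon, b.lat), geodesy),
                elapsed_h=elapsed,
            )
        )
    return steps


def daily_to_frame(daily: Iterable[DailyPosition]) -> pd.DataFrame:
    rows = [
        {
            "bird_id": d.bird_id,
            "date": d.date,
            "mean_time": d.mean_time,
            "lon": d.lon,
            "lat": d.lat,
            "n_fixes": d.n_fixes,
        }
        for d in daily
    ]
    return pd.DataFrame(
        rows, columns=["bird_id", "date", "mean_time", "lon", "lat", "n_fixes"]
    )


def frame_to_daily(df: pd.DataFrame) -> list[DailyPosition]:
    out = []
    for r in df.itertuples():
        ts = pd.Timestamp(r.mean_time)
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        out.append(
            DailyPosition(
                bird_id=str(r.bird_id),
                date=pd.Timestamp(r.date).date(),
                mean_time=ts.to_pydatetime(),
                lon=float(r.lon),
                lat=float(r.lat),
                n_fixes=int(r.n_fixes),
            )
        )
    return out
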