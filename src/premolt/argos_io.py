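"""Reading/writing Argos fix tables and shared geodesy conventions.

Coordinates are WGS84 decimal degrees with longitude in (-180, 180] and all
timestamps UTC.  Distances use the spherical law of cosines on a sphere of
radius 6378137 m (the convention of the ``distCosine`` great-circle function
commonly used for Argos track processing), reported in kilometres.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, mapping

LOCATION_CLASSES = frozenset({"3", "2", "1", "0", "A", "B", "Z"})

#: Default column mapping for delimited Argos tables.
DEFAULT_DIALECT: dict[str, str] = {
    "id": "bird_id",
    "time": "timestamp",
    "lon": "lon",
    "lat": "lat",
    "class": "loc_class",
    "sep": ",",
}


@dataclass(frozen=True)
class GeodesyConfig:
    """Spherical-earth convention used for every distance in the package."""

    earth_radius_m: float = 6378137.0

    def __post_init__(self) -> None:
        if self.earth_radius_m <= 0:
            raise ValueError("earth radius must be positive")


DEFAULT_GEODESY = GeodesyConfig()


@dataclass(frozen=True)
class ArgosFix:
    """One raw satellite uplink."""

    bird_id: str
    timestamp: dt.datetime
    lon: float
    lat: float
    loc_class: str

    def __post_init__(self) -> None:
        if not (-180.0 < self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if self.loc_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown Argos location class {self.loc_class!r}")


@dataclass
class Coastline:
    """Mainland coast as one or more WGS84 polylines."""

    lines: MultiLineString

    def __post_init__(self) -> None:
        if self.lines.is_empty:
            raise ValueError("coastline must be non-empty")

    @classmethod
    def from_coords(cls, *polylines: Sequence[tuple[float, float]]) -> "Coastline":
        return cls(MultiLineString([LineString(p) for p in polylines]))


@dataclass
class ParseReport:
    n_parsed: int = 0
    n_dropped_duplicates: int = 0
    errors: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geodesy


def great_circle_km(
    p1: tuple[float, float],
    p2: tuple[float, float],
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> float:
    """Great-circle distance in km between two (lon, lat) points.

    Spherical law of cosines; antipodal pairs return pi*R exactly.  NaN
    coordinates raise rather than propagating silently.
    """
    if any(np.isnan(v) for v in (*p1, *p2)):
        raise ValueError("NaN coordinate passed to great_circle_km")
    lon1, lat1 = np.radians(p1)
    lon2, lat2 = np.radians(p2)
    cosc = np.sin(lat1) * np.sin(lat2) + np.cos(lat1) * np.cos(lat2) * np.cos(
        lon2 - lon1
    )
    return float(np.arccos(np.clip(cosc, -1.0, 1.0)) * geodesy.earth_radius_m / 1000.0)


def great_circle_km_vec(
    lon1: np.ndarray,
    lat1: np.ndarray,
    lon2: np.ndarray,
    lat2: np.ndarray,
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> np.ndarray:
    """Vectorised spherical-law-of-cosines distance in km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    cosc = np.sin(lat1) * np.sin(lat2) + np.cos(lat1) * np.cos(lat2) * np.cos(lon2 - lon1)
    return np.arccos(np.clip(cosc, -1.0, 1.0)) * geodesy.earth_radius_m / 1000.0


def initial_bearing_deg(p_from: tuple[float, float], p_to: tuple[float, float]) -> float:
    """Initial great-circle bearing (degrees clockwise from north)."""
    lon1, lat1 = np.radians(p_from)
    lon2, lat2 = np.radians(p_to)
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection (forward/inverse, km).

    Distances from the projection centre are undistorted, which is why it is
    used for kernel estimation and trip simulation centred on the colony.
    """

    def __init__(self, center_lon: float, center_lat: float,
                 geodesy: GeodesyConfig = DEFAULT_GEODESY) -> None:
        self.center_lon = center_lon
        self.center_lat = center_lat
        self.R_km = geodesy.earth_radius_m / 1000.0
        self._lam0 = np.radians(center_lon)
        self._phi0 = np.radians(center_lat)

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lam = np.radians(np.asarray(lon, float))
        phi = np.radians(np.asarray(lat, float))
        dlam = lam - self._lam0
        cosc = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        c = np.arccos(np.clip(cosc, -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = self.R_km * k * np.cos(phi) * np.sin(dlam)
        y = self.R_km * k * (
            np.cos(self._phi0) * np.sin(phi) - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, float) / self.R_km
        y = np.asarray(y, float) / self.R_km
        rho = np.hypot(x, y)
        c = rho
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        sinc, cosc = np.sin(c), np.cos(c)
        phi = np.arcsin(
            np.clip(cosc * np.sin(self._phi0) + y * sinc * np.cos(self._phi0) / safe_rho, -1, 1)
        )
        lam = self._lam0 + np.arctan2(
            x * sinc, safe_rho * np.cos(self._phi0) * cosc - y * np.sin(self._phi0) * sinc
        )
        phi = np.where(rho > 1e-12, phi, self._phi0)
        lam = np.where(rho > 1e-12, lam, self._lam0)
        lon = (np.degrees(lam) + 180.0) % 360.0 - 180.0
        lon = np.where(lon == -180.0, 180.0, lon)
        return lon, np.degrees(phi)


# ---------------------------------------------------------------------------
# reading


def _parse_time(value) -> dt.datetime:
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC").to_pydatetime()


def read_argos_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[dict[str, list[ArgosFix]], ParseReport]:
    """Read a delimited Argos fix table, grouped by bird.

    Returns fixes sorted by (bird_id, timestamp) with exact-duplicate rows
    dropped, plus a report of per-record errors (unparseable timestamps,
    unknown location classes, out-of-range coordinates) with line numbers.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep=d.get("sep", ","), dtype=str)
    for key in ("id", "time", "lon", "lat", "class"):
        if d[key] not in df.columns:
            raise ValueError(f"column {d[key]!r} (for {key!r}) missing from {path}")

    report = ParseReport()
    n_before = len(df)
    df = df.drop_duplicates()
    report.n_dropped_duplicates = n_before - len(df)

    birds: dict[str, list[ArgosFix]] = {}
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # 1-based, after header
        try:
            fix = ArgosFix(
                bird_id=str(row[d["id"]]),
                timestamp=_parse_time(row[d["time"]]),
                lon=float(row[d["lon"]]),
                lat=float(row[d["lat"]]),
                loc_class=str(row[d["class"]]).strip(),
            )
        except (ValueError, TypeError) as exc:
            report.errors.append(f"line {line_no}: {exc}")
            continue
        birds.setdefault(fix.bird_id, []).append(fix)
        report.n_parsed += 1
    for fixes in birds.values():
        fixes.sort(key=lambda f: f.timestamp)
    return dict(sorted(birds.items())), report


def fixes_to_frame(birds: Mapping[str, Sequence[ArgosFix]]) -> pd.DataFrame:
    rows = [
        {
            "bird_id": f.bird_id,
            "timestamp": f.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "lon": f.lon,
            "lat": f.lat,
            "loc_class": f.loc_class,
        }
        for fixes in birds.values()
        for f in fixes
    ]
    return pd.DataFrame(rows, columns=["bird_id", "timestamp", "lon", "lat", "loc_class"])


def write_argos_table(birds: Mapping[str, Sequence[ArgosFix]], path: str | Path) -> None:
    fixes_to_frame(birds).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# writing results


def write_trip_outputs(trips, kernels: Iterable, out_dir: str | Path) -> dict[str, Path]:
    """Write trip summaries as CSV and kernel isopleths as GeoJSON.

    ``trips`` is an iterable of TripSummary (any object with ``to_row``),
    ``kernels`` an iterable of KernelResult.  Field order is deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rows = [t.to_row() for t in trips]
    columns = [
        "bird_id", "sex", "body_mass_kg", "departure_date", "reversal_date",
        "landfall_date", "end_date", "duration_days", "outward_days",
        "inbound_days", "trip_length_km", "max_range_km", "destination",
        "status", "daily_dist_median_km", "daily_dist_min_km", "daily_dist_max_km",
    ]
    trip_path = out / "trip_summaries.csv"
    pd.DataFrame(rows, columns=columns).to_csv(trip_path, index=False)
    written["trips"] = trip_path

    features = []
    for kr in kernels:
        for q in sorted(kr.isopleths):
            geom = kr.isopleths[q]
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "phase": kr.phase,
                        "quantile_pct": q,
                        "area_km2": kr.areas_km2[q],
                    },
                    "geometry": mapping(geom),
                }
            )
    kern_path = out / "isopleths.geojson"
    kern_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    written["isopleths"] = kern_path
    return written


def write_daily_geojson(daily: pd.DataFrame, path: str | Path) -> None:
    """Daily mean positions as a GeoJSON FeatureCollection of points."""
    features = [
        {
            "type": "Feature",
            "properties": {
                "bird_id": r.bird_id,
                "date": str(r.date),
                "n_fixes": int(r.n_fixes),
            },
            "geometry": {"type": "Point", "coordinates": [r.lon, r.lat]},
        }
        for r in daily.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
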