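"""Synthetic Argos cohorts and environmental stacks with known ground truth.

Tracks are three-phase correlated random walks in a local azimuthal-
equidistant plane around the colony: an outbound leg inside a corridor
around a south-westerly heading, a loiter phase at the destination, and an
inbound leg back to the colony.  Daily true positions are perturbed per fix
with Argos-class-dependent isotropic noise (heavy-tailed: 5% of draws at 5x
scale) and a configurable fraction of fixes is replaced by gross outliers
displaced 50-500 km, mimicking the worst uplinks the SDA filter must catch.

Cohorts mix two destination regimes (near ~1500 km, far ~2200 km) and three
censoring states — complete, inbound-incomplete, outward-incomplete — in the
proportions observed in the study cohort (5:4:8 of 17).

The environment generator emits co-registered layers with controllable
structure: a north-south SST gradient with two front-like steps, patchy
chlorophyll (optionally elevated along one front), Gaussian-eddy sea-level
anomaly whose spatial gradient drives the current-speed layer, a ridge and
seamount chain in the bathymetry, and a smooth mixed-layer-depth field.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import xarray as xr

from .argos_io import ArgosFix, AzimuthalEquidistant, Coastline
from .habitat_kselect import GridSpec, derive_slope, empty_stack

DEFAULT_CLASS_MIX: dict[str, float] = {
    "3": 0.08, "2": 0.10, "1": 0.13, "0": 0.17, "A": 0.25, "B": 0.24, "Z": 0.03,
}
DEFAULT_CLASS_ERROR_SD_M: dict[str, float] = {
    "3": 150.0, "2": 400.0, "1": 1200.0, "0": 3000.0,
    "A": 5000.0, "B": 10000.0, "Z": 20000.0,
}


@dataclass(frozen=True)
class SimConfig:
    n_birds: int = 17
    colony: tuple[float, float] = (168.188, -44.188)
    start_date: dt.date = dt.date(2016, 11, 12)
    start_jitter_days: int = 20
    outbound_heading_deg: float = 230.0
    heading_sd_deg: float = 12.0
    mean_daily_km_range: tuple[float, float] = (40.0, 80.0)
    loiter_days_range: tuple[int, int] = (10, 20)
    loiter_step_km: float = 15.0
    destination_range_km: tuple[float, float] = (1500.0, 2200.0)
    fixes_per_day: tuple[int, int] = (1, 8)
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    class_error_sd_m: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ERROR_SD_M)
    )
    heavy_tail_prob: float = 0.05
    heavy_tail_scale: float = 5.0
    outlier_rate: float = 0.0
    outlier_km_range: tuple[float, float] = (50.0, 500.0)
    pre_departure_trips: int = 2
    censoring_proportions: tuple[int, int, int] = (5, 4, 8)  # complete, inbound-, outward-incomplete
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class mix probabilities sum to {total}, not 1")
        for scale in self.class_error_sd_m.values():
            if scale < 0:
                raise ValueError("error scales must be non-negative")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")


@dataclass
class SimTruth:
    bird_id: str
    daily_dates: list[dt.date]
    daily_lon: np.ndarray
    daily_lat: np.ndarray
    departure_date: dt.date
    reversal_date: dt.date | None
    loiter_window: tuple[dt.date, dt.date] | None
    landfall_date: dt.date | None
    regime: str  # "near" or "far"
    status: str  # complete / inbound_incomplete / outward_incomplete
    outlier_flags: list[bool] = field(default_factory=list)  # parallel to the fixes


@dataclass
class Cohort:
    birds: dict[str, list[ArgosFix]]
    truths: dict[str, SimTruth]
    metadata: dict[str, dict]  # bird_id -> {"sex": ..., "body_mass_kg": ...}


def make_synthetic_coast(
    colony: tuple[float, float], bearing_deg: float = 35.0, half_length_km: float = 600.0
) -> Coastline:
    """Straight synthetic coastline through the colony in lon/lat.

    Oriented NE-SW like the study area's coast, so that the default
    south-westerly outbound heading leads offshore.
    """
    proj = AzimuthalEquidistant(*colony)
    b = np.radians(bearing_deg)
    ts = np.linspace(-half_length_km, half_length_km, 61)
    lon, lat = proj.inverse(ts * np.sin(b), ts * np.cos(b))
    return Coastline.from_coords(list(zip(lon, lat)))


def _bird_rng(seed: int, bird_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, bird_index]))


def _true_path_km(
    config: SimConfig, rng: np.random.Generator, regime: str
) -> tuple[np.ndarray, dict]:
    """Daily true positions in the km plane plus phase bookkeeping."""
    dest_km = config.destination_range_km[0 if regime == "near" else 1]
    dest_km *= rng.uniform(0.92, 1.08)
    mean_step = rng.uniform(*config.mean_daily_km_range)
    loiter_days = int(rng.integers(config.loiter_days_range[0],
                                   config.loiter_days_range[1] + 1))
    pts = [np.zeros(2)]
    phases = ["colony"]

    # pre-departure coastal sorties: 2 days away (> departure threshold),
    # then back to the colony
    for _ in range(config.pre_departure_trips):
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(25.0, 40.0)
        away = np.array([r * np.sin(ang), r * np.cos(ang)])
        pts += [away, away + rng.normal(0, 5, 2)]
        phases += ["sortie", "sortie"]
        # two colony days so sorties never merge with the final departure
        for _ in range(2):
            pts.append(rng.normal(0, 1.5, 2))
            phases.append("colony")

    # outbound correlated walk in a corridor around the outbound heading
    heading = config.outbound_heading_deg
    pos = pts[-1].copy()
    first_out = len(pts)
    while np.hypot(*pos) < dest_km:
        heading = (
            config.outbound_heading_deg
            + 0.6 * (heading - config.outbound_heading_deg)
            + rng.normal(0, config.heading_sd_deg)
        )
        step = max(5.0, rng.normal(mean_step, 0.15 * mean_step))
        rad = np.radians(heading)
        pos = pos + step * np.array([np.sin(rad), np.cos(rad)])
        pts.append(pos.copy())
        phases.append("outbound")
    departure_i = first_out

    # loiter: small-step movement drifting slightly outward so the true
    # maximum range falls inside the loiter window
    loiter_start = len(pts) - 1
    out_dir = pos / np.hypot(*pos)
    for _ in range(loiter_days):
        pos = pos + rng.normal(0, config.loiter_step_km, 2) + 2.0 * out_dir
        pts.append(pos.copy())
        phases.append("loiter")
    loiter_end = len(pts) - 1

    # inbound: straight back towards the colony with directional noise,
    # final approach capped so the track lands at the colony exactly
    while np.hypot(*pos) > 1.0:
        remaining = np.hypot(*pos)
        back = -pos / remaining
        ang = np.arctan2(back[0], back[1]) + np.radians(rng.normal(0, 8))
        step = min(remaining, max(5.0, rng.normal(mean_step, 0.15 * mean_step)))
        pos = pos + step * np.array([np.sin(ang), np.cos(ang)])
        pts.append(pos.copy())
        phases.append("inbound")
    landfall_i = len(pts) - 1
    for _ in range(2):  # hauled out at the colony after landfall
        pts.append(rng.normal(0, 0.5, 2))
        phases.append("ashore")

    return np.array(pts), {
        "departure_i": departure_i,
        "loiter": (loiter_start, loiter_end),
        "landfall_i": landfall_i,
        "mean_step": mean_step,
    }


def simulate_track(
    config: SimConfig, bird_index: int, regime: str = "far", status: str = "complete"
) -> tuple[list[ArgosFix], SimTruth]:
    """Simulate one bird's fixes and the ground truth behind them."""
    rng = _bird_rng(config.seed, bird_index)
    bird_id = f"SB{bird_index:02d}"
    proj = AzimuthalEquidistant(*config.colony)
    path, info = _true_path_km(config, rng, regime)

    start = config.start_date + dt.timedelta(
        days=int(rng.integers(0, config.start_jitter_days + 1))
    )
    dates = [start + dt.timedelta(days=i) for i in range(len(path))]
    departure_date = dates[info["departure_i"]]
    dist = np.hypot(path[:, 0], path[:, 1])
    reversal_i = int(np.argmax(dist))
    reversal_date = dates[reversal_i]
    loiter_window = (dates[info["loiter"][0]], dates[info["loiter"][1]])
    landfall_date = dates[info["landfall_i"]]

    # censoring: truncate the observed track, keep the full truth phases
    n_days = len(path)
    if status == "inbound_incomplete":
        lo, hi = reversal_i + 2, n_days - 3
        n_days = int(rng.integers(lo, max(lo + 1, hi))) if hi > lo else reversal_i + 2
        landfall_date = None
    elif status == "outward_incomplete":
        lo = info["departure_i"] + 3
        hi = max(lo + 1, reversal_i - int(config.loiter_days_range[0]))
        n_days = int(rng.integers(lo, hi))
        reversal_date = None
        loiter_window = None
        landfall_date = None

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    fixes: list[ArgosFix] = []
    outlier_flags: list[bool] = []
    for i in range(n_days):
        n_fix = int(rng.integers(config.fixes_per_day[0], config.fixes_per_day[1] + 1))
        secs = np.sort(rng.uniform(0, 86400, n_fix))
        nxt = path[min(i + 1, len(path) - 1)]
        for s in secs:
            cls = classes[int(rng.choice(len(classes), p=probs))]
            sd_km = config.class_error_sd_m[cls] / 1000.0
            if rng.random() < config.heavy_tail_prob:
                sd_km *= config.heavy_tail_scale
            # the bird holds near the daily anchor through the first half of
            # the day and relocates to the next anchor over the second half,
            # keeping true travel speeds below the filter threshold
            g = max(0.0, 2.0 * s / 86400.0 - 1.0)
            true_xy = path[i] + g * (nxt - path[i])
            xy = true_xy + rng.normal(0, sd_km, 2)
            is_outlier = rng.random() < config.outlier_rate
            if is_outlier:
                r = rng.uniform(*config.outlier_km_range)
                ang = rng.uniform(0, 2 * np.pi)
                xy = true_xy + r * np.array([np.sin(ang), np.cos(ang)])
            lon, lat = proj.inverse(xy[0], xy[1])
            ts = dt.datetime.combine(
                dates[i], dt.time(), tzinfo=dt.timezone.utc
            ) + dt.timedelta(seconds=float(s))
            fixes.append(ArgosFix(bird_id, ts, float(lon), float(lat), cls))
            outlier_flags.append(is_outlier)

    lons, lats = proj.inverse(path[:n_days, 0], path[:n_days, 1])
    truth = SimTruth(
        bird_id=bird_id,
        daily_dates=dates[:n_days],
        daily_lon=np.atleast_1d(lons),
        daily_lat=np.atleast_1d(lats),
        departure_date=departure_date,
        reversal_date=reversal_date,
        loiter_window=loiter_window,
        landfall_date=landfall_date,
        regime=regime,
        status=status,
        outlier_flags=outlier_flags,
    )
    return fixes, truth


def simulate_cohort(config: SimConfig = SimConfig()) -> Cohort:
    """Simulate a cohort with mixed destination regimes and censoring."""
    n = config.n_birds
    nc, ni, no = config.censoring_proportions
    statuses = (
        ["complete"] * nc + ["inbound_incomplete"] * ni + ["outward_incomplete"] * no
    )
    # scale the stated proportions to the requested cohort size
    if len(statuses) != n:
        reps = [round(n * v / (nc + ni + no)) for v in (nc, ni, no)]
        reps[0] += n - sum(reps)
        statuses = (
            ["complete"] * reps[0]
            + ["inbound_incomplete"] * reps[1]
            + ["outward_incomplete"] * reps[2]
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000]))
    birds: dict[str, list[ArgosFix]] = {}
    truths: dict[str, SimTruth] = {}
    metadata: dict[str, dict] = {}
    for i in range(n):
        regime = "near" if i % 2 == 0 else "far"
        fixes, truth = simulate_track(config, i, regime=regime, status=statuses[i])
        birds[truth.bird_id] = fixes
        truths[truth.bird_id] = truth
        metadata[truth.bird_id] = {
            "sex": "male" if rng.random() < 0.6 else "female",
            "body_mass_kg": float(np.round(rng.normal(3.2, 0.35), 2)),
        }
    return Cohort(birds=birds, truths=truths, metadata=metadata)


# ---------------------------------------------------------------------------
# synthetic environmental stacks


def simulate_env(
    grid: GridSpec,
    seed: int = 0,
    coupling: bool = False,
    n_eddies: int = 25,
    eddy_amplitude_m: float = 0.15,
    constant: bool = False,
) -> tuple[xr.Dataset, dict]:
    """Synthetic co-registered environmental stack on the analysis grid.

    Returns the stack and a truth dict holding the front latitudes (grid-y
    positions) and eddy parameters, for use in coupled-preference tests.
    """
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(grid.x_centers, grid.y_centers)
    stack = empty_stack(grid)
    extent_y = grid.cell_km * grid.ny

    if constant:
        for name, value in (
            ("SST", 12.0), ("CHLA", 0.3), ("SLA", 0.0), ("CURR", 0.0),
            ("BATHY", -4000.0), ("SLOPE", 0.0), ("MLD", 60.0),
        ):
            stack[name] = (("y", "x"), np.full_like(gx, value))
        return stack, {"constant": True}

    y0, y1 = grid.y0_km + 0.35 * extent_y, grid.y0_km + 0.65 * extent_y
    width = 0.04 * extent_y
    # north-south gradient plus two front-like steps
    sst = (
        8.0
        + 8.0 * (gy - grid.y0_km) / extent_y
        + 2.0 * np.tanh((gy - y0) / width)
        + 1.5 * np.tanh((gy - y1) / width)
    )
    stack["SST"] = (("y", "x"), sst)

    chla = np.full_like(gx, 0.15)
    blobs = []
    for _ in range(12):
        cx = rng.uniform(gx.min(), gx.max())
        cy = rng.uniform(gy.min(), gy.max())
        amp = rng.uniform(0.2, 0.8)
        s = rng.uniform(100, 250)
        blobs.append((cx, cy, amp, s))
        chla += amp * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * s**2))
    if coupling:
        # productivity ridge along the northern (subtropical) front
        chla += 0.9 * np.exp(-((gy - y1) ** 2) / (2 * (1.5 * width) ** 2))
    stack["CHLA"] = (("y", "x"), chla)

    sla = np.zeros_like(gx)
    eddies = []
    for _ in range(n_eddies):
        cx = rng.uniform(gx.min(), gx.max())
        cy = rng.uniform(gy.min(), gy.max())
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0) * eddy_amplitude_m
        s = rng.uniform(60, 150)
        eddies.append((cx, cy, amp, s))
        sla += amp * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * s**2))
    stack["SLA"] = (("y", "x"), sla)

    # geostrophic-like speed from the SLA gradient magnitude (scaled)
    dy, dx = np.gradient(sla, grid.cell_km)
    stack["CURR"] = (("y", "x"), 500.0 * np.hypot(dx, dy))

    bathy = np.full_like(gx, -4200.0) + 150.0 * np.sin(gx / 900.0) * np.cos(gy / 1100.0)
    # NNE-SSW ridge with a seamount chain on it
    ridge_x = grid.x0_km + 0.45 * grid.cell_km * grid.nx + 0.15 * (gy - grid.y0_km)
    bathy += 2500.0 * np.exp(-((gx - ridge_x) ** 2) / (2 * 120.0**2))
    for k in range(5):
        cy = grid.y0_km + (0.15 + 0.17 * k) * extent_y
        cx = grid.x0_km + 0.45 * grid.cell_km * grid.nx + 0.15 * (cy - grid.y0_km)
        bathy += 1200.0 * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * 70.0**2))
    bathy = np.minimum(bathy, -50.0)
    stack["BATHY"] = (("y", "x"), bathy)
    stack["SLOPE"] = derive_slope(stack["BATHY"], grid.cell_km)

    mld_s = 0.5 * extent_y
    mld = 40.0 + 45.0 * np.exp(
        -((gx - gx.mean()) ** 2 + (gy - gy.mean() - 0.2 * extent_y) ** 2) / (2 * mld_s**2)
    )
    stack["MLD"] = (("y", "x"), mld)

    truth = {"front_y_km": (y0, y1), "eddies": eddies, "chla_blobs": blobs,
             "coupling": coupling}
    return stack, truth


def env_time_series(
    grid: GridSpec, n_days: int, seed: int = 0, **kwargs
) -> list[xr.Dataset]:
    """Daily stacks with small day-to-day perturbations, for compositing."""
    out = []
    for d in range(n_days):
        stack, _ = simulate_env(grid, seed=seed, **kwargs)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 20_000 + d]))
        stack = stack.copy()
        stack["SST"] = stack["SST"] + rng.normal(0, 0.15)
        stack["SLA"] = stack["SLA"] + rng.normal(0, 0.01)
        out.append(stack)
    return out


def noise_free(config: SimConfig) -> SimConfig:
    """A copy of the config with all positional noise and outliers off."""
    return replace(
        config,
        class_error_sd_m={c: 0.0 for c in config.class_error_sd_m},
        heavy_tail_prob=0.0,
        outlier_rate=0.0,
    )
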