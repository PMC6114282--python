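"""Environmental stack construction and K-select habitat-selection analysis.

Environmental layers (bathymetry and its slope, SST, chlorophyll-a, surface
current speed, sea-level anomaly, mixed-layer depth) are composited over the
destination time window and co-registered on one equal-area grid (57.4 km
cells by default, the coarsest native resolution among the source products).

K-select then measures per-animal habitat selection as marginality: the
difference between the mean environmental conditions an animal used at its
trip destination and the mean conditions available to it there, in
standardized variable space.  A weighted non-centred PCA of the marginality
vectors across animals extracts the axes along which selection is shared:
if every animal selected the same conditions, all vectors point the same
way and the first eigenvalue captures (nearly) all marginality.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .argos_io import AzimuthalEquidistant
from .daily_track import DailyPosition
from .trips import TripSummary

ENV_VARS = ("BATHY", "SLOPE", "SST", "CHLA", "CURR", "SLA", "MLD")


@dataclass(frozen=True)
class GridSpec:
    """Equal-area analysis grid in an azimuthal-equidistant km plane."""

    center: tuple[float, float]  # lon, lat of projection centre
    cell_km: float = 57.4
    x0_km: float = -2000.0
    y0_km: float = -2000.0
    nx: int = 70
    ny: int = 70

    def __post_init__(self) -> None:
        if self.cell_km <= 0 or self.nx < 1 or self.ny < 1:
            raise ValueError("invalid grid spec")

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0_km + self.cell_km * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0_km + self.cell_km * (np.arange(self.ny) + 0.5)

    def projection(self) -> AzimuthalEquidistant:
        return AzimuthalEquidistant(*self.center)

    def cell_index(self, x_km: np.ndarray, y_km: np.ndarray) -> np.ndarray:
        """Flat cell index for points in the km plane (-1 if outside)."""
        cx = np.floor((np.asarray(x_km) - self.x0_km) / self.cell_km).astype(int)
        cy = np.floor((np.asarray(y_km) - self.y0_km) / self.cell_km).astype(int)
        ok = (cx >= 0) & (cx < self.nx) & (cy >= 0) & (cy < self.ny)
        return np.where(ok, cy * self.nx + cx, -1)


def empty_stack(grid: GridSpec) -> xr.Dataset:
    return xr.Dataset(
        coords={"y": ("y", grid.y_centers), "x": ("x", grid.x_centers)},
        attrs={
            "cell_km": grid.cell_km,
            "center_lon": grid.center[0],
            "center_lat": grid.center[1],
        },
    )


@dataclass(frozen=True)
class HabitatConfig:
    window_days: int = 10
    availability_radius_km: float = 300.0
    composite_days: int = 32
    sla_composite_days: int = 5
    n_axes: int = 2
    resample_rule: str = "bilinear"

    def __post_init__(self) -> None:
        if min(self.window_days, self.availability_radius_km,
               self.composite_days, self.sla_composite_days, self.n_axes) <= 0:
            raise ValueError("all habitat parameters must be positive")
        if self.resample_rule not in ("bilinear", "nearest"):
            raise ValueError("resample_rule must be 'bilinear' or 'nearest'")


# ---------------------------------------------------------------------------
# layer operations


def composite_layers(layers: Sequence[xr.DataArray]) -> xr.DataArray:
    """Cell-wise arithmetic mean of time-sliced layers, ignoring masked cells."""
    if not layers:
        raise ValueError("empty compositing window")
    stack = xr.concat(list(layers), dim="time")
    return stack.mean(dim="time", skipna=True)


def derive_slope(bathy: xr.DataArray, cell_km: float) -> xr.DataArray:
    """Gradient magnitude of the depth field (Horn's 3x3 operator), m per km.

    Edge cells use replicated borders; interior values match the analytic
    gradient for planar ramps.
    """
    z = np.asarray(bathy, float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("grid too small for slope (need >= 3x3)")
    zp = np.pad(z, 1, mode="edge")
    # Horn weights: p = dz/dx, q = dz/dy over 8 neighbours
    p = (
        (zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8.0 * cell_km)
    q = (
        (zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])
    ) / (8.0 * cell_km)
    slope = np.hypot(p, q)
    return xr.DataArray(slope, coords=bathy.coords, dims=bathy.dims, name="SLOPE")


def current_speed(u: xr.DataArray, v: xr.DataArray) -> xr.DataArray:
    """Cell-wise speed sqrt(u^2 + v^2) of co-registered current components."""
    if u.shape != v.shape or list(u.coords) != list(v.coords):
        raise ValueError("u and v grids do not match")
    return xr.DataArray(np.hypot(np.asarray(u), np.asarray(v)),
                        coords=u.coords, dims=u.dims, name="CURR")


def resample_to_grid(
    layers: Mapping[str, xr.DataArray],
    grid: GridSpec,
    rule: str = "bilinear",
) -> xr.Dataset:
    """Resample native-resolution layers onto the common analysis grid.

    Each input layer must carry 1-D ``x``/``y`` coordinate arrays in the same
    km plane.  NaN masks propagate (bilinear contamination of a masked
    neighbour masks the output cell).
    """
    if rule not in ("bilinear", "nearest"):
        raise ValueError("rule must be 'bilinear' or 'nearest'")
    method = "linear" if rule == "bilinear" else "nearest"
    out = empty_stack(grid)
    gx, gy = np.meshgrid(grid.x_centers, grid.y_centers)
    pts = np.column_stack([gy.ravel(), gx.ravel()])
    for name, layer in layers.items():
        ys = np.asarray(layer["y"]) if "y" in layer.coords else None
        xs = np.asarray(layer["x"]) if "x" in layer.coords else None
        if ys is None or xs is None:
            raise ValueError(f"layer {name!r} lacks x/y coordinates")
        if (gx.min() > xs.max() or gx.max() < xs.min()
                or gy.min() > ys.max() or gy.max() < ys.min()):
            raise ValueError(f"layer {name!r} has no spatial overlap with the grid")
        interp = RegularGridInterpolator(
            (ys, xs), np.asarray(layer, float),
            method=method, bounds_error=False, fill_value=np.nan,
        )
        out[name] = (("y", "x"), interp(pts).reshape(grid.ny, grid.nx))
    return out


# ---------------------------------------------------------------------------
# destination windows and the K-select eigenanalysis


def destination_window_points(
    trip: TripSummary,
    daily: Sequence[DailyPosition],
    config: HabitatConfig = HabitatConfig(),
) -> list[DailyPosition]:
    """Daily positions within +-window_days of the trip reversal date."""
    if trip.reversal_date is None:
        raise ValueError(f"bird {trip.bird_id} has no reversal date")
    w = dt.timedelta(days=config.window_days)
    return [d for d in daily if abs((d.date - trip.reversal_date).days) <= config.window_days]


@dataclass
class KSelectResult:
    variables: list[str]
    eigenvalues: np.ndarray  # non-increasing, >= 0
    loadings: np.ndarray  # (n_vars, n_axes) orthonormal columns
    animals: list[str]
    weights: np.ndarray  # sum to 1
    marginality: np.ndarray  # (n_animals, n_vars), standardized space
    available_scores: np.ndarray  # (n_animals, n_axes) availability centroids
    projections: np.ndarray  # (n_animals, n_axes) marginality on the axes
    n_axes_retained: int

    @property
    def recentred_projections(self) -> np.ndarray:
        """Marginality projections with every availability mean at the origin."""
        return self.projections

    def explained(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues * 0.0


def kselect(
    used: Mapping[str, pd.DataFrame],
    available: Mapping[str, pd.DataFrame],
    weights: Mapping[str, float] | None = None,
    n_axes: int = 2,
) -> KSelectResult:
    """K-select eigenanalysis of per-animal marginality vectors.

    ``used`` and ``available`` map animal id to a table of environmental
    values (one row per used relocation / available cell, one column per
    variable).  Variables are standardized to weighted zero mean and unit
    variance over the pooled availability; per-animal marginality is the
    used-mean minus available-mean in that space; the weighted cross-product
    of marginality vectors is eigen-decomposed (non-centred weighted PCA).
    """
    animals = sorted(used)
    if len(animals) < 2:
        raise ValueError("K-select needs at least 2 animals")
    if set(available) < set(used):
        raise ValueError("every animal needs an availability table")
    variables = list(used[animals[0]].columns)
    for a in animals:
        if list(used[a].columns) != variables or list(available[a].columns) != variables:
            raise ValueError("all tables must share the same variable columns")

    if weights is None:
        w = np.array([len(used[a]) for a in animals], float)
    else:
        w = np.array([weights[a] for a in animals], float)
    w = w / w.sum()

    # availability-weighted standardization: each animal's availability pool
    # contributes with that animal's weight
    pooled = np.concatenate([np.asarray(available[a], float) for a in animals])
    pw = np.concatenate(
        [np.full(len(available[a]), w[i] / len(available[a])) for i, a in enumerate(animals)]
    )
    pw = pw / pw.sum()
    mu = pw @ pooled
    var = pw @ (pooled - mu) ** 2
    tol = 1e-12 * (1.0 + mu**2)  # scale-aware zero test
    if np.any(var <= tol):
        bad = [v for v, s, t in zip(variables, var, tol) if s <= t]
        raise ValueError(f"zero-variance variable(s) over availability: {bad}")
    sd = np.sqrt(var)

    marg = np.empty((len(animals), len(variables)))
    avail_means = np.empty_like(marg)
    for i, a in enumerate(animals):
        u_mean = (np.asarray(used[a], float).mean(axis=0) - mu) / sd
        a_mean = (np.asarray(available[a], float).mean(axis=0) - mu) / sd
        marg[i] = u_mean - a_mean
        avail_means[i] = a_mean

    C = (marg * w[:, None]).T @ marg
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| component positive
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] *= -1

    n_axes = min(n_axes, len(variables))
    return KSelectResult(
        variables=variables,
        eigenvalues=evals,
        loadings=evecs[:, :n_axes],
        animals=animals,
        weights=w,
        marginality=marg,
        available_scores=avail_means @ evecs[:, :n_axes],
        projections=marg @ evecs[:, :n_axes],
        n_axes_retained=n_axes,
    )


def extract_used_available(
    trips: Sequence[TripSummary],
    daily: Mapping[str, Sequence[DailyPosition]],
    stack: xr.Dataset,
    grid: GridSpec,
    config: HabitatConfig = HabitatConfig(),
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Build per-animal used/available environment tables from the stack.

    Used cells: grid cells under the destination-window daily positions, one
    row per position (usage intensity counts multiply).  Available cells: all
    non-masked cells within availability_radius_km of the window centroid.
    """
    proj = grid.projection()
    variables = [v for v in ENV_VARS if v in stack]
    arr = np.stack([np.asarray(stack[v], float) for v in variables], axis=-1)
    gx, gy = np.meshgrid(grid.x_centers, grid.y_centers)
    used: dict[str, pd.DataFrame] = {}
    avail: dict[str, pd.DataFrame] = {}
    for t in trips:
        if t.reversal_date is None:
            continue
        pts = destination_window_points(t, daily[t.bird_id], config)
        if not pts:
            continue
        x, y = proj.forward([p.lon for p in pts], [p.lat for p in pts])
        idx = grid.cell_index(x, y)
        rows = []
        for k in idx:
            if k < 0:
                continue
            vals = arr.reshape(-1, len(variables))[k]
            if not np.any(np.isnan(vals)):
                rows.append(vals)
        if not rows:
            continue
        cx, cy = float(np.mean(x)), float(np.mean(y))
        inside = np.hypot(gx - cx, gy - cy) <= config.availability_radius_km
        cells = arr[inside]
        cells = cells[~np.isnan(cells).any(axis=1)]
        if len(cells) == 0:
            continue
        used[t.bird_id] = pd.DataFrame(rows, columns=variables)
        avail[t.bird_id] = pd.DataFrame(cells, columns=variables)
    return used, avail


def kselect_from_tracks(
    trips: Sequence[TripSummary],
    daily: Mapping[str, Sequence[DailyPosition]],
    stack: xr.Dataset,
    grid: GridSpec,
    config: HabitatConfig = HabitatConfig(),
) -> KSelectResult:
    used, avail = extract_used_available(trips, daily, stack, grid, config)
    return kselect(used, avail, n_axes=config.n_axes)


def randomization_test(
    used: Mapping[str, pd.DataFrame],
    available: Mapping[str, pd.DataFrame],
    n_perm: int = 199,
    seed: int = 0,
) -> dict[str, float]:
    """Optional permutation test of per-animal marginality strength.

    For each animal, the observed squared marginality norm is compared with
    the null distribution obtained by drawing |used| rows at random from the
    animal's availability table.
    """
    rng = np.random.default_rng(seed)
    base = kselect(used, available)
    pvals: dict[str, float] = {}
    for i, a in enumerate(base.animals):
        obs = float(base.marginality[i] @ base.marginality[i])
        av = np.asarray(available[a], float)
        n_used = len(used[a])
        null = []
        for _ in range(n_perm):
            fake = {**used, a: pd.DataFrame(
                av[rng.integers(0, len(av), n_used)], columns=base.variables)}
            r = kselect(fake, available)
            j = r.animals.index(a)
            null.append(float(r.marginality[j] @ r.marginality[j]))
        pvals[a] = (1 + sum(v >= obs for v in null)) / (1 + n_perm)
    return pvals
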