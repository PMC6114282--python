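"""Phase-wise kernel density surfaces and quantile isopleths.

Outward-phase points are the daily positions between departure and trip
reversal of birds for which a reversal was observed; inward-phase points run
from reversal to landfall for birds that reached the coast.  Densities are
bivariate Gaussian kernels on azimuthal-equidistant coordinates centred on
the colony; the q% isopleth is the smallest-area region containing q% of the
density mass (percent-volume contour, the home-range convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde
from shapely.geometry import box
from shapely.ops import unary_union

from .argos_io import AzimuthalEquidistant
from .daily_track import DailyPosition
from .trips import TripSummary


@dataclass(frozen=True)
class KernelConfig:
    quantiles: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)
    bandwidth_rule: str = "reference"  # "reference" (Silverman) or "fixed"
    fixed_bandwidth_km: float | None = None
    grid_cell_km: float = 25.0
    projection_center: tuple[float, float] = (168.188, -44.188)

    def __post_init__(self) -> None:
        q = self.quantiles
        if not all(0 < v < 100 for v in q) or any(b <= a for a, b in zip(q, q[1:])):
            raise ValueError("quantiles must be strictly increasing in (0, 100)")
        if self.bandwidth_rule not in ("reference", "fixed"):
            raise ValueError("bandwidth_rule must be 'reference' or 'fixed'")
        if self.bandwidth_rule == "fixed" and not self.fixed_bandwidth_km:
            raise ValueError("fixed bandwidth requires fixed_bandwidth_km")


@dataclass
class KernelResult:
    phase: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # shape (ny, nx); integrates to ~1 over the grid
    isopleths: dict[float, object] = field(default_factory=dict)  # quantile -> (Multi)Polygon, km coords
    areas_km2: dict[float, float] = field(default_factory=dict)
    mass_within: dict[float, float] = field(default_factory=dict)

    def total_mass(self) -> float:
        cell = (self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0])
        return float(self.density.sum() * cell)


def phase_points(
    trips: Sequence[TripSummary],
    daily: dict[str, Sequence[DailyPosition]],
    phase: str,
) -> list[DailyPosition]:
    """Daily positions belonging to the outward or inward leg across birds.

    Birds without a reversal contribute nothing; the inward set additionally
    requires a landfall.  The reversal day falls in the outward set, the
    landfall day in the inward set.
    """
    if phase not in ("outward", "inward"):
        raise ValueError("phase must be 'outward' or 'inward'")
    pts: list[DailyPosition] = []
    for t in trips:
        if t.reversal_date is None:
            continue
        track = daily.get(t.bird_id, [])
        if phase == "outward":
            pts.extend(
                d for d in track if t.departure_date <= d.date <= t.reversal_date
            )
        else:
            if t.landfall_date is None:
                continue
            pts.extend(
                d for d in track if t.reversal_date < d.date <= t.landfall_date
            )
    return pts


def kde_isopleths(
    points: Sequence[DailyPosition] | np.ndarray,
    config: KernelConfig = KernelConfig(),
    phase: str = "outward",
) -> KernelResult:
    """Gaussian KDE on projected coordinates with percent-volume isopleths.

    The threshold for the q% contour is found by sorting cell masses in
    descending order and accumulating until q% of the total mass is covered;
    the isopleth polygon is the union of the selected cells.
    """
    if isinstance(points, np.ndarray):
        xy = np.asarray(points, float)
    else:
        proj = AzimuthalEquidistant(*config.projection_center)
        lon = np.array([p.lon for p in points])
        lat = np.array([p.lat for p in points])
        x, y = proj.forward(lon, lat)
        xy = np.column_stack([x, y])
    if len(xy) < 10:
        raise ValueError("need at least 10 points for a kernel density")
    if np.allclose(xy.std(axis=0), 0):
        raise ValueError("degenerate point set")

    if config.bandwidth_rule == "fixed":
        # gaussian_kde's factor scales the data covariance; to obtain an
        # isotropic fixed bandwidth we whiten manually.
        h = float(config.fixed_bandwidth_km)
        kde = gaussian_kde(xy.T / h, bw_method=1.0)

        def density_at(gx, gy):
            return kde(np.vstack([gx / h, gy / h])) / h**2
    else:
        kde = gaussian_kde(xy.T, bw_method="silverman")

        def density_at(gx, gy):
            return kde(np.vstack([gx, gy]))

    pad = 4.0 * np.sqrt(np.max(np.linalg.eigvalsh(np.cov(xy.T)))) * (
        len(xy) ** (-1 / 6)
    ) + 3 * config.grid_cell_km
    span = xy.max(axis=0) - xy.min(axis=0)
    pad = max(pad, 0.25 * float(span.max()))
    cell = config.grid_cell_km
    x_edges = np.arange(xy[:, 0].min() - pad, xy[:, 0].max() + pad + cell, cell)
    y_edges = np.arange(xy[:, 1].min() - pad, xy[:, 1].max() + pad + cell, cell)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx, gy = np.meshgrid(xc, yc)
    dens = density_at(gx.ravel(), gy.ravel()).reshape(gy.shape)

    result = KernelResult(phase=phase, x_edges=x_edges, y_edges=y_edges, density=dens)
    cell_mass = dens * cell * cell
    total = cell_mass.sum()
    flat = cell_mass.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order]) / total
    for q in config.quantiles:
        k = int(np.searchsorted(cum, q / 100.0)) + 1
        chosen = order[:k]
        rows, cols = np.unravel_index(chosen, dens.shape)
        cells = [
            box(x_edges[c], y_edges[r], x_edges[c + 1], y_edges[r + 1])
            for r, c in zip(rows, cols)
        ]
        poly = unary_union(cells)
        result.isopleths[q] = poly
        result.areas_km2[q] = float(poly.area)
        result.mass_within[q] = float(cum[k - 1])
    return result


def isopleths_to_lonlat(result: KernelResult, config: KernelConfig) -> dict[float, object]:
    """Back-project isopleth polygons from the km plane to lon/lat."""
    from shapely.ops import transform

    proj = AzimuthalEquidistant(*config.projection_center)

    def inv(x, y, z=None):
        return proj.inverse(np.asarray(x), np.asarray(y))

    return {q: transform(inv, poly) for q, poly in result.isopleths.items()}
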