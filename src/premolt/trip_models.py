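"""Statistical models of trip parameters.

Two model families:

* Linear mixed-effects models ``response ~ destination + sex + (1 | bird)``
  of per-bird trip parameters (reference levels: SAF destination, female).
  With exactly one observation per bird the random-intercept variance is not
  separable from the residual and the fixed-effect estimates coincide with
  ordinary least squares; the fit therefore solves the least-squares problem
  directly and flags the variance decomposition as non-identifiable.
  Standard errors and p-values use the small-sample t convention with
  residual degrees of freedom n - 3.

* A penalized-spline smooth of daily travel rate (km/day) over relative trip
  time in [0, 1] with a per-bird random intercept, the random intercepts
  implemented as ridge-penalized bird offsets and the smoothing parameter
  chosen by generalized cross-validation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .trips import TripSummary

DATE_RESPONSES = {"departure_date", "reversal_date"}
COMPLETE_ONLY_RESPONSES = {"duration", "trip_length"}

_RESPONSE_GETTERS: dict[str, Callable[[TripSummary], object]] = {
    "departure_date": lambda t: t.departure_date,
    "reversal_date": lambda t: t.reversal_date,
    "max_range": lambda t: t.max_range_km,
    "daily_distance_median": lambda t: t.daily_dist_median_km,
    "duration": lambda t: t.duration_days,
    "trip_length": lambda t: t.trip_length_km,
}


@dataclass
class TripModelFit:
    response: str
    coef: pd.DataFrame  # rows: Intercept, Front (STF), Sex (Male)
    n_obs: int
    df_resid: int
    date_origin: dt.date | None = None
    intercept_date: dt.date | None = None
    variance_identifiable: bool = False  # one observation per bird


def _design(trips: Sequence[TripSummary]) -> np.ndarray:
    for t in trips:
        if t.destination not in ("SAF", "STF"):
            raise ValueError(f"bird {t.bird_id}: destination undefined")
        if t.sex not in ("male", "female"):
            raise ValueError(f"bird {t.bird_id}: sex undefined")
    return np.array(
        [[1.0, 1.0 if t.destination == "STF" else 0.0, 1.0 if t.sex == "male" else 0.0]
         for t in trips]
    )


def fit_trip_lmm(
    trips: Sequence[TripSummary],
    response: str,
    date_origin: dt.date | None = None,
) -> TripModelFit:
    """Fit ``response ~ destination + sex + (1 | bird)`` to per-bird values.

    Date responses are converted to day offsets from ``date_origin`` (default
    the earliest date in the subset; the choice cancels in the non-intercept
    effects) and the intercept is back-converted to the nearest day.
    """
    if response not in _RESPONSE_GETTERS:
        raise ValueError(f"unknown response {response!r}")
    getter = _RESPONSE_GETTERS[response]
    subset = [t for t in trips if t.reversal_date is not None]
    if response in COMPLETE_ONLY_RESPONSES:
        subset = [t for t in subset if t.status == "complete"]
    subset = [t for t in subset if getter(t) is not None]
    if not subset:
        raise ValueError(f"no birds with defined {response}")

    X = _design(subset)
    for name, col in (("STF", X[:, 1]), ("SAF", 1 - X[:, 1]),
                      ("male", X[:, 2]), ("female", 1 - X[:, 2])):
        if col.sum() == 0:
            raise ValueError(f"factor level {name!r} absent from the model subset")

    raw = [getter(t) for t in subset]
    origin = None
    if response in DATE_RESPONSES:
        origin = date_origin or min(raw)
        y = np.array([(v - origin).days for v in raw], float)
    else:
        y = np.asarray(raw, float)

    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df if df > 0 else float("nan")
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tval = beta / se
    pval = 2 * stats.t.sf(np.abs(tval), df)

    coef = pd.DataFrame(
        {
            "estimate": beta,
            "std_error": se,
            "df": df,
            "t": tval,
            "p": pval,
        },
        index=["Intercept", "Front (STF)", "Sex (Male)"],
    )
    fit = TripModelFit(
        response=response, coef=coef, n_obs=n, df_resid=df, date_origin=origin
    )
    if origin is not None:
        fit.intercept_date = origin + dt.timedelta(days=round(float(beta[0])))
    return fit


def fit_table2_models(trips: Sequence[TripSummary]) -> dict[str, TripModelFit]:
    """Fit the full set of per-bird trip-parameter models."""
    return {
        r: fit_trip_lmm(trips, r)
        for r in ("departure_date", "max_range", "daily_distance_median",
                  "duration", "trip_length")
    }


# ---------------------------------------------------------------------------
# travel-rate smooth


@dataclass
class TravelRateFit:
    knots: np.ndarray
    spline_coef: np.ndarray
    bird_ids: list[str]
    bird_intercepts: np.ndarray  # centred; weighted sum ~ 0
    lambda_smooth: float
    gcv: float
    fitted: np.ndarray
    se_scale: float
    _basis: object = field(repr=False, default=None)

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Population mean curve (random intercepts at zero) on [0, 1]."""
        t = np.clip(np.asarray(t, float), 0.0, 1.0)
        return self._basis(t) @ self.spline_coef


def _bspline_basis(n_knots: int = 12, degree: int = 3):
    interior = np.linspace(0, 1, n_knots)
    knots = np.concatenate([[0] * degree, interior, [1] * degree])
    n_basis = len(knots) - degree - 1

    def design(t: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, float), 0, 1 - 1e-12)
        return BSpline.design_matrix(t, knots, degree).toarray()

    return design, n_basis, knots


def fit_travel_rate(
    km_per_day: Sequence[float],
    rel_time: Sequence[float],
    bird_ids: Sequence[str],
    n_knots: int = 12,
    ridge_birds: float = 1.0,
) -> TravelRateFit:
    """Penalized cubic-spline smooth of travel rate over relative trip time.

    Minimises ``||y - B c - Z b||^2 + lam * ||D2 c||^2 + tau * ||b||^2`` where
    B is a cubic B-spline basis on [0,1], D2 a second-difference penalty, and
    Z per-bird indicators (ridge-penalized intercepts, i.e. shrunk random
    effects).  ``lam`` is selected by generalized cross-validation on a log
    grid.  Bird offsets are recentred to weighted mean zero afterwards, the
    offset mean being absorbed into the spline intercept.
    """
    y = np.asarray(km_per_day, float)
    t = np.asarray(rel_time, float)
    ids = list(bird_ids)
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    if len({*ids}) < 2:
        raise ValueError("need at least 2 birds")

    design, n_basis, _knots = _bspline_basis(n_knots)
    B = design(t)
    uniq = sorted(set(ids))
    Z = np.zeros((len(y), len(uniq)))
    for j, u in enumerate(uniq):
        Z[:, j] = [1.0 if i == u else 0.0 for i in ids]

    D2 = np.diff(np.eye(n_basis), n=2, axis=0)
    X = np.hstack([B, Z])
    P_base = np.zeros((X.shape[1], X.shape[1]))
    P_base[:n_basis, :n_basis] = D2.T @ D2
    P_ridge = np.zeros_like(P_base)
    P_ridge[n_basis:, n_basis:] = np.eye(len(uniq))

    XtX = X.T @ X
    Xty = X.T @ y
    best = None
    for lam in np.logspace(-4, 4, 25):
        A = XtX + lam * P_base + ridge_birds * P_ridge
        coef = np.linalg.solve(A, Xty)
        H_trace = float(np.trace(np.linalg.solve(A, XtX)))
        resid = y - X @ coef
        rss = float(resid @ resid)
        denom = max(len(y) - H_trace, 1e-8)
        gcv = len(y) * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, H_trace, rss)
    gcv, lam, coef, edf, rss = best

    c = coef[:n_basis].copy()
    b = coef[n_basis:].copy()
    counts = Z.sum(axis=0)
    b_mean = float(np.average(b, weights=counts))
    b -= b_mean
    c += b_mean  # B-spline basis sums to 1, so a constant shifts all coefs

    fitted = B @ c + Z @ b
    sigma2 = rss / max(len(y) - edf, 1.0)
    return TravelRateFit(
        knots=_knots,
        spline_coef=c,
        bird_ids=uniq,
        bird_intercepts=b,
        lambda_smooth=float(lam),
        gcv=float(gcv),
        fitted=fitted,
        se_scale=float(np.sqrt(sigma2)),
        _basis=design,
    )


def travel_rate_inputs(
    trips: Sequence[TripSummary],
    daily: dict[str, Sequence],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (km/day, relative time, bird id) from complete trips."""
    from .daily_track import daily_steps
    from .trips import relative_trip_time

    km, rt, ids = [], [], []
    for tsum in trips:
        if tsum.status != "complete":
            continue
        track = [
            d for d in daily[tsum.bird_id]
            if tsum.departure_date <= d.date <= tsum.landfall_date
        ]
        steps = daily_steps(track)
        mid_dates = [s.to_date for s in steps]
        rel = relative_trip_time(mid_dates, tsum.departure_date, tsum.landfall_date)
        km.extend(s.km_per_day for s in steps)
        rt.extend(rel)
        ids.extend([tsum.bird_id] * len(steps))
    return np.array(km), np.array(rt), ids
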