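"""End-to-end orchestration: simulate -> filter -> aggregate -> trips ->
kernels -> models -> K-select, from one config mapping.

A "fixture mode" bypasses the raw-track stages and feeds the packaged
published per-bird table directly into the model fits and cohort statistics,
for regression reports when no raw Argos tracks are available.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .argos_io import Coastline, write_trip_outputs
from .daily_track import daily_aggregate, daily_to_frame
from .habitat_kselect import GridSpec, HabitatConfig, kselect_from_tracks
from .kernels import KernelConfig, kde_isopleths, phase_points
from .synthetic_data import Cohort, SimConfig, make_synthetic_coast, simulate_cohort, simulate_env
from .track_filter import FilterConfig, filter_cohort
from .trip_models import fit_table2_models, fit_travel_rate, travel_rate_inputs
from .trips import TripConfig, cohort_summary, summarize_trip, table1_to_trips

log = logging.getLogger("premolt")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def fixture_report() -> dict[str, Any]:
    """Refit the trip-parameter models to the packaged published table."""
    trips = table1_to_trips()
    fits = fit_table2_models(trips)
    summ = cohort_summary(trips)
    report: dict[str, Any] = {"mode": "fixture", "models": {}, "cohort": {}}
    for name, fit in fits.items():
        block = fit.coef["estimate"].round(4).to_dict()
        if fit.intercept_date is not None:
            block["intercept_date"] = fit.intercept_date.isoformat()
        report["models"][name] = block
    for name, s in summ.stats.items():
        report["cohort"][name] = {
            "median": s.median, "min": s.min, "max": s.max, "n": s.n,
        }
    return report


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run the configured chain; returns the report also written to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
    }

    if config.get("fixture_mode"):
        report.update(fixture_report())
        (out / "report.json").write_text(
            json.dumps(report, indent=1, default=_json_default)
        )
        return report

    # --- simulate -----------------------------------------------------
    try:
        sim_cfg = SimConfig(seed=seed, **config.get("sim", {}))
        cohort: Cohort = simulate_cohort(sim_cfg)
        coast = make_synthetic_coast(sim_cfg.colony)
        log.info("simulated %d birds", len(cohort.birds))
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    # --- filter + aggregate -------------------------------------------
    try:
        fcfg = FilterConfig(**config.get("filter", {}))
        filtered = filter_cohort(cohort.birds, fcfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", exc) from exc
    try:
        daily = {b: daily_aggregate(r) for b, r in filtered.items()}
        frames = [daily_to_frame(d) for d in daily.values()]
        pd.concat(frames).to_csv(out / "daily.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("aggregate", exc) from exc

    # --- trips ---------------------------------------------------------
    try:
        if "coast" in config and config["coast"] is None:
            raise FileNotFoundError("coastline file missing")
        tcfg = TripConfig(colony=sim_cfg.colony, **config.get("trips", {}))
        trips = []
        for b, d in daily.items():
            try:
                trips.append(
                    summarize_trip(d, tcfg, coastline=coast, metadata=cohort.metadata[b])
                )
            except ValueError as exc:
                log.warning("bird %s skipped: %s", b, exc)
        summ = cohort_summary(trips)
        report["cohort"] = {
            k: {"median": s.median, "min": s.min, "max": s.max, "n": s.n}
            for k, s in summ.stats.items()
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("trips", exc) from exc

    # --- kernels --------------------------------------------------------
    try:
        kcfg = KernelConfig(
            projection_center=sim_cfg.colony, **config.get("kernels", {})
        )
        kernel_results = []
        for phase in ("outward", "inward"):
            pts = phase_points(trips, daily, phase)
            if len(pts) >= 10:
                kernel_results.append(kde_isopleths(pts, kcfg, phase=phase))
        write_trip_outputs(trips, kernel_results, out)
        report["kernels"] = {
            kr.phase: {str(q): kr.areas_km2[q] for q in kr.areas_km2}
            for kr in kernel_results
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("kernels", exc) from exc

    # --- models ---------------------------------------------------------
    try:
        fits = fit_table2_models(trips)
        report["models"] = {
            name: fit.coef["estimate"].round(4).to_dict() for name, fit in fits.items()
        }
        km, rt, ids = travel_rate_inputs(trips, daily)
        if len(km) >= 10 and len(set(ids)) >= 2:
            tr = fit_travel_rate(km, rt, ids)
            grid_t = np.linspace(0, 1, 51)
            pd.DataFrame({"t": grid_t, "fit": tr.predict(grid_t)}).to_csv(
                out / "travel_rate.csv", index=False
            )
            report["travel_rate_lambda"] = tr.lambda_smooth
    except Exception as exc:  # noqa: BLE001
        raise StageError("models", exc) from exc

    # --- K-select -------------------------------------------------------
    try:
        hcfg = HabitatConfig(**config.get("habitat", {}))
        grid = GridSpec(center=sim_cfg.colony, **config.get("grid", {}))
        stack, _ = simulate_env(grid, seed=seed, coupling=True)
        ks = kselect_from_tracks(trips, daily, stack, grid, hcfg)
        report["kselect"] = {
            "eigenvalues": ks.eigenvalues.tolist(),
            "explained": ks.explained().tolist(),
            "variables": ks.variables,
            "loadings_axis1": ks.loadings[:, 0].tolist(),
            "n_animals": len(ks.animals),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("kselect", exc) from exc

    (out / "report.json").write_text(
        json.dumps(report, indent=1, default=_json_default)
    )
    return report
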