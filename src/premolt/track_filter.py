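"""Speed-distance-angle (SDA) filtering of Argos fixes.

Removes implausible uplinks in three stages: (1) drop invalid class-Z fixes;
(2) iteratively remove the fix whose root-mean-square speed against up to two
retained neighbours on each side exceeds the maximum plausible swimming speed
(2.0 m/s for a penguin travelling at sea); (3) remove "spike" fixes forming an
acute turning angle between two long steps — the classic out-and-back
signature of a bad uplink.  Fixes are only ever removed, never relocated, and
track endpoints are always kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .argos_io import (
    ArgosFix,
    DEFAULT_GEODESY,
    GeodesyConfig,
    great_circle_km,
    initial_bearing_deg,
)


@dataclass(frozen=True)
class FilterConfig:
    vmax_ms: float = 2.0
    spike_angles_deg: tuple[float, ...] = (15.0, 25.0)
    spike_dists_m: tuple[float, ...] = (2500.0, 5000.0)
    drop_class_z: bool = True

    def __post_init__(self) -> None:
        if self.vmax_ms <= 0:
            raise ValueError("vmax must be positive")
        if len(self.spike_angles_deg) != len(self.spike_dists_m):
            raise ValueError("spike angle and distance lists must have equal length")
        for seq in (self.spike_angles_deg, self.spike_dists_m):
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError("spike thresholds must be strictly increasing")


@dataclass
class FilterResult:
    retained: list[ArgosFix]
    removed: list[ArgosFix] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)  # parallel to removed

    @property
    def retention_fraction(self) -> float:
        n = len(self.retained) + len(self.removed)
        return len(self.retained) / n if n else float("nan")


def turning_angle(
    prev: tuple[float, float],
    cur: tuple[float, float],
    nxt: tuple[float, float],
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> float:
    """Internal angle in degrees at ``cur`` between bearings to prev and next.

    180 means straight continuation, 0 a full out-and-back reversal.
    Coincident points are treated as straight (180, no spike).
    """
    if (cur == prev) or (cur == nxt):
        return 180.0
    b1 = initial_bearing_deg(cur, prev)
    b2 = initial_bearing_deg(cur, nxt)
    d = abs(b1 - b2) % 360.0
    return min(d, 360.0 - d)


def _speed_ms(f1: ArgosFix, f2: ArgosFix, geodesy: GeodesyConfig) -> float:
    dt_s = abs((f2.timestamp - f1.timestamp).total_seconds())
    dist_m = great_circle_km((f1.lon, f1.lat), (f2.lon, f2.lat), geodesy) * 1000.0
    if dt_s == 0:
        return float("inf") if dist_m > 0 else 0.0
    return dist_m / dt_s


def _rms_speed(fixes: Sequence[ArgosFix], i: int, geodesy: GeodesyConfig) -> float:
    """RMS of segment speeds from fix i to up to 2 neighbours on each side."""
    speeds = [
        _speed_ms(fixes[j], fixes[i], geodesy)
        for j in range(max(0, i - 2), min(len(fixes), i + 3))
        if j != i
    ]
    sq = [s * s for s in speeds]
    return float(np.sqrt(np.mean(sq))) if sq else 0.0


def sda_filter(
    fixes: Sequence[ArgosFix],
    config: FilterConfig = FilterConfig(),
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> FilterResult:
    """Apply the SDA filter to the time-sorted fixes of one bird."""
    fixes = list(fixes)
    if any(
        fixes[i].timestamp > fixes[i + 1].timestamp for i in range(len(fixes) - 1)
    ):
        raise ValueError("fixes must be sorted by timestamp")

    removed: list[ArgosFix] = []
    reasons: list[str] = []

    work = []
    for f in fixes:
        if config.drop_class_z and f.loc_class == "Z":
            removed.append(f)
            reasons.append("class_z")
        else:
            work.append(f)

    # Alternate speed and spike stages to a fixpoint, so the retained set
    # satisfies both criteria on re-scan and the filter is idempotent.
    while len(work) >= 3:
        n_before = len(work)

        # Speed stage: repeatedly drop the worst non-endpoint fix.
        while len(work) >= 3:
            rms = [_rms_speed(work, i, geodesy) for i in range(1, len(work) - 1)]
            worst = float(np.max(rms))
            if worst <= config.vmax_ms:
                break
            # ties broken to the later fix
            i_rel = max(i for i, v in enumerate(rms) if v == worst)
            victim = work.pop(i_rel + 1)
            removed.append(victim)
            reasons.append("speed")

        # Spike stage: acute angle between two long adjacent steps.
        changed = True
        while changed and len(work) >= 3:
            changed = False
            for i in range(1, len(work) - 1):
                prev, cur, nxt = work[i - 1], work[i], work[i + 1]
                ang = turning_angle(
                    (prev.lon, prev.lat), (cur.lon, cur.lat), (nxt.lon, nxt.lat), geodesy
                )
                d1 = great_circle_km((prev.lon, prev.lat), (cur.lon, cur.lat), geodesy) * 1000
                d2 = great_circle_km((cur.lon, cur.lat), (nxt.lon, nxt.lat), geodesy) * 1000
                if any(
                    ang < a and d1 > d and d2 > d
                    for a, d in zip(config.spike_angles_deg, config.spike_dists_m)
                ):
                    removed.append(work.pop(i))
                    reasons.append("spike")
                    changed = True
                    break

        if len(work) == n_before:
            break

    order = {id(f): k for k, f in enumerate(fixes)}
    pairs = sorted(zip(removed, reasons), key=lambda p: order[id(p[0])])
    removed = [p[0] for p in pairs]
    reasons = [p[1] for p in pairs]
    return FilterResult(retained=work, removed=removed, reasons=reasons)


def filter_cohort(
    birds: dict[str, list[ArgosFix]],
    config: FilterConfig = FilterConfig(),
    geodesy: GeodesyConfig = DEFAULT_GEODESY,
) -> dict[str, FilterResult]:
    return {b: sda_filter(f, config, geodesy) for b, f in birds.items()}
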