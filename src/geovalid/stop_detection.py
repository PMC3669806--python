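"""Stay-point (stop) detection with a movement-anomaly screen.

A stop is a maximal episode during which every retained fix lies within a
small radius of the episode's running centroid and the dwell — including
recording gaps bounded by near-identical positions, since the tracker
records only while it detects movement — lasts at least ``min_dwell_s``
seconds (default 10 minutes).

The anomaly screen targets single-fix GPS spikes: implausible speed
(recorded or implied, above ``max_speed_mph``) combined with an abrupt
circular heading change (above ``turn_deg``).  Plausible fast travel on a
steady bearing (highway driving) is deliberately not flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from geovalid.trajectory_io import (
    MPH_PER_MPS,
    Trajectory,
    bearing_deg_vec,
    haversine_m,
    haversine_m_vec,
)

__all__ = ["Stop", "StopConfig", "flag_anomalous_fixes", "detect_stops", "remove_anomalous_stops"]


@dataclass(frozen=True)
class Stop:
    """A detected dwell episode."""

    arrive_t: pd.Timestamp
    depart_t: pd.Timestamp
    centroid: tuple[float, float]
    radius_m: float
    n_fixes: int
    gap_inferred: bool = False
    prev_distance_m: float | None = None
    anomalous: bool = False

    @property
    def duration_s(self) -> float:
        return (self.depart_t - self.arrive_t).total_seconds()

    def __post_init__(self) -> None:
        if self.depart_t <= self.arrive_t:
            raise ValueError("stop must depart after it arrives")


@dataclass
class StopConfig:
    """Tunables for the anomaly screen and the stay-point sweep.

    ``min_dwell_s``: minimum dwell for a stop (600 s = the 10-minute
    definition).  ``eps_m``: stationarity radius — the operationalization
    of "no detectable change in location" under consumer-GPS scatter.
    ``max_speed_mph`` / ``turn_deg``: the anomaly bounds (75 mph spikes in
    apparently random directions).  ``gap_dwell_eps_m``: maximum
    displacement across a recording gap still counted as dwell; defaults
    to ``eps_m``.
    """

    min_dwell_s: float = 600.0
    eps_m: float = 50.0
    max_speed_mph: float = 75.0
    turn_deg: float = 90.0
    gap_dwell_eps_m: float | None = None

    def __post_init__(self) -> None:
        if min(self.min_dwell_s, self.eps_m, self.max_speed_mph, self.turn_deg) <= 0:
            raise ValueError("all StopConfig bounds must be positive")
        if not 0 < self.turn_deg <= 180:
            raise ValueError("turn_deg must lie in (0, 180]")
        if self.gap_dwell_eps_m is None:
            self.gap_dwell_eps_m = self.eps_m


def _circular_diff_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % 360.0
    return np.minimum(d, 360.0 - d)


def flag_anomalous_fixes(traj: Trajectory, cfg: StopConfig) -> np.ndarray:
    """Boolean mask over fixes; True marks a spike to exclude from stops.

    Fix *i* is flagged iff its speed is implausible (recorded speed or the
    speed implied by the displacement from fix *i−1* exceeds
    ``max_speed_mph``) AND its heading swings by more than ``turn_deg``
    relative to fix *i−1* (circular difference; recorded headings are used
    when present, otherwise successive travel bearings).  The first fix is
    never flagged.
    """
    f = traj.fixes
    n = len(f)
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask

    lat = f["lat"].to_numpy(float)
    lon = f["lon"].to_numpy(float)
    dt = np.diff(f["t"].astype("int64").to_numpy()) / 1e9  # seconds
    seg_m = haversine_m_vec(lat[:-1], lon[:-1], lat[1:], lon[1:])
    implied_mph = np.where(dt > 0, seg_m / np.maximum(dt, 1e-12) * MPH_PER_MPS, 0.0)

    recorded = f["speed"].to_numpy(float)
    speed_i = np.where(np.isnan(recorded[1:]), -np.inf, recorded[1:])
    fast = (speed_i > cfg.max_speed_mph) | (implied_mph > cfg.max_speed_mph)

    heading = f["heading"].to_numpy(float)
    travel_bearing = bearing_deg_vec(lat[:-1], lon[:-1], lat[1:], lon[1:])
    # heading attributed to fix i: recorded if present, else bearing of the
    # segment arriving at i
    head_i = np.where(np.isnan(heading[1:]), travel_bearing, heading[1:])
    head_prev = np.empty(n - 1)
    head_prev[0] = head_i[0]  # fix 1 compared with itself -> zero turn
    if n > 2:
        prev_rec = heading[1:-1]
        head_prev[1:] = np.where(np.isnan(prev_rec), travel_bearing[:-1], prev_rec)
    turn = _circular_diff_deg(head_i, head_prev) > cfg.turn_deg

    mask[1:] = fast & turn
    return mask


def detect_stops(traj: Trajectory, cfg: StopConfig, mask: np.ndarray | None = None) -> list[Stop]:
    """Stay-point sweep over unflagged fixes.

    Grows a window while each new fix stays within ``eps_m`` of the
    window's running centroid; a recording gap whose bounding fixes are
    within ``gap_dwell_eps_m`` counts toward dwell (device silence implies
    stationarity).  Emits a maximal window as a :class:`Stop` when its
    dwell reaches ``min_dwell_s`` (boundary inclusive).  A stop whose
    member fixes were majority-flagged inherits ``anomalous=True``.
    """
    f = traj.fixes
    if len(f) == 0:
        raise ValueError("empty trajectory")
    if mask is None:
        mask = flag_anomalous_fixes(traj, cfg)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(f),):
        raise ValueError("anomaly mask must align with the trajectory")

    keep = ~mask
    lat = f["lat"].to_numpy(float)[keep]
    lon = f["lon"].to_numpy(float)[keep]
    t_ns = f["t"].astype("int64").to_numpy()[keep]
    n = len(lat)
    stops: list[Stop] = []
    if n == 0:
        return stops

    # nominal fix cadence: a gap is any inter-fix interval well above it
    gap_threshold_s = 5.0

    def emit(i0: int, i1: int) -> None:
        dwell = (t_ns[i1] - t_ns[i0]) / 1e9
        if dwell < cfg.min_dwell_s:
            return
        clat = float(np.mean(lat[i0 : i1 + 1]))
        clon = float(np.mean(lon[i0 : i1 + 1]))
        radius = float(np.max(haversine_m_vec(lat[i0 : i1 + 1], lon[i0 : i1 + 1], clat, clon)))
        dts = np.diff(t_ns[i0 : i1 + 1]) / 1e9
        stops.append(
            Stop(
                arrive_t=pd.Timestamp(t_ns[i0], unit="ns", tz="UTC"),
                depart_t=pd.Timestamp(t_ns[i1], unit="ns", tz="UTC"),
                centroid=(clat, clon),
                radius_m=radius,
                n_fixes=i1 - i0 + 1,
                gap_inferred=bool(len(dts) and dts.max() > gap_threshold_s),
            )
        )

    start = 0
    sum_lat, sum_lon = lat[0], lon[0]
    for j in range(1, n):
        k = j - start
        clat, clon = sum_lat / k, sum_lon / k
        dt_gap = (t_ns[j] - t_ns[j - 1]) / 1e9
        if dt_gap > gap_threshold_s:
            # recording gap: silence implies stationarity, so the gap counts
            # toward dwell when the resuming fix coincides with any recent
            # pre-gap position (any-of-last-5 is robust to single-fix noise
            # and to travel fixes contaminating the window tail)
            k_tail = min(5, j - start)
            within = any(
                haversine_m((lat[j - m], lon[j - m]), (lat[j], lon[j])) <= cfg.gap_dwell_eps_m
                for m in range(1, k_tail + 1)
            )
        else:
            within = haversine_m((clat, clon), (lat[j], lon[j])) <= cfg.eps_m
        if within:
            sum_lat += lat[j]
            sum_lon += lon[j]
        else:
            emit(start, j - 1)
            start = j
            sum_lat, sum_lon = lat[j], lon[j]
    emit(start, n - 1)

    # a stop is anomalous when the majority of ALL fixes falling in its time
    # span were flagged (only possible when the caller disables exclusion by
    # passing a permissive mask, or when spikes dominate a window)
    all_ns = f["t"].astype("int64").to_numpy()
    annotated = []
    for s in stops:
        in_span = (all_ns >= s.arrive_t.value) & (all_ns <= s.depart_t.value)
        frac = mask[in_span].mean() if in_span.any() else 0.0
        annotated.append(
            Stop(
                arrive_t=s.arrive_t,
                depart_t=s.depart_t,
                centroid=s.centroid,
                radius_m=s.radius_m,
                n_fixes=s.n_fixes,
                gap_inferred=s.gap_inferred,
                anomalous=bool(frac > 0.5),
            )
        )
    return _with_prev_distances(annotated)


def _with_prev_distances(stops: list[Stop]) -> list[Stop]:
    out: list[Stop] = []
    prev: Stop | None = None
    for s in stops:
        d = None if prev is None else haversine_m(prev.centroid, s.centroid)
        out.append(
            Stop(
                arrive_t=s.arrive_t,
                depart_t=s.depart_t,
                centroid=s.centroid,
                radius_m=s.radius_m,
                n_fixes=s.n_fixes,
                gap_inferred=s.gap_inferred,
                prev_distance_m=d,
                anomalous=s.anomalous,
            )
        )
        prev = s
    return out


def remove_anomalous_stops(stops: list[Stop]) -> list[Stop]:
    """Drop stops flagged anomalous; recompute inter-stop distances."""
    return _with_prev_distances([s for s in stops if not s.anomalous])
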