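"""GPS fix-stream ingest, geodesic primitives, and the activity report.

A *fix* is one positional record from a wearable tracker (timestamp,
WGS84 latitude/longitude, and optionally speed, heading and altitude,
nominally recorded at 1 Hz while the device detects movement).  A
*trajectory* is the validated, time-ordered fix stream for one subject.

Distances use the haversine great-circle formula on a sphere of radius
6,371,000 m; the sub-0.5% ellipsoidal error is immaterial at the tens-of-
meters scale of stop detection.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0
MPH_PER_MPS = 2.2369362920544025  # 1 m/s in miles per hour

__all__ = [
    "EARTH_RADIUS_M",
    "GpsFix",
    "Trajectory",
    "ParseLog",
    "haversine_m",
    "bearing_deg",
    "implied_speed_mph",
    "read_fix_table",
    "read_gpx",
    "write_activity_report",
    "read_activity_report",
]


@dataclass(frozen=True)
class GpsFix:
    """One positional record.

    ``t`` is a UTC timestamp (``pd.Timestamp``); ``lat``/``lon`` are WGS84
    decimal degrees; ``speed`` is in mph (``None`` when the device did not
    record it); ``heading`` is degrees clockwise from north in [0, 360);
    ``altitude`` is meters.
    """

    t: pd.Timestamp
    lat: float
    lon: float
    speed: float | None = None
    heading: float | None = None
    altitude: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.speed is not None and self.speed < 0:
            raise ValueError(f"negative speed {self.speed}")


@dataclass
class ParseLog:
    """Audit trail of an ingest: nothing is silently dropped."""

    n_read: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    n_duplicate_ts: int = 0
    n_reordered: int = 0
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class Trajectory:
    """Validated fix stream for one subject.

    ``fixes`` is a DataFrame with columns ``t`` (tz-aware UTC datetime64),
    ``lat``, ``lon``, ``speed``, ``heading``, ``altitude`` (the last three
    may hold NaN), strictly increasing in ``t``.  ``tz`` is the IANA
    timezone used to assign local calendar days downstream.
    """

    subject_id: str
    fixes: pd.DataFrame
    tz: str = "UTC"
    parse_log: ParseLog | None = None

    def __post_init__(self) -> None:
        required = {"t", "lat", "lon"}
        missing = required - set(self.fixes.columns)
        if missing:
            raise ValueError(f"trajectory missing columns {sorted(missing)}")
        if len(self.fixes) == 0:
            raise ValueError("empty trajectory")
        for col in ("speed", "heading", "altitude"):
            if col not in self.fixes.columns:
                self.fixes[col] = np.nan
        t = self.fixes["t"]
        if t.dt.tz is None:
            raise ValueError("timestamps must be timezone-aware (UTC)")
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)


def haversine_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in meters between (lat, lon) points in degrees."""
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def haversine_m_vec(lat1, lon1, lat2, lon2):
    """Vectorized haversine over arrays of degrees; returns meters."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    h = np.sin((lat2 - lat1) / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def bearing_deg(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Initial great-circle bearing from ``a`` to ``b``, degrees in [0, 360)."""
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    dlon = lon2 - lon1
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0


def bearing_deg_vec(lat1, lon1, lat2, lon2):
    """Vectorized initial bearing in degrees [0, 360)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def implied_speed_mph(f1: GpsFix, f2: GpsFix) -> float:
    """Speed implied by the displacement between two fixes, in mph.

    Raises ``ValueError`` unless ``f2.t > f1.t``.
    """
    dt = (f2.t - f1.t).total_seconds()
    if dt <= 0:
        raise ValueError(f"non-positive time delta {dt} s between fixes")
    d = haversine_m((f1.lat, f1.lon), (f2.lat, f2.lon))
    return d / dt * MPH_PER_MPS


def read_fix_table(
    path: str | Path,
    dialect: Mapping[str, object] | None = None,
    subject_id: str = "unknown",
    tz: str = "UTC",
) -> Trajectory:
    """Read a delimited fix export into a validated :class:`Trajectory`.

    ``dialect`` maps logical fields to the export's column names and
    declares the parse settings::

        {"timestamp": "time", "lat": "latitude", "lon": "longitude",
         "speed": "speed", "heading": "direction", "altitude": "altitude",
         "delimiter": ",", "timestamp_format": None, "timestamp_tz": "UTC"}

    Only ``timestamp``/``lat``/``lon`` are mandatory.  Rows with
    unparseable coordinates or timestamps are rejected and counted in the
    parse log, never silently dropped; out-of-order rows are sorted and
    duplicate timestamps collapsed to the first occurrence.
    """
    dialect = dict(dialect or {})
    colmap = {
        "timestamp": dialect.get("timestamp", "timestamp"),
        "lat": dialect.get("lat", "lat"),
        "lon": dialect.get("lon", "lon"),
    }
    optional = {k: dialect[k] for k in ("speed", "heading", "altitude") if dialect.get(k)}
    raw = pd.read_csv(path, delimiter=dialect.get("delimiter", ","), dtype=str, keep_default_na=False)
    for logical, col in colmap.items():
        if col not in raw.columns:
            raise KeyError(f"fix table is missing mandatory column {col!r} (mapped from {logical!r})")

    log = ParseLog(n_read=len(raw))
    ts = pd.to_datetime(
        raw[colmap["timestamp"]],
        format=dialect.get("timestamp_format"),
        errors="coerce",
        utc=False,
    )
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(dialect.get("timestamp_tz", "UTC"))
    ts = ts.dt.tz_convert("UTC")
    lat = pd.to_numeric(raw[colmap["lat"]], errors="coerce")
    lon = pd.to_numeric(raw[colmap["lon"]], errors="coerce")

    bad = ts.isna() | lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    for i in np.flatnonzero(bad.to_numpy()):
        reason = "unparseable timestamp" if pd.isna(ts.iloc[i]) else "invalid coordinate"
        log.rejected_rows.append((int(i), reason))
    log.n_rejected = int(bad.sum())

    df = pd.DataFrame({"t": ts[~bad], "lat": lat[~bad], "lon": lon[~bad]})
    for logical, col in optional.items():
        vals = pd.to_numeric(raw.loc[~bad, col], errors="coerce")
        df[logical if logical != "heading" else "heading"] = vals
    df = df.reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"empty trajectory after parsing {path}")

    if not df["t"].is_monotonic_increasing:
        log.n_reordered = int((df["t"].diff().dt.total_seconds() < 0).sum())
        df = df.sort_values("t", kind="stable").reset_index(drop=True)
    dup = df["t"].duplicated(keep="first")
    log.n_duplicate_ts = int(dup.sum())
    df = df.loc[~dup].reset_index(drop=True)
    log.n_kept = len(df)
    return Trajectory(subject_id=subject_id, fixes=df, tz=tz, parse_log=log)


_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


def read_gpx(path: str | Path, subject_id: str = "unknown", tz: str = "UTC") -> Trajectory:
    """Read GPX 1.1 track points into a :class:`Trajectory`.

    Track-point ``<time>`` is required; ``<ele>`` maps to altitude.  Speed
    is left unset (GPX 1.1 has no core speed element) and downstream code
    falls back to implied speed.  Raises ``ValueError`` on malformed XML or
    an empty track.
    """
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed GPX file {path}: {exc}") from exc
    rows = []
    for trkpt in root.iter(f"{_GPX_NS}trkpt"):
        lat = float(trkpt.attrib["lat"])
        lon = float(trkpt.attrib["lon"])
        t_el = trkpt.find(f"{_GPX_NS}time")
        if t_el is None or not t_el.text:
            continue
        ele = trkpt.find(f"{_GPX_NS}ele")
        rows.append(
            {
                "t": pd.Timestamp(t_el.text),
                "lat": lat,
                "lon": lon,
                "altitude": float(ele.text) if ele is not None and ele.text else np.nan,
            }
        )
    if not rows:
        raise ValueError(f"empty trajectory: no timestamped track points in {path}")
    df = pd.DataFrame(rows)
    if df["t"].dt.tz is None:
        df["t"] = df["t"].dt.tz_localize("UTC")
    else:
        df["t"] = df["t"].dt.tz_convert("UTC")
    df = df.sort_values("t", kind="stable").drop_duplicates(subset="t", keep="first").reset_index(drop=True)
    return Trajectory(subject_id=subject_id, fixes=df, tz=tz)


_REPORT_COLUMNS = [
    "arrive_t",
    "depart_t",
    "duration_s",
    "centroid_lat",
    "centroid_lon",
    "radius_m",
    "n_fixes",
    "gap_inferred",
    "prev_distance_m",
    "anomalous",
]


def write_activity_report(stops, path: str | Path) -> Path:
    """Write the per-stop activity report CSV.

    One row per stop: arrival/departure (ISO-8601 UTC), duration, centroid
    coordinates (the reproducible stand-in for a street address), maximum
    fix distance from the centroid, fix count, gap flag, distance from the
    previous stop's centroid (blank for the first stop), anomaly flag.
    """
    path = Path(path)
    rows = []
    for s in stops:
        rows.append(
            {
                "arrive_t": s.arrive_t.isoformat(),
                "depart_t": s.depart_t.isoformat(),
                "duration_s": round(s.duration_s, 6),
                "centroid_lat": round(s.centroid[0], 6),
                "centroid_lon": round(s.centroid[1], 6),
                "radius_m": round(s.radius_m, 6),
                "n_fixes": s.n_fixes,
                "gap_inferred": s.gap_inferred,
                "prev_distance_m": "" if s.prev_distance_m is None else round(s.prev_distance_m, 6),
                "anomalous": s.anomalous,
            }
        )
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, index=False)
    return path


def read_activity_report(path: str | Path):
    """Read back an activity report written by :func:`write_activity_report`."""
    from geovalid.stop_detection import Stop  # local import to avoid a cycle

    df = pd.read_csv(path)
    stops = []
    for _, r in df.iterrows():
        stops.append(
            Stop(
                arrive_t=pd.Timestamp(r["arrive_t"]),
                depart_t=pd.Timestamp(r["depart_t"]),
                centroid=(float(r["centroid_lat"]), float(r["centroid_lon"])),
                radius_m=float(r["radius_m"]),
                n_fixes=int(r["n_fixes"]),
                gap_inferred=bool(r["gap_inferred"]),
                prev_distance_m=None if pd.isna(r["prev_distance_m"]) else float(r["prev_distance_m"]),
                anomalous=bool(r["anomalous"]),
            )
        )
    return stops
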