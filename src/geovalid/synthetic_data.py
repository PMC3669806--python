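"""Synthetic study generator with retained ground truth.

Emulates every input the validity pipeline consumes, for a cohort design
of 4 full observation days (2 weekdays + 2 weekend days):

* latent Active/Sedentary Lifestyle factors for each subject (standard
  bivariate normal, correlation −0.30 by default);
* true Number-of-Places-Visited counts per subject × period from the
  linear structural model
  ``NPV = intercept + b_AL·AL + b_SL·SL + b_Time·Time + subject effect +
  residual`` (defaults: intercept 11.87 places per 2-day period,
  b_AL 1.79, b_Time −3.68, b_SL 0), allocated binomially across the
  period's two days;
* per-day itineraries (ordered place visits with arrive/depart times)
  realizing those counts, and 1 Hz GPS traces rendered from them with
  configurable positional noise, motion-triggered dropout while dwelling,
  and injected teleport anomalies;
* Diary and Google self-reports = truth plus independent zero-mean
  observation error (with optional binomial-thinning recall error);
* questionnaire indicator totals loaded on the latents and rescaled to
  realistic instrument moments;
* MCAR missingness applied per task, with the 0/1 completion matrix.

The anomaly model is a single-fix multipath spike: a teleported position
implying speed far above the 75 mph screen whose bearing deviates at
least ``anomaly_min_turn_deg`` (default 120°) from the preceding travel
bearing — the "impossible speed in a random direction" signature the
anomaly screen is designed to catch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from geovalid.place_classification import NpvRecord
from geovalid.trajectory_io import Trajectory

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimStudy",
    "simulate_latents",
    "simulate_true_npv",
    "build_itineraries",
    "render_trajectory",
    "simulate_self_reports",
    "simulate_indicators",
    "apply_mcar",
    "simulate_study",
    "INDICATOR_MODEL",
]

#: per-indicator generative model: (factor, loading, mean, sd, lo, hi).
#: Loadings follow the indicator–composite correlations observed for
#: these instruments (≈0.6–0.9); means/SDs are realistic college-sample
#: totals; SWL loads negatively on SL and is reversed at analysis time.
INDICATOR_MODEL: dict[str, tuple[str, float, float, float, float, float]] = {
    "PA": ("AL", 0.77, 36.81, 7.06, 10, 50),
    "MK": ("AL", 0.67, 1.22, 0.70, -3, 3),
    "C": ("AL", 0.74, 7.63, 6.92, -24, 24),
    "E": ("AL", 0.78, 8.34, 6.81, -24, 24),
    "A": ("AL", 0.59, 8.43, 5.98, -24, 24),
    "BDI": ("SL", 0.91, 4.49, 5.18, 0, 63),
    "CESD": ("SL", 0.72, 38.42, 6.43, 0, 60),
    "NA": ("SL", 0.82, 19.86, 6.90, 10, 50),
    "SWL": ("SL", -0.61, 25.38, 5.86, 5, 35),
    "N": ("SL", 0.83, -4.26, 8.29, -24, 24),
}

# default study window: Thu/Fri (weekdays) + Sat/Sun (weekend)
_DEFAULT_CALENDAR = (date(2010, 11, 4), date(2010, 11, 5), date(2010, 11, 6), date(2010, 11, 7))


@dataclass
class SimConfig:
    """All generator knobs, with the study's conditions as defaults."""

    n_subjects: int = 96
    calendar: tuple[date, ...] = _DEFAULT_CALENDAR
    tz: str = "America/Phoenix"

    # structural NPV model (per 2-day period; Time coded −½ weekday, +½ weekend)
    intercept: float = 11.87
    b_AL: float = 1.79
    b_SL: float = 0.0
    b_Time: float = -3.68
    subject_sd: float = 2.5
    residual_sd: float = 1.5
    discretize: bool = True  # round to a count and floor at zero

    # latent factors
    latent_corr: float = -0.30

    # GPS rendering
    fix_rate_hz: float = 1.0
    noise_sd_m: float = 5.0
    dropout_when_stationary: bool = True
    anomaly_rate: float = 0.0
    anomaly_min_turn_deg: float = 120.0
    anomaly_jump_m: float = 3000.0
    place_sep_m: float = 250.0
    n_places: int = 30
    dwell_min_s: float = 1200.0
    dwell_max_s: float = 1800.0
    travel_speed_mph: float = 15.0
    day_start_hour: float = 8.0
    day_end_hour: float = 22.0
    base_lat: float = 32.2
    base_lon: float = -110.9

    # self-report observation model (additive zero-mean by default;
    # binomial-thinning recall error available as sensitivity knobs)
    method_sd_diary: float = 3.0
    method_sd_google: float = 3.0
    method_sd_gps: float = 2.5
    p_recall_diary: float = 1.0
    p_recall_google: float = 1.0
    false_report_rate: float = 0.0

    # MCAR missingness per task
    mcar_rate_npv: float = 0.2
    mcar_rate_indicator: float = 0.12

    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_recall_diary, self.p_recall_google):
            if not 0.0 <= p <= 1.0:
                raise ValueError("recall probabilities must lie in [0, 1]")
        if not 0.0 <= self.anomaly_rate <= 1.0:
            raise ValueError("anomaly_rate must lie in [0, 1]")
        for r in (self.mcar_rate_npv, self.mcar_rate_indicator):
            if not 0.0 <= r < 1.0:
                raise ValueError("MCAR rates must lie in [0, 1)")
        cal = sorted(self.calendar)
        if len(cal) != 4 or sum(d.weekday() >= 5 for d in cal) != 2:
            raise ValueError("calendar must contain exactly 2 weekday and 2 weekend dates")


@dataclass
class GroundTruth:
    """Retained truth for recovery tests."""

    latents: pd.DataFrame  # subject_id, AL, SL
    period_counts: pd.DataFrame  # subject_id, period, true_npv
    day_counts: pd.DataFrame  # subject_id, day, true_npv
    itineraries: dict[str, list[dict]] = field(default_factory=dict)


@dataclass
class SimStudy:
    """One simulated study: all pipeline inputs plus ground truth."""

    config: SimConfig
    truth: GroundTruth
    indicators: pd.DataFrame  # subject_id + indicator columns (MCAR applied)
    npv_records: pd.DataFrame  # subject_id, method, period, npv (MCAR applied)
    completion: pd.DataFrame  # subject × task 0/1
    trajectories: dict[str, Trajectory] = field(default_factory=dict)


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(1, n + 1)]


def simulate_latents(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Standard bivariate normal (AL, SL) with the configured correlation."""
    rho = cfg.latent_corr
    if not abs(rho) < 1:
        raise ValueError("latent correlation must satisfy |rho| < 1")
    cov = np.array([[1.0, rho], [rho, 1.0]])
    draws = rng.multivariate_normal([0.0, 0.0], cov, size=cfg.n_subjects)
    return pd.DataFrame({"subject_id": _subject_ids(cfg.n_subjects), "AL": draws[:, 0], "SL": draws[:, 1]})


def simulate_true_npv(latents: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True NPV per subject × period, plus its allocation across days.

    Period mean = intercept + b_AL·AL + b_SL·SL + b_Time·Time(±½) +
    subject effect; a zero-mean residual is added per period and (by
    default) the result rounded and floored at zero.  Each period's count
    is split across its two calendar days binomially (p=½).
    """
    cal = sorted(cfg.calendar)
    weekdays = [d for d in cal if d.weekday() < 5]
    weekends = [d for d in cal if d.weekday() >= 5]
    u = rng.normal(0.0, cfg.subject_sd, size=len(latents))
    period_rows, day_rows = [], []
    for period, time_code, days in (("weekday", -0.5, weekdays), ("weekend", 0.5, weekends)):
        mu = (
            cfg.intercept
            + cfg.b_AL * latents["AL"].to_numpy()
            + cfg.b_SL * latents["SL"].to_numpy()
            + cfg.b_Time * time_code
            + u
        )
        val = mu + rng.normal(0.0, cfg.residual_sd, size=len(mu))
        if cfg.discretize:
            val = np.maximum(0, np.rint(val)).astype(int)
            day1 = rng.binomial(val, 0.5)
        else:
            day1 = val / 2.0
        day2 = val - day1
        for sid, v, d1, d2 in zip(latents["subject_id"], val, day1, day2):
            period_rows.append({"subject_id": sid, "period": period, "true_npv": v})
            day_rows.append({"subject_id": sid, "day": days[0], "true_npv": d1})
            day_rows.append({"subject_id": sid, "day": days[1], "true_npv": d2})
    return pd.DataFrame(period_rows), pd.DataFrame(day_rows)


def _places(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Place coordinates on a jittered grid with separation ≥ place_sep_m."""
    side = math.ceil(math.sqrt(cfg.n_places))
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * math.cos(math.radians(cfg.base_lat))
    jitter = cfg.place_sep_m * 0.1
    pts = []
    for k in range(cfg.n_places):
        gx, gy = k % side, k // side
        x = gx * cfg.place_sep_m * 1.5 + rng.uniform(-jitter, jitter)
        y = gy * cfg.place_sep_m * 1.5 + rng.uniform(-jitter, jitter)
        pts.append((cfg.base_lat + y / m_per_deg_lat, cfg.base_lon + x / m_per_deg_lon))
    return np.array(pts)


def build_itineraries(
    day_counts: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, list[dict]]:
    """Per-subject itineraries realizing the true day counts.

    Each day schedules ``true_npv`` dwell episodes (duration uniform in
    [dwell_min_s, dwell_max_s], all well above the 10-minute stop
    threshold) at distinct non-consecutive places inside a
    day_start–day_end local window.  The first place of a day always
    differs from the previous day's last place so overnight recording
    gaps never span distinct itinerary entries at one location.
    """
    out: dict[str, list[dict]] = {}
    # reserve enough slot time for the longest possible grid traverse
    travel_reserve_s = 600.0
    max_per_day = int(
        (cfg.day_end_hour - cfg.day_start_hour) * 3600 // (cfg.dwell_min_s + travel_reserve_s)
    )
    for sid, grp in day_counts.groupby("subject_id", sort=True):
        places = _places(cfg, rng)
        entries: list[dict] = []
        prev_place = 0  # overnight anchor: home
        for _, row in grp.sort_values("day").iterrows():
            k = int(min(row["true_npv"], max_per_day))
            if k <= 0:
                continue
            day: date = row["day"]
            window_s = (cfg.day_end_hour - cfg.day_start_hour) * 3600.0
            slot = window_s / k
            t0 = cfg.day_start_hour * 3600.0
            for j in range(k):
                choices = [p for p in range(cfg.n_places) if p != prev_place]
                place = int(rng.choice(choices))
                dwell = rng.uniform(cfg.dwell_min_s, min(cfg.dwell_max_s, slot - travel_reserve_s))
                arrive = t0 + j * slot + rng.uniform(0, max(0.0, slot - dwell - travel_reserve_s))
                entries.append(
                    {
                        "day": day,
                        "place": place,
                        "lat": places[place, 0],
                        "lon": places[place, 1],
                        "arrive_local_s": arrive,
                        "depart_local_s": arrive + dwell,
                    }
                )
                prev_place = place
        out[sid] = entries
    return out


def _local_to_utc_ns(day: date, local_s: float, tz: str) -> int:
    ts = pd.Timestamp(day).tz_localize(tz) + pd.Timedelta(seconds=float(local_s))
    return ts.tz_convert("UTC").value


def render_trajectory(
    itinerary: list[dict], cfg: SimConfig, rng: np.random.Generator, subject_id: str = "unknown"
) -> Trajectory | None:
    """Render a 1 Hz fix stream from an itinerary.

    Travel segments are straight lines at ``travel_speed_mph`` sampled at
    the fix rate with Gaussian positional noise.  While dwelling, the
    motion-triggered device records nothing (``dropout_when_stationary``)
    or jittered fixes at the fix rate.  Teleport anomalies are injected
    between movement fixes at ``anomaly_rate`` per eligible fix.
    Returns ``None`` for an empty itinerary.
    """
    if not itinerary:
        return None
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * math.cos(math.radians(cfg.base_lat))
    speed_mps = cfg.travel_speed_mph * 0.44704
    dt = 1.0 / cfg.fix_rate_hz

    t_ns: list[int] = []
    lat: list[float] = []
    lon: list[float] = []
    speed: list[float] = []

    def emit(ts_ns: int, la: float, lo: float, sp: float) -> None:
        if cfg.noise_sd_m > 0:
            la = la + rng.normal(0, cfg.noise_sd_m) / m_per_deg_lat
            lo = lo + rng.normal(0, cfg.noise_sd_m) / m_per_deg_lon
        t_ns.append(ts_ns)
        lat.append(la)
        lon.append(lo)
        speed.append(sp)

    prev = None  # (day, depart_local_s, lat, lon) of previous dwell
    for e in itinerary:
        if prev is None:
            # lead-in travel from an off-grid origin so the first dwell
            # has a clean arrival
            origin = (e["lat"] + 4 * cfg.place_sep_m / m_per_deg_lat, e["lon"])
            start_day, start_s = e["day"], None
        else:
            origin = (prev[2], prev[3])
            start_day, start_s = prev[0], prev[1]

        dist_m = math.hypot(
            (e["lat"] - origin[0]) * m_per_deg_lat, (e["lon"] - origin[1]) * m_per_deg_lon
        )
        travel_s = max(dist_m / speed_mps, 2 * dt)
        arrive_ns = _local_to_utc_ns(e["day"], e["arrive_local_s"], cfg.tz)
        depart_prev_ns = arrive_ns - int(travel_s * 1e9)
        n_fix = max(int(travel_s / dt), 2)
        for i in range(n_fix + 1):
            frac = i / n_fix
            emit(
                depart_prev_ns + int(frac * travel_s * 1e9),
                origin[0] + frac * (e["lat"] - origin[0]),
                origin[1] + frac * (e["lon"] - origin[1]),
                cfg.travel_speed_mph,
            )
        dwell_start_ns = arrive_ns
        dwell_end_ns = _local_to_utc_ns(e["day"], e["depart_local_s"], cfg.tz)
        if not cfg.dropout_when_stationary:
            k = int((dwell_end_ns - dwell_start_ns) / 1e9 / dt)
            for i in range(1, k + 1):
                emit(dwell_start_ns + int(i * dt * 1e9), e["lat"], e["lon"], 0.0)
        prev = (e["day"], e["depart_local_s"], e["lat"], e["lon"])

    # study-end departure: the device records again once the subject moves
    # on after the final dwell, which closes that dwell's recording window
    end_ns = _local_to_utc_ns(prev[0], prev[1], cfg.tz)
    dest = (prev[2] + 4 * cfg.place_sep_m / m_per_deg_lat, prev[3])
    leave_s = 4 * cfg.place_sep_m / speed_mps
    n_fix = max(int(leave_s / dt), 2)
    for i in range(n_fix + 1):
        frac = i / n_fix
        emit(
            end_ns + int(frac * leave_s * 1e9),
            prev[2] + frac * (dest[0] - prev[2]),
            prev[3] + frac * (dest[1] - prev[3]),
            cfg.travel_speed_mph,
        )

    df = pd.DataFrame(
        {
            "t": pd.to_datetime(np.array(t_ns, dtype="int64"), utc=True),
            "lat": lat,
            "lon": lon,
            "speed": speed,
        }
    )
    df = df.drop_duplicates(subset="t", keep="first").sort_values("t", kind="stable").reset_index(drop=True)

    if cfg.anomaly_rate > 0:
        df = _inject_anomalies(df, cfg, rng, m_per_deg_lat, m_per_deg_lon)
    return Trajectory(subject_id=subject_id, fixes=df, tz=cfg.tz)


def inject_anomalies(traj: Trajectory, cfg: SimConfig, rng: np.random.Generator) -> Trajectory:
    """Inject teleport spikes into an existing trajectory.

    Lets invariance checks compare one rendered trajectory with and
    without spikes, holding everything else fixed.
    """
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = m_per_deg_lat * math.cos(math.radians(cfg.base_lat))
    df = _inject_anomalies(traj.fixes.copy(), cfg, rng, m_per_deg_lat, m_per_deg_lon)
    return Trajectory(subject_id=traj.subject_id, fixes=df, tz=traj.tz)


def _inject_anomalies(df, cfg, rng, m_per_deg_lat, m_per_deg_lon):
    """Insert single-fix teleport spikes between movement fixes."""
    t = df["t"].astype("int64").to_numpy()
    dt_s = np.diff(t) / 1e9
    eligible = np.flatnonzero((dt_s > 0) & (dt_s <= 2.0))
    eligible = eligible[eligible >= 1]  # need a preceding segment for bearing
    pick = eligible[rng.random(len(eligible)) < cfg.anomaly_rate]
    # enforce spacing so spike/return flag pairs never interact
    spaced = []
    last = -10
    for i in pick:
        if i - last >= 3:
            spaced.append(i)
            last = i
    if not spaced:
        return df
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    rows = []
    for i in spaced:
        prev_bearing = math.degrees(
            math.atan2((lon[i] - lon[i - 1]) * m_per_deg_lon, (lat[i] - lat[i - 1]) * m_per_deg_lat)
        )
        turn = rng.uniform(cfg.anomaly_min_turn_deg, 180.0) * rng.choice([-1.0, 1.0])
        theta = math.radians(prev_bearing + turn)
        d = cfg.anomaly_jump_m
        rows.append(
            {
                "t": pd.Timestamp((t[i] + t[i + 1]) // 2, unit="ns", tz="UTC"),
                "lat": lat[i] + d * math.cos(theta) / m_per_deg_lat,
                "lon": lon[i] + d * math.sin(theta) / m_per_deg_lon,
                "speed": np.nan,
            }
        )
    out = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
    out = out.drop_duplicates(subset="t", keep="first").sort_values("t", kind="stable").reset_index(drop=True)
    return out


def simulate_self_reports(
    period_counts: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Diary and Google NPV records from the true period counts.

    Each method observes truth plus independent zero-mean Gaussian error
    (rounded, floored at zero when discretizing).  When a recall
    probability is below 1, each true visit is first recalled
    independently with that probability and spurious reports are added at
    ``false_report_rate`` (Poisson) — the sensitivity model for
    recall-driven convergence loss.
    """
    rows = []
    for method, sd, p_recall in (
        ("Diary", cfg.method_sd_diary, cfg.p_recall_diary),
        ("Google", cfg.method_sd_google, cfg.p_recall_google),
    ):
        for _, r in period_counts.iterrows():
            truth = r["true_npv"]
            if p_recall < 1.0:
                base = rng.binomial(int(round(truth)), p_recall)
            else:
                base = truth
            base = base + rng.poisson(cfg.false_report_rate)
            val = base + rng.normal(0.0, sd) if sd > 0 else float(base)
            if cfg.discretize:
                val = int(max(0, round(val)))
            rows.append({"subject_id": r["subject_id"], "method": method, "period": r["period"], "npv": val})
    return pd.DataFrame(rows)


def simulate_indicators(latents: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Indicator totals: z = λ·latent + √(1−λ²)·noise, rescaled and clipped."""
    out = pd.DataFrame({"subject_id": latents["subject_id"]})
    for name, (factor, lam, mean, sd, lo, hi) in INDICATOR_MODEL.items():
        z = lam * latents[factor].to_numpy() + math.sqrt(1.0 - lam * lam) * rng.normal(size=len(latents))
        out[name] = np.clip(mean + sd * z, lo, hi)
    return out


def apply_mcar(
    indicators: pd.DataFrame, npv_records: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Delete cells independently per task; emit the completion matrix.

    Tasks are the three NPV methods (a missing method drops both of the
    subject's period rows — non-compliance is per task, not per day) and
    each questionnaire scale.
    """
    subjects = list(indicators["subject_id"])
    completion = pd.DataFrame(1, index=pd.Index(subjects, name="subject_id"), columns=[], dtype=int)

    ind = indicators.set_index("subject_id").copy()
    for col in ind.columns:
        drop = rng.random(len(subjects)) < cfg.mcar_rate_indicator
        ind.loc[drop, col] = np.nan
        completion[col] = (~drop).astype(int)

    npv = npv_records.copy()
    keep_mask = np.ones(len(npv), dtype=bool)
    for method in npv["method"].unique():
        drop = rng.random(len(subjects)) < cfg.mcar_rate_npv
        dropped = {s for s, d in zip(subjects, drop) if d}
        keep_mask &= ~(npv["method"].eq(method) & npv["subject_id"].isin(dropped)).to_numpy()
        completion[method] = [0 if s in dropped else 1 for s in subjects]
    return ind.reset_index(), npv[keep_mask].reset_index(drop=True), completion


def simulate_study(
    cfg: SimConfig | None = None,
    seed: int | None = None,
    render_gps: bool = False,
) -> SimStudy:
    """Generate one complete study.

    With ``render_gps=False`` (the fast statistical mode) the GPS record
    is truth plus its own zero-mean observation error; with
    ``render_gps=True`` full 1 Hz trajectories are rendered and retained
    so the detection pipeline can be run end to end.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    latents = simulate_latents(cfg, rng)
    period_counts, day_counts = simulate_true_npv(latents, cfg, rng)
    itineraries: dict[str, list[dict]] = {}
    trajectories: dict[str, Trajectory] = {}

    reports = simulate_self_reports(period_counts, cfg, rng)
    gps_rows = []
    for _, r in period_counts.iterrows():
        val = r["true_npv"] + (rng.normal(0.0, cfg.method_sd_gps) if cfg.method_sd_gps > 0 else 0.0)
        if cfg.discretize:
            val = int(max(0, round(val)))
        gps_rows.append({"subject_id": r["subject_id"], "method": "GPS", "period": r["period"], "npv": val})
    npv_records = pd.concat([reports, pd.DataFrame(gps_rows)], ignore_index=True)

    if render_gps:
        itineraries = build_itineraries(day_counts, cfg, rng)
        for sid, itin in itineraries.items():
            traj = render_trajectory(itin, cfg, rng, subject_id=sid)
            if traj is not None:
                trajectories[sid] = traj

    indicators = simulate_indicators(latents, cfg, rng)
    indicators, npv_records, completion = apply_mcar(indicators, npv_records, cfg, rng)

    # 4-day totals per subject × method where both periods survived MCAR
    wide = npv_records.pivot_table(index=["subject_id", "method"], columns="period", values="npv", aggfunc="first")
    if {"weekday", "weekend"} <= set(wide.columns):
        both = wide.dropna(subset=["weekday", "weekend"])
        totals = pd.DataFrame(
            {
                "subject_id": [i[0] for i in both.index],
                "method": [i[1] for i in both.index],
                "period": "total4day",
                "npv": (both["weekday"] + both["weekend"]).to_numpy(),
            }
        )
        npv_records = pd.concat([npv_records, totals], ignore_index=True)

    truth = GroundTruth(
        latents=latents, period_counts=period_counts, day_counts=day_counts, itineraries=itineraries
    )
    return SimStudy(
        config=cfg,
        truth=truth,
        indicators=indicators,
        npv_records=npv_records,
        completion=completion,
        trajectories=trajectories,
    )
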