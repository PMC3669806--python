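"""End-to-end orchestration: simulate → extract NPV → factors → models.

``run_pipeline`` drives every stage from a single config mapping and a
single seed, writes CSV outputs per stage, and returns a machine-readable
manifest (config hash, seed, per-stage files with row counts and SHA-256
digests) so that a re-run with the same config and seed is verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import date
from pathlib import Path

import pandas as pd

import geovalid
from geovalid.place_classification import ClassifyConfig, NpvRecord, aggregate_npv, classify_stops, count_daily_npv
from geovalid.psychometrics import AL_SPEC, SL_SPEC, standardize_columns, unit_weighted_score
from geovalid.stop_detection import StopConfig, detect_stops, flag_anomalous_fixes, remove_anomalous_stops
from geovalid.synthetic_data import SimConfig, simulate_study
from geovalid.trajectory_io import Trajectory
from geovalid.validity_analysis import (
    build_long_table,
    correlation_panel,
    final_parameter_fit,
    fit_both_orders,
    missingness_screen,
)

__all__ = ["extract_npv", "score_factors", "run_pipeline", "RunManifest"]


def extract_npv(
    traj: Trajectory,
    calendar: list[date],
    stop_cfg: StopConfig | None = None,
    classify_cfg: ClassifyConfig | None = None,
) -> tuple[list[NpvRecord], list]:
    """Full GPS chain for one subject: screen → stops → visits → NPV."""
    stop_cfg = stop_cfg or StopConfig()
    mask = flag_anomalous_fixes(traj, stop_cfg)
    stops = detect_stops(traj, stop_cfg, mask)
    stops = remove_anomalous_stops(stops)
    visits = classify_stops(stops, classify_cfg, tz=traj.tz)
    daily = count_daily_npv(visits)
    records = aggregate_npv(daily, calendar, traj.subject_id, method="GPS")
    return records, visits


def score_factors(indicators: pd.DataFrame, min_present: int = 3) -> pd.DataFrame:
    """Standardize indicators and build the AL and SL composites."""
    ind = indicators.set_index("subject_id") if "subject_id" in indicators.columns else indicators
    cols = [c for c in AL_SPEC.indicators + SL_SPEC.indicators if c in ind.columns]
    z = standardize_columns(ind[cols])
    al_spec = dataclasses.replace(AL_SPEC, min_present=min_present)
    sl_spec = dataclasses.replace(SL_SPEC, min_present=min_present)
    return pd.DataFrame({"AL": unit_weighted_score(z, al_spec), "SL": unit_weighted_score(z, sl_spec)})


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, stage: dict) -> None:
    df.to_csv(path, index=False)
    stage[path.name] = {"rows": int(len(df)), "sha256": _sha256(path)}


def run_pipeline(config: dict | None, out_dir: str | Path, seed: int = 0) -> RunManifest:
    """Run simulate → extract → score → correlate → split-plot → report.

    ``config`` may override any :class:`SimConfig`, :class:`StopConfig`
    or :class:`ClassifyConfig` field under the ``simulate``/``gps``/
    ``classify`` keys, plus ``render_gps`` (default False: the GPS record
    comes from the statistical observation model; True runs the full
    trajectory chain).
    """
    config = config or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config.get("simulate", {}))
    render_gps = bool(config.get("render_gps", sim_kwargs.pop("render_gps", False)))
    if "calendar" in sim_kwargs:
        sim_kwargs["calendar"] = tuple(pd.Timestamp(d).date() for d in sim_kwargs["calendar"])
    cfg = SimConfig(**sim_kwargs, seed=seed)
    stop_cfg = StopConfig(**config.get("gps", {}))
    classify_cfg = ClassifyConfig(**config.get("classify", {}))

    config_hash = hashlib.sha256(
        json.dumps({**config, "seed": seed}, sort_keys=True, default=str).encode()
    ).hexdigest()
    stages: dict[str, dict] = {}

    # --- simulate -----------------------------------------------------
    study = simulate_study(cfg, render_gps=render_gps)
    st: dict = {}
    _write(study.indicators, out / "indicators.csv", st)
    _write(study.truth.latents, out / "ground_truth_latents.csv", st)
    _write(study.truth.period_counts, out / "ground_truth_npv.csv", st)
    _write(study.completion, out / "completion.csv", st)
    stages["simulate"] = st

    npv = study.npv_records
    if render_gps:
        cal = sorted(cfg.calendar)
        gps_rows = []
        for sid, traj in study.trajectories.items():
            records, _ = extract_npv(traj, cal, stop_cfg, classify_cfg)
            gps_rows.extend(dataclasses.asdict(r) for r in records)
        gps_df = pd.DataFrame(gps_rows)
        keep = ~npv["method"].eq("GPS")
        npv = pd.concat([npv[keep], gps_df], ignore_index=True)
    st = {}
    _write(npv, out / "npv_records.csv", st)
    stages["extract_npv"] = st

    # --- factors ------------------------------------------------------
    factors = score_factors(study.indicators).reset_index()
    st = {}
    _write(factors, out / "factor_scores.csv", st)
    stages["score_factors"] = st

    # --- correlation panels -------------------------------------------
    st = {}
    for period in ("total4day", "weekday", "weekend"):
        wide = npv[npv["period"] == period].pivot_table(
            index="subject_id", columns="method", values="npv", aggfunc="first"
        )
        for m in ("Diary", "Google", "GPS"):
            if m not in wide.columns:
                wide[m] = float("nan")
        panel = correlation_panel(wide)
        _write(panel, out / f"correlations_{period}.csv", st)
    stages["correlate"] = st

    # --- split-plot GLMs ----------------------------------------------
    long = build_long_table(npv, factors)
    st = {}
    _write(long, out / "long_table.csv", st)
    res1, res2 = fit_both_orders(long)
    _write(res1.table, out / "anova_al_first.csv", st)
    _write(res2.table, out / "anova_sl_first.csv", st)
    stages["splitplot"] = st

    # --- final parameter model & missingness report -------------------
    st = {}
    fit = final_parameter_fit(long)
    params = pd.DataFrame({"predictor": fit.params.index, "estimate": fit.params.values, "se": fit.bse.values})
    _write(params, out / "parameter_estimates.csv", st)
    screen = missingness_screen(study.completion, study.truth.latents.set_index("subject_id"))
    _write(screen, out / "missingness_report.csv", st)
    stages["report"] = st

    manifest = RunManifest(config_hash=config_hash, seed=seed, version=geovalid.__version__, stages=stages)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
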