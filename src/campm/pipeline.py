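"""End-to-end orchestration: simulate/load -> aggregate -> QC -> fuse -> model.

Stages run in a fixed order; any session failing QC is excluded from every
downstream stage and appears in the run manifest with its reason, so the
manifest conserves sessions (included + excluded = input).  Reruns with the
same config and seed are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import concept_frequency, minutes_to_intervals, photos_to_minutes
from .concepts import ConceptVocabulary, DEFAULT_VOCABULARY
from .config import RunConfig, config_hash, config_to_dict
from .fusion import daily_mean, fuse, fuse_intervals, summarize_by_concept, time_budget
from .models import (ModelSpec, build_design, fit_gamma_repeated,
                     fit_hourly_selfreport)
from .pm_processing import (DeviceTempCorrection, GravimetricFit, IDENTITY_FIT,
                            check_flow_drift, fit_gravimetric, preclean_session,
                            process_session)
from .simulate import StudyData, simulate_study, write_study_csvs

log = logging.getLogger(__name__)

__all__ = ["run", "report", "RunManifest", "RunOutputs", "load_study_csvs"]


@dataclass
class RunManifest:
    """Accounting for one pipeline run: what went in, what survived, why."""

    config_hash: str
    package_version: str
    seed: int
    n_sessions_input: int = 0
    n_sessions_included: int = 0
    n_sessions_excluded: int = 0
    session_verdicts: list[dict] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)
    model_exclusions: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "seed": self.seed,
            "n_sessions_input": self.n_sessions_input,
            "n_sessions_included": self.n_sessions_included,
            "n_sessions_excluded": self.n_sessions_excluded,
            "session_verdicts": self.session_verdicts,
            "stage_counts": self.stage_counts,
            "model_exclusions": self.model_exclusions,
            "notes": self.notes,
        }


@dataclass
class RunOutputs:
    """In-memory results of a pipeline run (also written as CSV/JSON)."""

    study: StudyData | None
    minute_annotations: pd.DataFrame
    interval_annotations: pd.DataFrame
    minute_pm: pd.DataFrame
    qc_reports: list[dict]
    grav_fit: GravimetricFit
    fused_minutes: pd.DataFrame
    fused_intervals: pd.DataFrame
    concept_summary: pd.DataFrame
    time_budget_long: pd.DataFrame
    time_budget_summary: pd.DataFrame
    daily_per_day: pd.DataFrame
    daily_overall: pd.DataFrame
    model_results: pd.DataFrame
    hourly_results: pd.DataFrame
    manifest: RunManifest


def load_study_csvs(indir: str | Path) -> StudyData:
    """Load the four observable CSVs (and truth, if present) from a directory."""
    indir = Path(indir)
    photos = pd.read_csv(indir / "photos.csv", parse_dates=["timestamp"])
    sensor = pd.read_csv(indir / "sensor.csv", parse_dates=["timestamp"])
    sessions = pd.read_csv(indir / "sessions.csv",
                           parse_dates=["session_start", "session_end"])
    diary = pd.read_csv(indir / "diary.csv", parse_dates=["hour_start"])
    diary["activity2"] = diary.get("activity2", pd.Series("", index=diary.index)).fillna("")
    truth = {}
    tm = pd.DataFrame()
    if (indir / "truth.json").exists():
        truth = json.loads((indir / "truth.json").read_text())
    if (indir / "true_minutes.csv").exists():
        tm = pd.read_csv(indir / "true_minutes.csv", parse_dates=["minute"])
    return StudyData(photos=photos, sensor=sensor, sessions=sessions,
                     diary=diary, true_minutes=tm, truth=truth)


def _temp_corrections(config: RunConfig) -> dict[str, DeviceTempCorrection]:
    """Device correction table; for simulated runs the injected slopes are known."""
    art = config.artifacts
    table = {}
    for i in range(config.simulation.n_devices):
        dev = f"D{i + 1}"
        slope = art.temp_slope if dev in art.temp_affected_devices else 0.0
        table[dev] = DeviceTempCorrection(dev, art.temp_threshold, slope, 0.0)
    return table


def run(config: RunConfig, outdir: str | Path | None = None,
        vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
        write: bool = True) -> RunOutputs:
    """Execute the full pipeline and return all stage outputs plus manifest."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    # stage 0: simulate or load ------------------------------------------------
    if config.input_dir:
        study = load_study_csvs(config.input_dir)
    else:
        config.simulation.random_seed = config.seed
        study = simulate_study(config.simulation, config.parameters,
                               config.artifacts, vocabulary)
        if write:
            write_study_csvs(study, outdir)
    sessions = study.sessions
    manifest = RunManifest(config_hash=config_hash(config),
                           package_version=__version__, seed=config.seed,
                           n_sessions_input=len(sessions))
    manifest.stage_counts["photos"] = len(study.photos)
    manifest.stage_counts["sensor_samples"] = len(study.sensor)

    # stage 1: session screening (flow drift, data presence) -------------------
    verdicts: dict[str, dict] = {}
    for _, meta in sessions.iterrows():
        day = meta["participant_day"]
        v = check_flow_drift(meta, tolerance=config.qc.flow_tolerance)
        verdicts[day] = {"participant_day": day, "included": v.keep,
                         "stage": "flow_qc" if not v.keep else "",
                         "reason": v.reason, "flow_drift": v.drift_fraction}
    photo_days = set(study.photos["participant_day"].unique())
    sensor_days = set(study.sensor["participant_day"].unique())
    for day, v in verdicts.items():
        if v["included"] and day not in photo_days:
            v.update(included=False, stage="completeness", reason="no wearable camera data")
        if v["included"] and day not in sensor_days:
            v.update(included=False, stage="completeness", reason="no sensor data")
    kept = [d for d, v in verdicts.items() if v["included"]]

    # stage 2: annotation aggregation ------------------------------------------
    minute_frames, interval_frames = [], []
    for day in kept:
        recs = study.photos.loc[study.photos["participant_day"] == day]
        minutes = photos_to_minutes(recs, config.aggregation, vocabulary)
        minutes.insert(0, "participant_day", day)
        intervals = minutes_to_intervals(minutes, config.aggregation, vocabulary)
        intervals.insert(0, "participant_day", day)
        minute_frames.append(minutes)
        interval_frames.append(intervals)
    minute_ann = pd.concat(minute_frames, ignore_index=True) if minute_frames else pd.DataFrame()
    interval_ann = pd.concat(interval_frames, ignore_index=True) if interval_frames else pd.DataFrame()
    manifest.stage_counts["annotated_minutes"] = len(minute_ann)
    manifest.stage_counts["annotated_intervals"] = len(interval_ann)

    # stage 3: sensor QC -------------------------------------------------------
    corrections = _temp_corrections(config)
    sensor_by_day = dict(tuple(study.sensor.groupby("participant_day")))
    meta_by_day = sessions.set_index("participant_day", drop=False)

    precleaned: dict[str, pd.Series] = {}
    grav_rows = []
    for day in kept:
        raw = sensor_by_day[day].reset_index(drop=True)
        dev = meta_by_day.loc[day, "device_id"]
        corr = corrections.get(dev, DeviceTempCorrection(dev))
        pm, n_out = preclean_session(raw, corr, config.qc)
        precleaned[day] = (raw, pm, n_out, corr)
        ref = meta_by_day.loc[day, "grav_ref"]
        if pd.notna(ref):
            grav_rows.append({"participant_day": day,
                              "neph_mean": float(pm.mean()), "grav_ref": float(ref)})
    if len(grav_rows) >= 2:
        grav_fit = fit_gravimetric(pd.DataFrame(grav_rows))
    else:
        grav_fit = IDENTITY_FIT
        manifest.notes.append("fewer than 2 gravimetric reference sessions; "
                              "nephelometer used uncorrected")

    minute_pm_frames, qc_reports = [], []
    for day in kept:
        raw, _, _, corr = precleaned[day]
        minutes, rep = process_session(raw, meta_by_day.loc[day], corr,
                                       grav_fit, config.qc)
        qc_reports.append(rep.to_dict())
        if not rep.kept:
            verdicts[day].update(included=False, stage="sensor_qc", reason=rep.reason)
            continue
        minute_pm_frames.append(minutes)
    kept = [d for d, v in verdicts.items() if v["included"]]
    minute_pm = (pd.concat(minute_pm_frames, ignore_index=True)
                 if minute_pm_frames else pd.DataFrame())
    manifest.stage_counts["pm_minutes"] = len(minute_pm)

    # stage 4: fusion and descriptives -----------------------------------------
    if kept and not minute_pm.empty and not minute_ann.empty:
        kept_ann = minute_ann[minute_ann["participant_day"].isin(kept)]
        kept_iv = interval_ann[interval_ann["participant_day"].isin(kept)]
        fused_min = fuse(minute_pm, kept_ann, sessions, vocabulary)
        fused_iv = fuse_intervals(minute_pm, kept_iv, sessions,
                                  config.aggregation.interval_min, vocabulary)
        concept_summary = (summarize_by_concept(fused_min, vocabulary)
                           if not fused_min.empty else pd.DataFrame())
        tb_long, tb_summary = time_budget(kept_ann, sessions, vocabulary)
        daily_day, daily_all = daily_mean(minute_pm, sessions)
    else:
        fused_min = fused_iv = concept_summary = pd.DataFrame()
        tb_long = tb_summary = daily_day = daily_all = pd.DataFrame()
        if not kept:
            manifest.notes.append("no session passed QC; downstream stages empty")
    manifest.stage_counts["fused_minutes"] = len(fused_min)
    manifest.stage_counts["fused_intervals"] = len(fused_iv)

    # stage 5: exposure models (per sex) ---------------------------------------
    model_frames = []
    for sex, g in (fused_iv.groupby("sex") if not fused_iv.empty else []):
        days = g["participant_day"].unique()
        photos_sex = study.photos[study.photos["participant_day"].isin(days)]
        counts = concept_frequency(photos_sex, vocabulary)
        try:
            design, excl = build_design(g, counts, config.photo_threshold,
                                        vocabulary=vocabulary)
            predictors = tuple(c for c in design.columns if c in vocabulary.concepts)
            spec = ModelSpec(predictors=predictors, stratum=str(sex))
            res = fit_gamma_repeated(design, spec, exclusions=excl)
            frame = res.summary_frame()
            frame["rho_hat"] = res.rho_hat
            frame["sigma_u_hat"] = res.sigma_u_hat
            frame["exp_alpha"] = res.exp_alpha
            model_frames.append(frame)
            manifest.model_exclusions[str(sex)] = excl
        except (ValueError, RuntimeError) as e:
            manifest.notes.append(f"5-min model for {sex}: not fit ({e})")
    model_results = (pd.concat(model_frames, ignore_index=True)
                     if model_frames else pd.DataFrame())

    # stage 6: hourly self-report model ----------------------------------------
    hourly_frames = []
    if not minute_pm.empty and not study.diary.empty:
        mp = minute_pm.copy()
        mp["hour_start"] = pd.to_datetime(mp["minute"]).dt.floor("h")
        hourly = (mp.groupby(["participant_day", "hour_start"])["pm"]
                  .mean().rename("pm_hourly").reset_index())
        diary = study.diary[study.diary["participant_day"].isin(kept)].copy()
        diary["activity2"] = diary["activity2"].fillna("")
        diary["hour_start"] = pd.to_datetime(diary["hour_start"])
        sex_map = sessions.set_index("participant_day")["sex"]
        diary["sex"] = diary["participant_day"].map(sex_map)
        for sex, g in diary.groupby("sex"):
            try:
                res = fit_hourly_selfreport(g, hourly, stratum=str(sex))
                frame = res.summary_frame()
                frame["exp_alpha"] = res.exp_alpha
                hourly_frames.append(frame)
            except (ValueError, RuntimeError) as e:
                manifest.notes.append(f"hourly model for {sex}: not fit ({e})")
    hourly_results = (pd.concat(hourly_frames, ignore_index=True)
                      if hourly_frames else pd.DataFrame())

    # manifest wrap-up ---------------------------------------------------------
    manifest.session_verdicts = list(verdicts.values())
    manifest.n_sessions_included = sum(v["included"] for v in verdicts.values())
    manifest.n_sessions_excluded = manifest.n_sessions_input - manifest.n_sessions_included

    outputs = RunOutputs(
        study=study, minute_annotations=minute_ann, interval_annotations=interval_ann,
        minute_pm=minute_pm, qc_reports=qc_reports, grav_fit=grav_fit,
        fused_minutes=fused_min, fused_intervals=fused_iv,
        concept_summary=concept_summary, time_budget_long=tb_long,
        time_budget_summary=tb_summary, daily_per_day=daily_day,
        daily_overall=daily_all, model_results=model_results,
        hourly_results=hourly_results, manifest=manifest,
    )
    if write:
        _write_outputs(outputs, outdir, config)
    return outputs


def _write_outputs(out: RunOutputs, outdir: Path, config: RunConfig) -> None:
    for name, df in [
        ("minute_annotations", out.minute_annotations),
        ("interval_annotations", out.interval_annotations),
        ("minute_pm", out.minute_pm),
        ("fused_minutes", out.fused_minutes),
        ("fused_intervals", out.fused_intervals),
        ("concept_summary", out.concept_summary),
        ("time_budget", out.time_budget_long),
        ("time_budget_summary", out.time_budget_summary),
        ("daily_means_per_day", out.daily_per_day),
        ("daily_means", out.daily_overall),
        ("model_results", out.model_results),
        ("hourly_model_results", out.hourly_results),
    ]:
        df.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "qc_reports.json", "w") as fh:
        json.dump(out.qc_reports, fh, indent=1, default=str)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(out.manifest.to_dict(), fh, indent=1, default=str)
    with open(outdir / "config.json", "w") as fh:
        json.dump(config_to_dict(config), fh, indent=1, default=str)
    (outdir / "report.md").write_text(report(out))


def report(out: RunOutputs) -> str:
    """Human-readable run summary; every number repeats a stage output."""
    m = out.manifest
    lines = [
        "# Pipeline run report",
        "",
        f"- config hash: `{m.config_hash}`  (campm {m.package_version}, seed {m.seed})",
        f"- sessions: {m.n_sessions_input} input, {m.n_sessions_included} included, "
        f"{m.n_sessions_excluded} excluded "
        f"({100 * m.n_sessions_excluded / max(m.n_sessions_input, 1):.0f}%)",
        "",
        "## Session exclusions",
    ]
    excluded = [v for v in m.session_verdicts if not v["included"]]
    if excluded:
        for v in excluded:
            lines.append(f"- {v['participant_day']}: {v['stage']} — {v['reason']}")
    else:
        lines.append("- none")
    lines += ["", "## Stage row counts"]
    for k, v in m.stage_counts.items():
        lines.append(f"- {k}: {v}")
    lines += ["", "## Daily mean PM2.5 (ug/m3) by sex"]
    if not out.daily_overall.empty:
        for _, r in out.daily_overall.iterrows():
            lines.append(f"- {r['sex']}: {r['mean']:.1f} (sd {r['sd']:.1f}, "
                         f"{int(r['n_days'])} participant-days)")
    lines += ["", "## Per-concept exposure (top rows)"]
    if not out.concept_summary.empty:
        top = out.concept_summary.sort_values("mean", ascending=False).head(10)
        for _, r in top.iterrows():
            lines.append(
                f"- {r['concept']} ({r['sex']}): mean {r['mean']:.0f} "
                f"(sd {r['sd']:.0f}), median {r['median']:.0f}, "
                f"{int(r['total_minutes'])} min")
    lines += ["", "## 5-min exposure model (percent change, 95% CI)"]
    if out.model_results.empty:
        lines.append("- no model fit (all concepts excluded or too little data)")
    else:
        for _, r in out.model_results.iterrows():
            lines.append(
                f"- {r['stratum']} / {r['term']}: {r['percent_change']:+.0f}% "
                f"({r['ci_low']:.0f}%, {r['ci_high']:.0f}%)")
    if m.notes:
        lines += ["", "## Notes"] + [f"- {n}" for n in m.notes]
    return "\n".join(lines) + "\n"
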