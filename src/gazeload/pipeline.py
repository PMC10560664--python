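"""End-to-end orchestration: simulate -> QC -> metrics -> dispersion ->
stats -> features -> classification, plus the reference-summary
arithmetic-consistency stage."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import aoi as aoi_mod
from . import dispersion as disp_mod
from . import features as feat_mod
from . import stats as stats_mod
from .aoi import AOISet, default_aoi_set
from .core import (
    GazeRecording,
    TrialSchedule,
    qc_gaze_capture,
    read_gaze_table,
    segment_trials,
    write_gaze_table,
)
from .network import ClassifierConfig
from .synthetic import Cohort, CohortConfig, simulate_cohort

log = logging.getLogger("gazeload")


def load_reference_summary() -> dict:
    """Bundled reference mean/SD cells for the three gaze metrics."""
    with resources.files("gazeload.data").joinpath("reference_summary.json").open() as fh:
        return json.load(fh)


def reference_summary_frame(ref: dict | None = None) -> pd.DataFrame:
    """Reference cells as the same tidy frame condition_summary produces."""
    ref = load_reference_summary() if ref is None else ref
    rows = []
    for metric, groups in ref["cells"].items():
        for group, conds in groups.items():
            for cond, (mean, sd) in conds.items():
                rows.append(
                    {"group": group, "condition": cond, "metric": metric,
                     "mean": mean, "sd": sd, "n": np.nan}
                )
    return pd.DataFrame(rows)


def effects_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Pooled means and load effects for every metric x group in *summary*."""
    rows = []
    for metric in summary["metric"].unique():
        for group in summary[summary["metric"] == metric]["group"].unique():
            e = stats_mod.load_effect(summary, metric, group)
            rows.append(
                {
                    "metric": e.metric,
                    "group": e.group,
                    "no_load_mean": e.no_load_mean,
                    "high_load_mean": e.high_load_mean,
                    "absolute_change": e.absolute_change,
                    "percent_change": e.percent_change,
                    "pooled_mean": e.pooled_mean,
                }
            )
    return pd.DataFrame(rows)


def replicate_table_arithmetic(values_path=None) -> pd.DataFrame:
    """Arithmetic-consistency stage: pooled means and load deltas recomputed
    from the reference summary cells (or a user-supplied file in the same
    JSON layout)."""
    if values_path is None:
        ref = load_reference_summary()
    else:
        with open(values_path, encoding="utf-8") as fh:
            ref = json.load(fh)
    return effects_table(reference_summary_frame(ref))


def compute_cohort_metrics(
    recordings,
    aoi_set: AOISet,
    schedule: TrialSchedule,
    with_dispersion: bool = True,
    qc_threshold: float = 0.25,
):
    """QC + per-trial metrics (incl. fixation distribution) for a cohort.

    Returns ``(metrics, qc_reports)``; excluded participants contribute QC
    rows but no metric rows.
    """
    frames = []
    qc_reports = []
    for rec in recordings:
        qc = qc_gaze_capture(rec, threshold=qc_threshold)
        qc_reports.append(qc)
        if qc.excluded:
            log.info("participant %s excluded (gaze capture %.1f%%)",
                     rec.participant_id, 100 * qc.gaze_capture_fraction)
            continue
        m = aoi_mod.compute_trial_metrics(rec, aoi_set, schedule)
        if with_dispersion:
            m = disp_mod.add_fixation_distribution(m, rec, schedule)
        frames.append(m)
    metrics = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return metrics, qc_reports


@dataclass
class PipelineConfig:
    out_dir: str = "gazeload_out"
    gaze_csv: str | None = None  # None -> simulate
    aoi_file: str | None = None
    schedule_file: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    run_classifier: bool = True
    cv_folds: int = 10


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aoi_set = (
        AOISet.from_json(config.aoi_file) if config.aoi_file else default_aoi_set()
    )
    if config.schedule_file:
        with open(config.schedule_file, encoding="utf-8") as fh:
            schedule = TrialSchedule.from_dict(json.load(fh))
    else:
        schedule = TrialSchedule()

    quiz = None
    if config.gaze_csv:
        recordings = [
            segment_trials(r, schedule) for r in read_gaze_table(config.gaze_csv)
        ]
        log.info("loaded %d recordings from %s", len(recordings), config.gaze_csv)
    else:
        cohort_cfg = config.cohort
        if cohort_cfg.seed != config.seed:
            cohort_cfg = CohortConfig(**{**cohort_cfg.__dict__, "seed": config.seed})
        cohort = simulate_cohort(cohort_cfg, schedule, aoi_set)
        recordings, quiz = cohort.recordings, cohort.quiz
        write_gaze_table(recordings, out / "gaze.csv")
        _write_csv(cohort.roster, out / "roster.csv")
        _write_csv(quiz, out / "quiz.csv")
        log.info("simulated cohort of %d participants", len(recordings))

    metrics, qc_reports = compute_cohort_metrics(recordings, aoi_set, schedule)
    qc_df = pd.DataFrame(
        [
            {
                "participant_id": q.participant_id,
                "gaze_capture_fraction": q.gaze_capture_fraction,
                "excluded": q.excluded,
            }
            for q in qc_reports
        ]
    )
    _write_csv(qc_df, out / "qc.csv")
    _write_csv(metrics, out / "metrics.csv")

    summary = stats_mod.condition_summary(metrics)
    _write_csv(summary, out / "summary.csv")
    _write_csv(effects_table(summary), out / "effects.csv")

    model_report = {}
    for metric in ("aoi_sample_pct", "aoi_fixation_duration_s", "fixation_distribution"):
        try:
            res = stats_mod.fit_mixed_model(metrics, metric)
            model_report[metric] = [
                {
                    "effect": e.effect,
                    "F": e.f_stat,
                    "df": [e.df_num, e.df_den],
                    "p": e.p_value,
                }
                for e in res.effects
            ]
        except Exception as exc:  # singular fits on tiny inputs
            warnings.warn(f"mixed model for {metric} failed: {exc}", stacklevel=2)
            model_report[metric] = {"error": str(exc)}
    (out / "model_report.json").write_text(json.dumps(model_report, indent=2))

    if quiz is not None:
        acc = stats_mod.quiz_accuracy(quiz)
        acc.rename("accuracy_pct").to_frame().reset_index().to_csv(
            out / "quiz_accuracy.csv", index=False, float_format="%.9g"
        )

    features = feat_mod.build_feature_table(recordings, metrics)
    _write_csv(features, out / "features.csv")

    cv_report = {}
    if config.run_classifier:
        X = features[feat_mod.feature_names()].to_numpy()
        groups = features["group"].to_numpy()
        for task in ("depression", "manic"):
            mask = np.isin(groups, ["control", task])
            if len(np.unique(groups[mask])) < 2:
                continue
            res = feat_mod.crossvalidate(
                X[mask],
                groups[mask],
                k=min(config.cv_folds, int(mask.sum())),
                config=config.classifier,
                seed=config.seed,
            )
            cv_report[f"{task}_vs_control"] = res
        (out / "cv_report.json").write_text(json.dumps(cv_report, indent=2))

    manifest = {"artifacts": {}, "seed": config.seed}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest["artifacts"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
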