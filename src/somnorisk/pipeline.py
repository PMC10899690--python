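"""End-to-end orchestration: simulate -> prepare -> label -> evaluate -> report.

Each stage reads/writes the CSV schemas of :mod:`somnorisk.io`; a run emits a
manifest recording the config snapshot, master seed and output digests so the
experiment is reproducible bit-identically from config + seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import CohortConfig, SweepConfig, config_to_dict
from .cohort import generate_cohort
from .evaluate import (iauc_table, loocv_personalization_sweep,
                       randomize_chronology_experiment)
from .io import RunManifest, file_digest, new_manifest, read_table, write_table
from .labeling import assign_session_isi, label_sessions
from .metrics import compare_iauc_curves
from .sessions import apply_inclusion_filters, build_sessions

logger = logging.getLogger(__name__)


def stage_simulate(cohort_cfg: CohortConfig, out_dir: Path) -> dict[str, Path]:
    tables = generate_cohort(cohort_cfg)
    out = {
        "subjects": write_table(tables.subjects, out_dir / "subjects.csv",
                                "subjects"),
        "presence_intervals": write_table(
            tables.presence_intervals, out_dir / "presence_intervals.csv",
            "presence_intervals"),
        "session_physiology": write_table(
            tables.session_physiology, out_dir / "session_physiology.csv",
            "session_physiology"),
        "questionnaires": write_table(
            tables.questionnaires, out_dir / "questionnaires.csv",
            "questionnaires"),
    }
    logger.info("simulated %d subjects, %d presence intervals, %d nights",
                len(tables.subjects), len(tables.presence_intervals),
                len(tables.session_physiology))
    return out


def stage_prepare(cohort_cfg: CohortConfig, sweep_cfg: SweepConfig,
                  in_dir: Path, out_dir: Path) -> dict[str, Path]:
    presence = read_table(in_dir / "presence_intervals.csv",
                          "presence_intervals")
    physio = read_table(in_dir / "session_physiology.csv",
                        "session_physiology")
    subjects = read_table(in_dir / "subjects.csv", "subjects")
    quest = read_table(in_dir / "questionnaires.csv", "questionnaires")
    sessions = build_sessions(presence, physio, subjects,
                              cohort_cfg.study_start_date,
                              cohort_cfg.study_days)
    sessions["bed_exits"] = sessions["bed_exits"].astype(int)
    window = (cohort_cfg.study_start_date,
              cohort_cfg.study_start_date
              + pd.Timedelta(days=cohort_cfg.study_days + 2))
    kept, report = apply_inclusion_filters(
        sessions, quest, subjects,
        min_sessions=sweep_cfg.min_sessions,
        min_questionnaires=sweep_cfg.min_questionnaires,
        study_window=window)
    logger.info("inclusion funnel: %s",
                ", ".join(f"{r.stage}={r.n_subjects}"
                          for r in report.itertuples()))
    return {
        "sessions": write_table(kept, out_dir / "sessions.csv", "sessions"),
        "inclusion_report": write_table(
            report, out_dir / "inclusion_report.csv", "inclusion_report"),
    }


def stage_label(cohort_cfg: CohortConfig, sweep_cfg: SweepConfig,
                in_dir: Path, out_dir: Path) -> dict[str, Path]:
    sessions = read_table(in_dir / "sessions.csv", "sessions")
    quest = read_table(in_dir / "questionnaires.csv", "questionnaires")
    quest = quest[quest["subject_id"].isin(sessions["subject_id"])]
    with_isi = assign_session_isi(sessions, quest, cohort_cfg.wave_dates())
    labeled = label_sessions(with_isi, sweep_cfg.thresholds,
                             sweep_cfg.inclusive_threshold)
    return {"labeled_sessions": write_table(
        labeled, out_dir / "labeled_sessions.csv", "labeled_sessions")}


def stage_evaluate(sweep_cfg: SweepConfig, in_dir: Path, out_dir: Path,
                   randomized: bool = False) -> dict[str, Path]:
    labeled = read_table(in_dir / "labeled_sessions.csv", "labeled_sessions")
    prefix = "randomized_" if randomized else ""
    if randomized:
        sweep = randomize_chronology_experiment(labeled, sweep_cfg,
                                                seed=sweep_cfg.seed)
    else:
        sweep = loocv_personalization_sweep(labeled, sweep_cfg)
    iauc = iauc_table(sweep, mode=sweep_cfg.aggregation_mode
                      if sweep_cfg.aggregation_mode == "per_subject"
                      else "pooled")
    return {
        f"{prefix}sweep_results": write_table(
            sweep, out_dir / f"{prefix}sweep_results.csv", "sweep_results"),
        f"{prefix}iauc": write_table(
            iauc, out_dir / f"{prefix}iauc.csv", "iauc"),
    }


def stage_report(out_dir: Path, plot_path: Path | None = None
                 ) -> dict[str, Path]:
    """Pairwise iAUC curve comparisons across thresholds (+ optional plot)."""
    iauc = read_table(out_dir / "iauc.csv", "iauc")
    thresholds = sorted(iauc["threshold"].unique())
    rows = []
    for i, a in enumerate(thresholds):
        for b in thresholds[i + 1:]:
            ca = iauc[iauc["threshold"] == a].sort_values("interval")["iauc"]
            cb = iauc[iauc["threshold"] == b].sort_values("interval")["iauc"]
            t, p = compare_iauc_curves(ca.to_numpy(), cb.to_numpy())
            rows.append({"comparison": f"ISI {a}-{b}",
                         "t_statistic": t, "p_value": p})
    out = {"iauc_tests": write_table(pd.DataFrame(rows),
                                     out_dir / "iauc_tests.csv", "iauc_tests")}
    if plot_path is not None:
        plot_auc_curves(iauc, plot_path)
        out["auc_plot"] = Path(plot_path)
    return out


def plot_auc_curves(iauc: pd.DataFrame, path) -> None:
    """AUC vs personalization interval, one line per ISI threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for thr, grp in iauc.groupby("threshold"):
        grp = grp.sort_values("interval")
        ax.plot(grp["interval"], grp["auc"], marker="o",
                label=f"ISI >= {thr}")
    ax.set_xlabel("personalization interval (sessions)")
    ax.set_ylabel("pooled AUC")
    ax.set_ylim(0.0, 1.0)
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.legend()
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(cohort_cfg: CohortConfig, sweep_cfg: SweepConfig,
                 out_dir, include_randomized: bool = False,
                 plot_path=None) -> RunManifest:
    """Execute every stage in order and emit the run manifest."""
    cohort_cfg.validate()
    sweep_cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stages = [
        ("simulate", lambda: stage_simulate(cohort_cfg, out_dir)),
        ("prepare", lambda: stage_prepare(cohort_cfg, sweep_cfg,
                                          out_dir, out_dir)),
        ("label", lambda: stage_label(cohort_cfg, sweep_cfg,
                                      out_dir, out_dir)),
        ("evaluate", lambda: stage_evaluate(sweep_cfg, out_dir, out_dir)),
    ]
    if include_randomized:
        stages.append(("randomize",
                       lambda: stage_evaluate(sweep_cfg, out_dir, out_dir,
                                              randomized=True)))
    stages.append(("report", lambda: stage_report(out_dir, plot_path)))
    for name, fn in stages:
        try:
            outputs.update(fn())
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s complete", name)
    manifest = new_manifest(sweep_cfg.seed, config_to_dict(cohort_cfg),
                            config_to_dict(sweep_cfg), __version__)
    manifest.outputs = {str(p): file_digest(p) for p in outputs.values()
                        if Path(p).suffix == ".csv"}
    manifest.save(out_dir / "run_manifest.yaml")
    return manifest
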