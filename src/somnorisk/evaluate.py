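"""Leave-one-subject-out personalization sweep and chronology-randomized control.

For each ISI threshold and each left-out subject, a generic PA model is
trained on every other subject's labeled sessions; a copy is then fine-tuned
on the left-out subject's chronologically first k sessions for each
personalization interval k, and scored on that subject's remaining sessions
(sessions 1..k are excluded from evaluation at every k, including k=0).
Accuracy/precision/recall are aggregated across subjects as mean +/- SD;
F1 and AUC are computed pooled over all left-out predictions (a per-subject
AUC aggregate is also reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SweepConfig
from .metrics import auc_rank, compute_iauc, compute_metrics, confusion_counts
from .pa import PAModel, Standardizer, _run_stream, _to_pm1
from .sessions import FEATURE_ORDER

logger = logging.getLogger(__name__)


@dataclass
class _SubjectData:
    subject_id: str
    X: np.ndarray          # (n_sessions, 14) chronological
    y: dict[int, np.ndarray]  # threshold -> {0,1} labels


def _subject_arrays(labeled: pd.DataFrame, thresholds,
                    shuffle_seed: int | None = None) -> list[_SubjectData]:
    """Per-subject chronological feature/label arrays.

    ``shuffle_seed`` permutes each subject's session order (features and
    labels move together) — the chronology-randomization control.
    """
    out = []
    df = labeled.sort_values(["subject_id", "session_date", "start"])
    for si, (sid, grp) in enumerate(df.groupby("subject_id", sort=True)):
        X = np.ascontiguousarray(grp[list(FEATURE_ORDER)].to_numpy(float))
        y = {t: grp[f"label_ge_{t}"].to_numpy(np.int8) for t in thresholds}
        if shuffle_seed is not None:
            rng = np.random.default_rng(
                np.random.SeedSequence([shuffle_seed, si]))
            perm = rng.permutation(len(X))
            X = np.ascontiguousarray(X[perm])
            y = {t: v[perm] for t, v in y.items()}
        out.append(_SubjectData(sid, X, y))
    return out


def _fit_generic_pooled(X: np.ndarray, y01: np.ndarray, cfg: SweepConfig,
                        seed_seq: np.random.SeedSequence
                        ) -> tuple[PAModel, Standardizer]:
    """Generic fit on a pre-pooled array (thin wrapper over fit_generic)."""
    from .pa import fit_generic
    return fit_generic(X, y01, aggressiveness_c=cfg.aggressiveness_c,
                       epochs=cfg.epochs, seed=seed_seq, variant=cfg.variant)


def loocv_personalization_sweep(labeled: pd.DataFrame, cfg: SweepConfig,
                                shuffle_seed: int | None = None,
                                ) -> pd.DataFrame:
    """Run the full (threshold x interval) LOOCV personalization sweep.

    Returns one row per (threshold, interval) with subject-averaged
    accuracy/precision/recall (NaN cells excluded from the mean/SD), pooled
    F1 and AUC, and the mean/SD of per-subject AUC.
    """
    cfg.validate()
    subjects = _subject_arrays(labeled, cfg.thresholds, shuffle_seed)
    max_k = max(cfg.intervals)
    eligible = [s for s in subjects if len(s.X) >= max_k + 2]
    for s in subjects:
        if len(s.X) < max_k + 2:
            logger.warning(
                "subject %s has %d sessions < %d; excluded from sweep",
                s.subject_id, len(s.X), max_k + 2)
    if not eligible:
        raise ValueError("no subject has enough sessions for the sweep")

    rows = []
    for ti, thr in enumerate(cfg.thresholds):
        per_subject: dict[int, dict[str, list[float]]] = {
            k: {"accuracy": [], "precision": [], "recall": [], "auc": []}
            for k in cfg.intervals}
        pooled_scores: dict[int, list[np.ndarray]] = {k: [] for k in cfg.intervals}
        pooled_labels: dict[int, list[np.ndarray]] = {k: [] for k in cfg.intervals}
        pooled_conf: dict[int, list] = {k: [] for k in cfg.intervals}

        X_all = np.concatenate([s.X for s in eligible])
        y_all = np.concatenate([s.y[thr] for s in eligible])
        sizes = np.array([len(s.X) for s in eligible])
        bounds = np.concatenate([[0], np.cumsum(sizes)])

        n_evaluated = 0
        for si, subj in enumerate(eligible):
            train_mask = np.ones(len(X_all), dtype=bool)
            train_mask[bounds[si]:bounds[si + 1]] = False
            seed_seq = np.random.SeedSequence(
                [cfg.seed, ti, si, 0 if shuffle_seed is None else 1])
            y_train = y_all[train_mask]
            if np.unique(y_train).size < 2:
                logger.warning(
                    "threshold %s: training stream without subject %s is "
                    "single-class; fold skipped", thr, subj.subject_id)
                continue
            n_evaluated += 1
            model, std = _fit_generic_pooled(
                X_all[train_mask], y_train, cfg, seed_seq)
            Xs_subj = std.transform(subj.X)
            y_subj = subj.y[thr]
            for k in cfg.intervals:
                tuned = model.copy()
                if k > 0:
                    _run_stream(tuned, np.ascontiguousarray(Xs_subj[:k]),
                                _to_pm1(y_subj[:k]))
                X_eval, y_eval = Xs_subj[k:], y_subj[k:]
                scores = X_eval @ tuned.weights + tuned.bias
                preds = np.where(scores >= 0, 1, 0)
                conf = confusion_counts(preds, y_eval)
                m = compute_metrics(conf, auc_rank(scores, y_eval))
                ps = per_subject[k]
                ps["accuracy"].append(m.accuracy)
                ps["precision"].append(m.precision)
                ps["recall"].append(m.recall)
                ps["auc"].append(m.auc)
                pooled_scores[k].append(scores)
                pooled_labels[k].append(y_eval)
                pooled_conf[k].append(conf)

        if n_evaluated == 0:
            raise ValueError(
                f"threshold {thr}: every leave-one-out training stream is "
                "single-class; cannot evaluate")
        for k in cfg.intervals:
            all_scores = np.concatenate(pooled_scores[k])
            all_labels = np.concatenate(pooled_labels[k])
            conf_sum = pooled_conf[k][0]
            for c in pooled_conf[k][1:]:
                conf_sum = conf_sum + c
            pooled_m = compute_metrics(
                conf_sum, auc_rank(all_scores, all_labels))
            row = {"threshold": thr, "interval": k,
                   "n_subjects": n_evaluated}
            for name in ("accuracy", "precision", "recall", "auc"):
                vals = np.asarray(per_subject[k][name], dtype=float)
                defined = vals[np.isfinite(vals)]
                prefix = "auc_subject" if name == "auc" else name
                row[f"{prefix}_mean"] = (
                    float(defined.mean()) if defined.size else float("nan"))
                row[f"{prefix}_sd"] = (
                    float(defined.std(ddof=0)) if defined.size else float("nan"))
                row[f"{prefix}_n_defined"] = int(defined.size)
            row["f1_pooled"] = pooled_m.f1
            row["auc_pooled"] = pooled_m.auc
            rows.append(row)
    return pd.DataFrame(rows)


def randomize_chronology_experiment(labeled: pd.DataFrame, cfg: SweepConfig,
                                    seed: int) -> pd.DataFrame:
    """Sweep after permuting each subject's session order (control experiment).

    Each subject's (feature vector, label) pairs are kept intact; only their
    chronological order is destroyed, so any order-dependent AUC structure in
    the main sweep that survives here is attributable to the learner rather
    than the data's chronology.
    """
    return loocv_personalization_sweep(labeled, cfg, shuffle_seed=seed)


def iauc_table(sweep: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Incremental AUC per threshold from a sweep result table.

    ``mode``: 'pooled' differentiates the pooled AUC sequence (default);
    'per_subject' differentiates the mean per-subject AUC sequence.
    """
    col = {"pooled": "auc_pooled", "per_subject": "auc_subject_mean"}[mode]
    rows = []
    for thr, grp in sweep.groupby("threshold", sort=True):
        grp = grp.sort_values("interval")
        iauc = compute_iauc(grp[col].to_numpy())
        for interval, v, a in zip(grp["interval"], iauc, grp[col]):
            rows.append({"threshold": thr, "interval": int(interval),
                         "auc": float(a), "iauc": float(v)})
    return pd.DataFrame(rows)
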