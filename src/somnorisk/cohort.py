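"""Synthetic longitudinal smart-bed cohort generator.

Emulates the statistical structure of a proprietary smart-bed study: a cohort
of subjects observed nightly over ~160 days, four ISI questionnaire waves six
weeks apart with per-wave nonresponse, per-night bed-presence intervals
(occasionally split within the night, occasionally with a daytime nap), and a
per-night physiology summary.

Generative model
----------------
Each subject carries a latent insomnia severity on the ISI scale that follows
a per-wave random walk from a Gaussian baseline.  Session physiology for
subject *i* on night *j* is

    x_ij = mu + u_i + lambda * (s_ij + a_i - mu_ISI) + eps_ij

where ``lambda`` is the per-feature severity loading, ``s_ij`` the nightly
latent severity, ``eps`` nightly noise, ``u_i`` small independent per-feature
subject offsets, and ``a_i = -(baseline_i - mu_ISI) + c_i`` a subject offset
acting *along the loading direction*.  Because ``a_i`` cancels the subject's
own severity level and replaces it with independent noise ``c_i``, a pooled
classifier sees features that do not track between-subject ISI differences
(pooled discrimination ~ chance) while within-subject severity changes remain
clearly expressed — the structure that makes personalization pay off.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .config import CohortConfig

GENDER_LEVELS = ("male", "female", "other")

#: Night-level physiology features drawn directly by the generator, with
#: (population mean, nightly noise SD) in their natural units.
PHYSIO_BASE: dict[str, tuple[float, float]] = {
    "sleep_duration": (430.0, 40.0),       # minutes asleep
    "restful_frac": (0.80, 0.05),          # restful fraction of sleep
    "time_to_fall_asleep": (25.0, 12.0),   # minutes
    "percent_motion": (0.10, 0.035),       # fraction of session
    "heart_rate": (62.0, 3.0),             # bpm
    "breathing_rate": (14.0, 1.2),         # breaths/min
    "hrv": (55.0, 10.0),                   # ms (SD of inter-beat interval)
    "quality_score": (70.0, 8.0),          # bounded 0-100 quality score
}

_CLIPS = {
    "sleep_duration": (180.0, 620.0),
    "restful_frac": (0.30, 0.98),
    "time_to_fall_asleep": (2.0, 150.0),
    "percent_motion": (0.003, 0.60),
    "heart_rate": (40.0, 110.0),
    "breathing_rate": (8.0, 25.0),
    "hrv": (5.0, 180.0),
    "quality_score": (5.0, 100.0),
}

_BASE_BEDTIME_JITTER_SD = 18.0   # minutes, at average severity
_MIN_JITTER_SD, _MAX_JITTER_SD = 6.0, 75.0
_NIGHTLY_SEVERITY_JITTER = 0.8   # ISI points


class CohortTables(NamedTuple):
    subjects: pd.DataFrame
    presence_intervals: pd.DataFrame
    session_physiology: pd.DataFrame
    questionnaires: pd.DataFrame
    #: generator-internal latents (subject offsets, per-wave severities);
    #: consumed only by oracle checks, never by the pipeline.
    latents: pd.DataFrame


def _allocate_items(total: int, rng: np.random.Generator) -> np.ndarray:
    """Distribute ``total`` points over 7 items capped at 4 each."""
    items = np.zeros(7, dtype=np.int64)
    for _ in range(int(total)):
        open_items = np.flatnonzero(items < 4)
        items[open_items[rng.integers(open_items.size)]] += 1
    return items


def _night_physiology(rng: np.random.Generator, dev: float,
                      loading: Mapping[str, float], noise_mult: float,
                      feature_offsets: Mapping[str, float]) -> dict[str, float]:
    """Draw one night's physiology given the effective severity deviation."""
    out: dict[str, float] = {}
    for name, (mu, sd) in PHYSIO_BASE.items():
        lam = loading.get(name, 0.0)
        v = (mu + feature_offsets.get(name, 0.0) + lam * dev
             + rng.normal(0.0, sd * noise_mult))
        lo, hi = _CLIPS[name]
        out[name] = float(np.clip(v, lo, hi))
    restful = out.pop("restful_frac") * out["sleep_duration"]
    out["restful_duration"] = float(restful)
    return out


def _simulate_night(rng: np.random.Generator, night_date: dt.date,
                    bedtime_center_min: float, dev: float,
                    config: CohortConfig,
                    feature_offsets: Mapping[str, float] | None = None,
                    ) -> tuple[list[tuple[dt.datetime, dt.datetime]], dict]:
    """One night: bed-presence intervals plus the physiology summary.

    ``night_date`` is the evening's calendar date; the session ends (and is
    later keyed) on the following morning's date in the usual case.
    """
    loading = config.severity_loading
    offsets = feature_offsets or {}
    physio = _night_physiology(rng, dev, loading, config.noise_sd, offsets)

    jitter_sd = float(np.clip(
        _BASE_BEDTIME_JITTER_SD + loading.get("sri", 0.0) * dev,
        _MIN_JITTER_SD, _MAX_JITTER_SD))
    jitter = float(np.clip(rng.normal(0.0, jitter_sd), -75.0, 75.0))
    bed_minute = bedtime_center_min + jitter

    wake_after = float(np.clip(abs(rng.normal(15.0, 10.0)), 0.0, 45.0))
    in_bed = physio["time_to_fall_asleep"] + physio["sleep_duration"] + wake_after

    midnight = dt.datetime.combine(night_date, dt.time())
    start = midnight + dt.timedelta(minutes=bed_minute)
    end = start + dt.timedelta(minutes=in_bed)

    intervals: list[tuple[dt.datetime, dt.datetime]] = []
    p_split = float(np.clip(
        config.split_night_prob + loading.get("bed_exits", 0.0) * dev, 0.0, 1.0))
    if rng.random() < p_split:
        cut = start + dt.timedelta(minutes=float(rng.uniform(0.3, 0.7)) * in_bed)
        gap = dt.timedelta(minutes=float(rng.uniform(10.0, 90.0)))
        intervals.append((start, cut))
        intervals.append((cut + gap, end + gap))
        end = end + gap
    else:
        intervals.append((start, end))

    if rng.random() < config.nap_prob:
        nap_day = end.date()
        nap_start = (dt.datetime.combine(nap_day, dt.time(13, 0))
                     + dt.timedelta(minutes=float(rng.uniform(0.0, 150.0))))
        nap_end = nap_start + dt.timedelta(minutes=float(rng.uniform(20.0, 80.0)))
        # keep the nap clear of the night on both sides (>2 h so it never merges)
        if nap_start >= end + dt.timedelta(minutes=150):
            intervals.append((nap_start, nap_end))

    physio["session_date"] = end.date()
    physio["in_bed_minutes"] = in_bed
    return intervals, physio


def generate_presence_intervals(subject: Mapping, night_date: dt.date,
                                rng: np.random.Generator,
                                config: CohortConfig | None = None,
                                severity_dev: float = 0.0,
                                ) -> list[tuple[dt.datetime, dt.datetime]]:
    """Bed-presence intervals for one subject-night.

    The main nocturnal interval is split in two (gap < 2 h, so downstream
    consolidation re-merges it) with probability ``split_night_prob``, and a
    short daytime nap is added with probability ``nap_prob``.
    """
    cfg = (config or CohortConfig()).validate()
    bedtime = float(subject.get("bedtime_center_minutes", 23 * 60.0))
    intervals, _ = _simulate_night(rng, night_date, bedtime, severity_dev, cfg)
    return intervals


def _orthogonalized(v: np.ndarray, all_latents: list[list[float]],
                    cfg: CohortConfig) -> np.ndarray:
    """Residualize ``v`` against subject severity summaries; rescale to unit SD.

    The summaries are the per-wave latent severities plus the per-subject
    fraction of waves at/above each risk threshold.  With too few subjects to
    support the projection the vector is returned centred/rescaled only.
    """
    n = v.size
    lat = np.array(all_latents)  # (n_subjects, n_waves)
    cols = [np.ones(n), *lat.T]
    for t in (8, 10, 15):
        cols.append((np.round(lat) >= t).mean(axis=1))
    Z = np.column_stack(cols)
    if n > 2 * Z.shape[1]:
        beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
        v = v - Z @ beta
    else:
        v = v - v.mean()
    sd = v.std()
    return v / sd if sd > 0 else v


def generate_cohort(config: CohortConfig) -> CohortTables:
    """Simulate the full cohort; deterministic for a fixed ``config.seed``."""
    cfg = config.validate()
    root = np.random.SeedSequence(cfg.seed)
    subj_seeds = root.spawn(cfg.n_subjects)
    wave_dates = cfg.wave_dates()
    thresholds_cycle = (8, 10, 15)

    subjects_rows, presence_rows, physio_rows, quest_rows, latent_rows = \
        [], [], [], [], []

    p_other = cfg.gender_other_prob
    p_female = (1.0 - p_other) * 811.0 / (669.0 + 811.0)
    p_male = 1.0 - p_other - p_female
    n_cross = int(round(cfg.crosser_fraction * cfg.n_subjects))

    # ---- pass 1: subject-level draws -----------------------------------
    rngs: list[np.random.Generator] = []
    bases: list[float] = []
    all_latents: list[list[float]] = []
    raw_c = np.empty(cfg.n_subjects)
    raw_b = np.empty((cfg.n_subjects, len(PHYSIO_BASE)))
    demo: list[tuple[float, str, float]] = []
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(subj_seeds[i])
        age = float(np.clip(rng.normal(51.72, 12.77), 18.0, 90.0))
        gender = GENDER_LEVELS[
            int(rng.choice(3, p=[p_male, p_female, p_other]))]
        bedtime_center = float(np.clip(rng.normal(23 * 60.0, 40.0),
                                       21 * 60.0, 25.5 * 60.0))
        if i < n_cross:
            base = thresholds_cycle[i % 3] + rng.normal(-1.5, 2.0)
        else:
            base = rng.normal(cfg.isi_baseline_mean, cfg.isi_baseline_sd)
        base = float(np.clip(base, 0.0, 28.0))
        latents = [base]
        for _ in range(1, cfg.n_waves):
            latents.append(float(np.clip(
                latents[-1] + rng.normal(cfg.isi_wave_drift_mean,
                                         cfg.isi_wave_drift_sd), 0.0, 28.0)))
        raw_c[i] = rng.normal(0.0, 1.0)
        raw_b[i] = rng.normal(0.0, 1.0, size=len(PHYSIO_BASE))
        rngs.append(rng)
        bases.append(base)
        all_latents.append(latents)
        demo.append((age, gender, bedtime_center))

    # Subject offsets c_i are drawn conditionally orthogonal (in sample) to
    # the latent severity trajectories and their threshold-crossing rates, so
    # pooled non-separability is a design property of the cohort rather than
    # a small-sample accident.
    c_vec = _orthogonalized(raw_c, all_latents, cfg) * cfg.subject_offset_sd
    b_mat = np.column_stack([
        _orthogonalized(raw_b[:, j], all_latents, cfg) * 0.5 * sd
        for j, (_, sd) in enumerate(PHYSIO_BASE.values())
    ])

    # ---- pass 2: questionnaires and nights -----------------------------
    for i in range(cfg.n_subjects):
        rng = rngs[i]
        sid = f"S{i:04d}"
        age, gender, bedtime_center = demo[i]
        base, latents = bases[i], all_latents[i]
        a_i = -(base - cfg.isi_baseline_mean) + float(c_vec[i])
        feature_offsets = dict(zip(PHYSIO_BASE.keys(), b_mat[i]))

        subjects_rows.append({
            "subject_id": sid, "age": round(age, 1), "gender": gender,
            "sleep_goal": int(cfg.sleep_goal_minutes),
            "bedtime_center_minutes": round(bedtime_center, 1),
        })
        latent_rows.append({
            "subject_id": sid, "offset_isi": a_i,
            **{f"latent_wave_{w+1}": latents[w] for w in range(cfg.n_waves)},
            **{f"off_{k}": v for k, v in feature_offsets.items()},
        })

        # questionnaires
        for w, wdate in enumerate(wave_dates, start=1):
            if rng.random() < cfg.wave_response_prob:
                total = int(np.clip(round(latents[w - 1]), 0, 28))
                items = _allocate_items(total, rng)
                quest_rows.append({
                    "subject_id": sid, "wave_index": w,
                    "response_date": wdate + dt.timedelta(
                        days=int(rng.integers(0, 14))),
                    **{f"isi_q{j+1}": int(items[j]) for j in range(7)},
                    "isi_total": total,
                })

        # nights
        for d in range(cfg.study_days):
            if rng.random() < cfg.night_skip_prob:
                continue
            night_date = cfg.study_start_date + dt.timedelta(days=d)
            wave_idx = sum(1 for wd in wave_dates if wd <= night_date) - 1
            wave_idx = max(wave_idx, 0)
            sev = float(np.clip(
                latents[wave_idx] + rng.normal(0.0, _NIGHTLY_SEVERITY_JITTER),
                0.0, 28.0))
            dev = sev + a_i - cfg.isi_baseline_mean
            intervals, physio = _simulate_night(
                rng, night_date, bedtime_center, dev, cfg, feature_offsets)
            for (s, e) in intervals:
                presence_rows.append({"subject_id": sid, "start": s, "end": e})
            physio_rows.append({
                "subject_id": sid,
                "session_date": physio["session_date"],
                "sleep_duration": round(physio["sleep_duration"], 2),
                "restful_duration": round(physio["restful_duration"], 2),
                "time_to_fall_asleep": round(physio["time_to_fall_asleep"], 2),
                "percent_motion": round(physio["percent_motion"], 4),
                "heart_rate": round(physio["heart_rate"], 2),
                "breathing_rate": round(physio["breathing_rate"], 2),
                "hrv": round(physio["hrv"], 2),
                "quality_score": round(physio["quality_score"], 2),
            })

    subjects = pd.DataFrame(subjects_rows)
    presence = pd.DataFrame(presence_rows)
    physio = pd.DataFrame(physio_rows)
    quest = pd.DataFrame(quest_rows)
    latents_df = pd.DataFrame(latent_rows)
    if not quest.empty:
        quest["response_date"] = pd.to_datetime(quest["response_date"])
    if not physio.empty:
        physio["session_date"] = pd.to_datetime(physio["session_date"])
    if not presence.empty:
        presence["start"] = pd.to_datetime(presence["start"])
        presence["end"] = pd.to_datetime(presence["end"])
        presence = presence.sort_values(
            ["subject_id", "start"]).reset_index(drop=True)
    return CohortTables(subjects, presence, physio, quest, latents_df)


def oracle_scores(sessions: pd.DataFrame, subjects: pd.DataFrame,
                  latents: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Severity scores an oracle that knows each subject's offsets would emit.

    Projects de-offset physiology onto the severity loading, noise-weighted.
    Used only to verify the generator's within-subject separability contract.
    """
    lam = config.severity_loading
    merged = sessions.merge(latents, on="subject_id", how="left")
    score = np.zeros(len(merged))
    for name, (_, sd) in PHYSIO_BASE.items():
        if name == "restful_frac":
            continue
        lam_f = lam.get(name, 0.0)
        if lam_f == 0.0 or name not in merged:
            continue
        x = merged[name].to_numpy(float)
        x = x - merged[f"off_{name}"].to_numpy(float) - lam_f * merged[
            "offset_isi"].to_numpy(float)
        score += lam_f / sd * x
    return score
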