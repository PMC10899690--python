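"""Session construction: consolidation, daily selection, SRI, features, filters.

Raw bed-presence intervals are consolidated into sleep sessions (intervals
separated by at most two hours belong to the same session, each re-entry
counting as one bed exit), at most one session — the longest — is kept per
subject-day, the sleep regularity index (SRI) is computed over a trailing
window of 1-minute sleep/wake epochs, and each retained session is expanded
into the canonical 14-component feature vector.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .errors import DataError

#: Canonical feature order of the model's 14-component input vector.
FEATURE_ORDER: tuple[str, ...] = (
    "age",
    "bed_exits",
    "breathing_rate",
    "gender_encoded",
    "heart_rate",
    "hrv",
    "percent_motion",
    "restful_duration",
    "session_duration",
    "sleep_debt",
    "sleep_duration",
    "quality_score",
    "sri",
    "time_to_fall_asleep",
)

MERGE_GAP = dt.timedelta(hours=2)
SRI_WINDOW_DAYS = 14
_EPOCHS_PER_DAY = 1440

GENDER_ENCODING = {"male": 0.0, "female": 1.0}
GENDER_OTHER_VALUE = 0.5  # default encoding for gender "other"


def consolidate_sessions(intervals: pd.DataFrame,
                         merge_gap: dt.timedelta = MERGE_GAP) -> pd.DataFrame:
    """Merge presence intervals separated by at most ``merge_gap``.

    The gap comparison is inclusive: a gap of exactly two hours still merges.
    ``session_duration`` is the summed in-bed time of the constituent
    intervals (gaps excluded); each merge adds one bed exit.  Overlapping
    intervals are a data error.

    Parameters
    ----------
    intervals : DataFrame with columns subject_id, start, end.

    Returns
    -------
    DataFrame with columns subject_id, start, end, session_date,
    session_duration (minutes), bed_exits.
    """
    cols = ["subject_id", "start", "end", "session_date",
            "session_duration", "bed_exits"]
    if len(intervals) == 0:
        return pd.DataFrame(columns=cols)
    df = intervals.sort_values(["subject_id", "start"])
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise DataError(
            f"interval with end <= start for subject {bad['subject_id']} "
            f"at {bad['start']}")
    rows = []
    for sid, grp in df.groupby("subject_id", sort=True):
        starts = grp["start"].to_list()
        ends = grp["end"].to_list()
        cur_start, cur_end = starts[0], ends[0]
        cur_dur = (cur_end - cur_start).total_seconds() / 60.0
        exits = 0
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_end:
                raise DataError(
                    f"overlapping intervals for subject {sid}: "
                    f"[{cur_start} .. {cur_end}] vs [{s} .. {e}]")
            if s - cur_end <= merge_gap:
                exits += 1
                cur_end = e
                cur_dur += (e - s).total_seconds() / 60.0
            else:
                rows.append((sid, cur_start, cur_end, cur_end.date(),
                             cur_dur, exits))
                cur_start, cur_end = s, e
                cur_dur = (e - s).total_seconds() / 60.0
                exits = 0
        rows.append((sid, cur_start, cur_end, cur_end.date(), cur_dur, exits))
    out = pd.DataFrame(rows, columns=cols)
    out["session_date"] = pd.to_datetime(out["session_date"])
    return out


def select_longest_per_day(spans: pd.DataFrame) -> pd.DataFrame:
    """Keep the single longest session per subject-day (ties: earlier start)."""
    if len(spans) == 0:
        return spans.copy()
    ordered = spans.sort_values(
        ["subject_id", "session_date", "session_duration", "start"],
        ascending=[True, True, False, True])
    return (ordered.groupby(["subject_id", "session_date"], sort=True)
            .head(1).reset_index(drop=True))


def compute_sleep_debt(goal: float, sleep_duration: float) -> float:
    """Positive part of (sleep goal - sleep duration), both in minutes."""
    if goal < 0 or sleep_duration < 0:
        raise DataError(
            f"sleep goal and duration must be non-negative, "
            f"got {goal!r}, {sleep_duration!r}")
    return max(0.0, float(goal) - float(sleep_duration))


def compute_sri(states: np.ndarray, as_of_index: int | None = None,
                window_days: int = SRI_WINDOW_DAYS) -> float:
    """Sleep regularity index over a trailing window of daily state rows.

    ``states`` holds one row per calendar day and one column per within-day
    epoch (any hashable state symbols; only equality matters).  The SRI is
    -100 + 200 * (fraction of epoch pairs exactly 24 h apart in the same
    state), over the ``window_days`` days ending at ``as_of_index``.
    Returns NaN when the window contains fewer than two days.
    """
    arr = np.asarray(states)
    if arr.ndim != 2:
        raise DataError("states must be a (days, epochs) array")
    if as_of_index is None:
        as_of_index = arr.shape[0] - 1
    lo = max(0, as_of_index - window_days + 1)
    window = arr[lo:as_of_index + 1]
    if window.shape[0] < 2:
        return float("nan")
    agree = window[:-1] == window[1:]
    return -100.0 + 200.0 * float(np.mean(agree))


def _sleep_state_grid(sessions: pd.DataFrame, start_date: dt.date,
                      n_days: int) -> np.ndarray:
    """Boolean asleep/awake grid (n_days x 1440) from one subject's sessions.

    A subject is marked asleep from (session start + time to fall asleep) for
    ``sleep_duration`` contiguous minutes; every other minute is awake.
    """
    grid = np.zeros(n_days * _EPOCHS_PER_DAY, dtype=bool)
    origin = dt.datetime.combine(start_date, dt.time())
    for row in sessions.itertuples():
        sleep_start = row.start.to_pydatetime() + dt.timedelta(
            minutes=float(row.time_to_fall_asleep))
        i0 = int((sleep_start - origin).total_seconds() // 60)
        i1 = i0 + int(round(float(row.sleep_duration)))
        i0, i1 = max(i0, 0), min(i1, grid.size)
        if i1 > i0:
            grid[i0:i1] = True
    return grid.reshape(n_days, _EPOCHS_PER_DAY)


def add_sri(sessions: pd.DataFrame, study_start: dt.date, study_days: int,
            window_days: int = SRI_WINDOW_DAYS) -> pd.DataFrame:
    """Attach a per-session SRI column computed on trailing sleep/wake grids.

    Sessions whose trailing window has under two days of history get the
    subject's mean SRI so far, falling back to the cohort mean.
    """
    n_days = study_days + 3  # headroom: sessions end after the last night
    out = sessions.copy()
    out["sri"] = np.nan
    for sid, grp in sessions.groupby("subject_id", sort=False):
        grid = _sleep_state_grid(grp, study_start, n_days)
        agree = np.mean(grid[:-1] == grid[1:], axis=1)  # day d vs d+1
        day_idx = ((grp["session_date"] - pd.Timestamp(study_start))
                   .dt.days.to_numpy())
        sri_vals = np.full(len(grp), np.nan)
        running: list[float] = []
        for j, d in enumerate(day_idx):
            lo = max(0, d - window_days + 1)
            if d - lo >= 1:
                sri_vals[j] = -100.0 + 200.0 * float(np.mean(agree[lo:d]))
            if np.isfinite(sri_vals[j]):
                running.append(sri_vals[j])
            elif running:
                sri_vals[j] = float(np.mean(running))
        out.loc[grp.index, "sri"] = sri_vals
    cohort_mean = float(np.nanmean(out["sri"])) if len(out) else 0.0
    out["sri"] = out["sri"].fillna(cohort_mean)
    return out


def encode_gender(gender: str, other_value: float = GENDER_OTHER_VALUE) -> float:
    if gender in GENDER_ENCODING:
        return GENDER_ENCODING[gender]
    if gender == "other":
        return float(other_value)
    raise DataError(f"unknown gender category {gender!r}")


def build_feature_vector(session, subject,
                         gender_other_value: float = GENDER_OTHER_VALUE
                         ) -> np.ndarray:
    """The 14-component feature vector in canonical order.

    ``session`` and ``subject`` are mappings (or namedtuples/Series) holding
    the session metrics and the subject demographics.  A missing or
    non-finite component is a data error naming the component.
    """
    sess = session._asdict() if hasattr(session, "_asdict") else dict(session)
    subj = subject._asdict() if hasattr(subject, "_asdict") else dict(subject)
    values = dict(sess)
    values["age"] = subj.get("age", sess.get("age"))
    values["gender_encoded"] = encode_gender(
        subj.get("gender", sess.get("gender", "")), gender_other_value)
    vec = np.empty(len(FEATURE_ORDER), dtype=float)
    for i, name in enumerate(FEATURE_ORDER):
        v = values.get(name)
        if v is None or not np.isfinite(float(v)):
            raise DataError(f"missing or non-finite feature component {name!r}")
        vec[i] = float(v)
    return vec


def build_sessions(presence: pd.DataFrame, physiology: pd.DataFrame,
                   subjects: pd.DataFrame, study_start: dt.date,
                   study_days: int,
                   gender_other_value: float = GENDER_OTHER_VALUE,
                   ) -> pd.DataFrame:
    """Full session table: consolidate, select, join physiology, derive features.

    Returns one row per retained session carrying identifiers, timestamps and
    all 14 canonical feature columns.
    """
    spans = select_longest_per_day(consolidate_sessions(presence))
    merged = spans.merge(physiology, on=["subject_id", "session_date"],
                         how="inner")
    goal = subjects.set_index("subject_id")["sleep_goal"]
    merged["sleep_debt"] = [
        compute_sleep_debt(goal[row.subject_id], row.sleep_duration)
        for row in merged.itertuples()
    ]
    merged = add_sri(merged, study_start, study_days)
    demo = subjects.set_index("subject_id")
    merged["age"] = merged["subject_id"].map(demo["age"]).astype(float)
    merged["gender_encoded"] = [
        encode_gender(g, gender_other_value)
        for g in merged["subject_id"].map(demo["gender"])
    ]
    id_cols = ["subject_id", "session_date", "start", "end"]
    return merged[id_cols + list(FEATURE_ORDER)].sort_values(
        ["subject_id", "session_date"]).reset_index(drop=True)


def apply_inclusion_filters(sessions: pd.DataFrame,
                            questionnaires: pd.DataFrame,
                            subjects: pd.DataFrame,
                            min_sessions: int = 120,
                            min_questionnaires: int = 3,
                            study_window: tuple[dt.date, dt.date] | None = None,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain subjects with enough answered waves and enough sessions.

    Returns the filtered session table and a funnel report with per-stage
    counts (enrolled -> answered >= min_questionnaires -> >= min_sessions).
    """
    sess = sessions
    if study_window is not None and len(sess):
        lo, hi = (pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1]))
        sess = sess[(sess["session_date"] >= lo) & (sess["session_date"] <= hi)]
    enrolled = subjects["subject_id"].unique()
    q_counts = (questionnaires.groupby("subject_id")["wave_index"].nunique()
                if len(questionnaires) else pd.Series(dtype=int))
    responders = {s for s in enrolled if q_counts.get(s, 0) >= min_questionnaires}
    s_counts = (sess.groupby("subject_id").size()
                if len(sess) else pd.Series(dtype=int))
    final = {s for s in responders if s_counts.get(s, 0) >= min_sessions}
    report = pd.DataFrame([
        {"stage": "enrolled", "n_subjects": len(enrolled)},
        {"stage": f"responded_ge_{min_questionnaires}", "n_subjects": len(responders)},
        {"stage": f"sessions_ge_{min_sessions}", "n_subjects": len(final)},
    ])
    kept = sess[sess["subject_id"].isin(final)].reset_index(drop=True)
    return kept, report
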