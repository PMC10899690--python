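"""ISI scoring, session-level ISI assignment, and risk binarization.

Every retained sleep session receives the ISI of the most recent answered
questionnaire wave (carry-forward); sessions that predate the subject's first
answered wave receive that first answered wave's ISI (backfill).  This single
last-observation-carried-forward-with-backfill rule reproduces all the stated
cases: sessions before wave 2 use wave 1 (or wave 2 when wave 1 is missing),
sessions after the last answered wave use that wave, and sessions between
answered waves n and n+1 use wave n.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

RISK_THRESHOLDS = (8, 10, 15)

ISI_CATEGORIES = (
    (0, 7, "none"),
    (8, 14, "subthreshold"),
    (15, 21, "clinical"),
    (22, 28, "severe"),
)


def score_isi(items: Sequence[int]) -> int:
    """Total ISI score: the sum of the 7 item responses (each 0-4)."""
    items = list(items)
    if len(items) != 7:
        raise ValidationError(f"ISI has exactly 7 items, got {len(items)}")
    for j, v in enumerate(items, start=1):
        if int(v) != v or not (0 <= int(v) <= 4):
            raise ValidationError(
                f"ISI item {j} must be an integer in [0, 4], got {v!r}")
    return int(sum(int(v) for v in items))


def categorize_isi(total: int) -> str:
    """Clinical category of a total ISI score.

    <8 none; 8-14 subthreshold insomnia; 15-21 clinical insomnia;
    22-28 severe clinical insomnia.
    """
    if int(total) != total or not (0 <= int(total) <= 28):
        raise ValidationError(f"ISI total must be an integer in [0, 28], got {total!r}")
    for lo, hi, name in ISI_CATEGORIES:
        if lo <= int(total) <= hi:
            return name
    raise AssertionError("unreachable")


def binarize_label(assigned_isi: int, threshold: int,
                   inclusive: bool = True) -> int:
    """1 iff the ISI reaches the threshold (>= by default, > if not inclusive).

    The inclusive reading places score 8 — the first subthreshold-insomnia
    score — in the at-risk class at threshold 8.
    """
    if inclusive:
        return int(assigned_isi >= threshold)
    return int(assigned_isi > threshold)


def assign_session_isi(sessions: pd.DataFrame, questionnaires: pd.DataFrame,
                       wave_dates: Sequence[dt.date]) -> pd.DataFrame:
    """Assign each session the ISI of its governing questionnaire wave.

    A session is governed by the latest answered wave whose administration
    (opening) date is on or before the session date; sessions before any
    answered wave's opening date take the earliest answered wave.  Subjects
    with no answered waves are an error (impossible after inclusion filtering).

    Returns ``sessions`` with ``assigned_isi`` and ``source_wave`` columns.
    """
    wave_open = {w + 1: pd.Timestamp(d) for w, d in enumerate(wave_dates)}
    out = sessions.copy()
    out["assigned_isi"] = -1
    out["source_wave"] = -1
    answered = {
        sid: sorted(
            ((int(r.wave_index), wave_open[int(r.wave_index)], int(r.isi_total))
             for r in grp.itertuples()),
            key=lambda t: t[1])
        for sid, grp in questionnaires.groupby("subject_id")
    }
    for sid, grp in out.groupby("subject_id", sort=False):
        waves = answered.get(sid)
        if not waves:
            raise ValidationError(
                f"subject {sid} has no answered questionnaires; "
                "inclusion filtering should have removed it")
        open_dates = [w[1] for w in waves]
        dates = grp["session_date"]
        # index of the latest answered wave opened on/before each session date
        pos = np.searchsorted(np.array(open_dates, dtype="datetime64[ns]"),
                              dates.to_numpy(), side="right") - 1
        pos = np.clip(pos, 0, len(waves) - 1)  # backfill before first answered
        out.loc[grp.index, "assigned_isi"] = [waves[p][2] for p in pos]
        out.loc[grp.index, "source_wave"] = [waves[p][0] for p in pos]
    return out


def label_sessions(sessions_with_isi: pd.DataFrame,
                   thresholds: Iterable[int] = RISK_THRESHOLDS,
                   inclusive: bool = True) -> pd.DataFrame:
    """Add one binary risk column per ISI threshold (``label_ge_<t>``)."""
    out = sessions_with_isi.copy()
    for t in thresholds:
        out[f"label_ge_{t}"] = [
            binarize_label(v, t, inclusive) for v in out["assigned_isi"]
        ]
    return out
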