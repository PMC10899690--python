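#!/usr/bin/env python
"""Consolidate presence intervals into sleep sessions and apply the
inclusion filters (>= 3 answered questionnaire waves, >= 120 retained
sessions).  Writes sessions.csv and the inclusion funnel report."""

from pathlib import Path

import somnorisk as sr
from somnorisk.io import read_table
from somnorisk.pipeline import stage_prepare

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 11


def main():
    cohort = sr.CohortConfig(seed=SEED)
    sweep = sr.SweepConfig(seed=SEED)
    stage_prepare(cohort, sweep, ROOT / "cohort", ROOT / "cohort")
    report = read_table(ROOT / "cohort" / "inclusion_report.csv",
                        "inclusion_report")
    sessions = read_table(ROOT / "cohort" / "sessions.csv", "sessions")
    print("inclusion funnel:")
    for row in report.itertuples():
        print(f"  {row.stage}: {row.n_subjects} subjects")
    per_subject = sessions.groupby("subject_id").size()
    print(f"retained {len(sessions)} sessions "
          f"({per_subject.mean():.0f} +/- {per_subject.std():.0f} per subject)")


if __name__ == "__main__":
    main()
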