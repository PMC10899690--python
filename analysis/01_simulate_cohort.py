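#!/usr/bin/env python
"""Simulate the default synthetic smart-bed cohort.

Generates 60 subjects observed over ~160 nights with four ISI questionnaire
waves six weeks apart, and writes the four raw tables (subjects, presence
intervals, nightly physiology, questionnaires) under results/cohort/.
"""

from pathlib import Path

import somnorisk as sr
from somnorisk.pipeline import stage_simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 11


def main():
    cfg = sr.CohortConfig(seed=SEED)
    outputs = stage_simulate(cfg, OUT)
    tabs = {name: path for name, path in outputs.items()}
    print(f"simulated cohort with seed {SEED}:")
    for name, path in tabs.items():
        n = sum(1 for _ in open(path)) - 1
        print(f"  {name}: {n} rows -> {path}")


if __name__ == "__main__":
    main()
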