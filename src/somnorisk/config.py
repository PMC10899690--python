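"""Configuration objects for the synthetic cohort and the evaluation sweep.

Both configs are plain dataclasses with a ``validate`` method; ``load_config``
reads a YAML file holding a ``cohort:`` and/or ``sweep:`` section.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: Default per-feature effect of one ISI point on the session physiology, in
#: the feature's own units.  Signs: worse insomnia lengthens sleep latency,
#: fragments the night (bed exits enter through the split probability, in
#: probability per point), raises motion and heart rate, shortens and degrades
#: sleep, lowers HRV and the quality score, and makes bed times irregular
#: (the ``sri`` entry is extra bed-time jitter in minutes per point).
DEFAULT_SEVERITY_LOADING: dict[str, float] = {
    "time_to_fall_asleep": 1.5,     # min / ISI point
    "bed_exits": 0.006,             # split probability / ISI point
    "percent_motion": 0.004,        # fraction / ISI point
    "heart_rate": 0.45,             # bpm / ISI point
    "restful_frac": -0.004,         # restful fraction / ISI point
    "sleep_duration": -4.0,         # min / ISI point
    "hrv": -1.4,                    # ms / ISI point
    "quality_score": -1.2,          # score points / ISI point
    "sri": 1.2,                     # bed-time jitter min / ISI point
    "breathing_rate": 0.0,
}


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {p!r}")


def _check_positive(name: str, v: float) -> None:
    if v <= 0:
        raise ConfigurationError(f"{name} must be > 0, got {v!r}")


@dataclass
class CohortConfig:
    """Parameters of the synthetic longitudinal cohort.

    The defaults emulate the study conditions: a ~160-day observation window
    (late October through late March), four questionnaire waves opening six
    weeks apart, and wave-1 ISI distributed as 9.65 +/- 5.23.
    """

    n_subjects: int = 60
    study_start_date: dt.date = dt.date(2021, 10, 21)
    study_days: int = 160
    n_waves: int = 4
    wave_spacing_days: int = 42
    wave_response_prob: float = 0.9
    isi_baseline_mean: float = 9.65
    isi_baseline_sd: float = 5.23
    isi_wave_drift_mean: float = -0.25
    isi_wave_drift_sd: float = 5.0
    #: Fraction of subjects whose baseline severity is seeded next to one of
    #: the risk thresholds so that within-study threshold crossings occur
    #: (needed for per-subject AUC to be defined).
    crosser_fraction: float = 0.4
    #: SD (in ISI-equivalent points) of the subject-level offset along the
    #: severity-loading direction; controls pooled non-separability.
    subject_offset_sd: float = 9.0
    severity_loading: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_LOADING)
    )
    noise_sd: float = 1.0  # multiplier on nightly feature noise
    split_night_prob: float = 0.08
    nap_prob: float = 0.05
    night_skip_prob: float = 0.02
    sleep_goal_minutes: int = 480
    gender_other_prob: float = 9.0 / 1489.0
    seed: int = 0

    def validate(self) -> "CohortConfig":
        _check_positive("n_subjects", self.n_subjects)
        _check_positive("study_days", self.study_days)
        _check_positive("wave_spacing_days", self.wave_spacing_days)
        _check_positive("sleep_goal_minutes", self.sleep_goal_minutes)
        if self.n_waves < 1:
            raise ConfigurationError(f"n_waves must be >= 1, got {self.n_waves}")
        for name in ("wave_response_prob", "split_night_prob", "nap_prob",
                     "night_skip_prob", "crosser_fraction", "gender_other_prob"):
            _check_prob(name, getattr(self, name))
        for name in ("isi_baseline_sd", "isi_wave_drift_sd",
                     "subject_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not isinstance(self.study_start_date, dt.date):
            raise ConfigurationError("study_start_date must be a date")
        return self

    def wave_dates(self) -> list[dt.date]:
        """Opening (administration) date of each questionnaire wave."""
        return [
            self.study_start_date + dt.timedelta(days=(w - 1) * self.wave_spacing_days)
            for w in range(1, self.n_waves + 1)
        ]


@dataclass
class SweepConfig:
    """Parameters of the leave-one-subject-out personalization sweep."""

    thresholds: tuple[int, ...] = (8, 10, 15)
    intervals: tuple[int, ...] = (0, 1, 5, 10, 20, 30, 40, 50, 60)
    aggressiveness_c: float = 1.0
    variant: str = "PA-I"
    epochs: int = 5
    inclusive_threshold: bool = True
    aggregation_mode: str = "pooled"   # or "per_subject"
    min_sessions: int = 120
    min_questionnaires: int = 3
    seed: int = 0

    def validate(self) -> "SweepConfig":
        ivs = tuple(self.intervals)
        if len(ivs) == 0 or ivs[0] != 0:
            raise ConfigurationError("intervals must start at 0")
        if any(b <= a for a, b in zip(ivs, ivs[1:])):
            raise ConfigurationError("intervals must be strictly increasing")
        _check_positive("aggressiveness_c", self.aggressiveness_c)
        _check_positive("epochs", self.epochs)
        if self.variant not in ("PA-I", "PA-II"):
            raise ConfigurationError(f"unknown PA variant {self.variant!r}")
        if self.aggregation_mode not in ("pooled", "per_subject"):
            raise ConfigurationError(
                f"unknown aggregation_mode {self.aggregation_mode!r}")
        if any(t < 0 or t > 28 for t in self.thresholds):
            raise ConfigurationError("ISI thresholds must lie in [0, 28]")
        return self


def _coerce(cls, data: Mapping) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    out = dict(data)
    if "study_start_date" in out and isinstance(out["study_start_date"], str):
        out["study_start_date"] = dt.date.fromisoformat(out["study_start_date"])
    for tup_key in ("thresholds", "intervals"):
        if tup_key in out:
            out[tup_key] = tuple(out[tup_key])
    return out


def load_config(path) -> tuple[CohortConfig, SweepConfig]:
    """Read ``cohort:`` / ``sweep:`` sections from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = CohortConfig(**_coerce(CohortConfig, raw.get("cohort", {}))).validate()
    sweep = SweepConfig(**_coerce(SweepConfig, raw.get("sweep", {}))).validate()
    return cohort, sweep


def config_to_dict(cfg) -> dict:
    """JSON/YAML-serializable snapshot of a config dataclass."""
    out = dataclasses.asdict(cfg)
    for k, v in out.items():
        if isinstance(v, dt.date):
            out[k] = v.isoformat()
        elif isinstance(v, tuple):
            out[k] = list(v)
    return out
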