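"""Shared fixtures: the default study cohort and its evaluation sweeps.

The heavy artifacts (60-subject cohort, LOOCV sweep, chronology-randomized
control) are session-scoped so the whole suite pays for them once.
"""

import pytest
from hypothesis import HealthCheck, settings

import somnorisk as sr
from somnorisk.cohort import generate_cohort
from somnorisk.labeling import assign_session_isi, label_sessions
from somnorisk.sessions import apply_inclusion_filters, build_sessions

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

#: Seed pinning the default study conditions for the structural checks.
DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    """Default 60-subject synthetic cohort (fixed seed) with its config."""
    cfg = sr.CohortConfig(seed=DEFAULT_SEED)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def labeled_default(default_cohort):
    """Filtered, ISI-labeled session table of the default cohort."""
    cfg, tabs = default_cohort
    sess = build_sessions(tabs.presence_intervals, tabs.session_physiology,
                          tabs.subjects, cfg.study_start_date, cfg.study_days)
    kept, report = apply_inclusion_filters(sess, tabs.questionnaires,
                                           tabs.subjects)
    quest = tabs.questionnaires[
        tabs.questionnaires.subject_id.isin(kept.subject_id)]
    labeled = label_sessions(assign_session_isi(kept, quest, cfg.wave_dates()))
    return cfg, labeled


@pytest.fixture(scope="session")
def default_sweep(labeled_default):
    """Full LOOCV personalization sweep on the default cohort."""
    _, labeled = labeled_default
    cfg = sr.SweepConfig(seed=DEFAULT_SEED)
    return cfg, sr.loocv_personalization_sweep(labeled, cfg)


@pytest.fixture(scope="session")
def randomized_sweep(labeled_default):
    """Chronology-randomized control sweep on the default cohort."""
    _, labeled = labeled_default
    cfg = sr.SweepConfig(seed=DEFAULT_SEED)
    return cfg, sr.randomize_chronology_experiment(labeled, cfg,
                                                   seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def small_labeled_cohort():
    """A small, quick cohort for interface-level evaluation tests."""
    cfg = sr.CohortConfig(n_subjects=10, study_days=60, seed=5)
    tabs = generate_cohort(cfg)
    sess = build_sessions(tabs.presence_intervals, tabs.session_physiology,
                          tabs.subjects, cfg.study_start_date, cfg.study_days)
    kept, _ = apply_inclusion_filters(sess, tabs.questionnaires, tabs.subjects,
                                      min_sessions=40)
    quest = tabs.questionnaires[
        tabs.questionnaires.subject_id.isin(kept.subject_id)]
    labeled = label_sessions(assign_session_isi(kept, quest, cfg.wave_dates()))
    return cfg, labeled
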