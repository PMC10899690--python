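"""Session construction: consolidation, daily selection, SRI, features, filters."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import somnorisk as sr
from somnorisk.errors import DataError
from somnorisk.sessions import (FEATURE_ORDER, add_sri,
                                apply_inclusion_filters, build_feature_vector,
                                compute_sleep_debt, compute_sri,
                                consolidate_sessions, select_longest_per_day)


def _iv(sid, *pairs):
    rows = [{"subject_id": sid, "start": pd.Timestamp(s), "end": pd.Timestamp(e)}
            for s, e in pairs]
    return pd.DataFrame(rows)


class TestConsolidation:
    def test_short_gap_merges_and_counts_one_bed_exit(self):
        spans = consolidate_sessions(_iv(
            "a", ("2022-01-01 22:00", "2022-01-01 23:00"),
            ("2022-01-01 23:30", "2022-01-02 06:00")))
        assert len(spans) == 1
        assert spans.loc[0, "bed_exits"] == 1
        assert spans.loc[0, "session_duration"] == 60 + 390  # gaps excluded

    def test_gap_over_two_hours_splits(self):
        spans = consolidate_sessions(_iv(
            "a", ("2022-01-01 22:00", "2022-01-01 23:00"),
            ("2022-01-02 01:30", "2022-01-02 06:00")))
        assert len(spans) == 2
        assert (spans["bed_exits"] == 0).all()

    def test_exactly_two_hour_gap_still_merges(self):
        spans = consolidate_sessions(_iv(
            "a", ("2022-01-01 22:00", "2022-01-01 23:00"),
            ("2022-01-02 01:00", "2022-01-02 06:00")))
        assert len(spans) == 1 and spans.loc[0, "bed_exits"] == 1

    def test_empty_input(self):
        assert len(consolidate_sessions(_iv("a"))) == 0

    def test_overlap_is_a_data_error_naming_the_subject(self):
        with pytest.raises(DataError, match="a"):
            consolidate_sessions(_iv(
                "a", ("2022-01-01 22:00", "2022-01-02 01:00"),
                ("2022-01-02 00:30", "2022-01-02 06:00")))

    def test_session_date_is_the_end_date(self):
        spans = consolidate_sessions(_iv(
            "a", ("2022-01-01 22:00", "2022-01-02 06:00")))
        assert spans.loc[0, "session_date"] == pd.Timestamp("2022-01-02")

    @given(st.lists(
        st.tuples(st.integers(0, 80), st.integers(1, 12)), min_size=1,
        max_size=8))
    def test_idempotent_and_preserves_in_bed_time(self, chunks):
        # build non-overlapping intervals from (gap, duration) hour chunks
        t = pd.Timestamp("2022-01-01")
        rows = []
        for gap_h, dur_h in chunks:
            t = t + pd.Timedelta(hours=gap_h + 1)
            rows.append(("s", t, t + pd.Timedelta(hours=dur_h)))
            t = t + pd.Timedelta(hours=dur_h)
        df = pd.DataFrame(rows, columns=["subject_id", "start", "end"])
        spans = consolidate_sessions(df)
        total_in_bed = (df["end"] - df["start"]).dt.total_seconds().sum() / 60
        assert spans["session_duration"].sum() == pytest.approx(total_in_bed)
        assert spans["bed_exits"].sum() == len(df) - len(spans)
        again = consolidate_sessions(
            spans[["subject_id", "start", "end"]])
        assert len(again) == len(spans)
        pd.testing.assert_series_equal(again["start"], spans["start"])
        pd.testing.assert_series_equal(again["end"], spans["end"])


class TestLongestPerDay:
    def _spans(self, *rows):
        df = pd.DataFrame(rows, columns=["subject_id", "start", "end",
                                         "session_date", "session_duration",
                                         "bed_exits"])
        df["session_date"] = pd.to_datetime(df["session_date"])
        return df

    def test_longest_kept(self):
        spans = self._spans(
            ("a", pd.Timestamp("2022-01-01 23:00"), pd.Timestamp("2022-01-02 06:00"), "2022-01-02", 420.0, 0),
            ("a", pd.Timestamp("2022-01-02 13:00"), pd.Timestamp("2022-01-02 13:35"), "2022-01-02", 35.0, 0))
        kept = select_longest_per_day(spans)
        assert len(kept) == 1 and kept.loc[0, "session_duration"] == 420.0

    def test_single_span_identity(self):
        spans = self._spans(("a", pd.Timestamp("2022-01-01 23:00"),
                             pd.Timestamp("2022-01-02 06:00"), "2022-01-02",
                             420.0, 0))
        pd.testing.assert_frame_equal(select_longest_per_day(spans), spans)

    def test_duration_tie_keeps_earlier_start(self):
        spans = self._spans(
            ("a", pd.Timestamp("2022-01-02 14:00"), pd.Timestamp("2022-01-02 15:00"), "2022-01-02", 60.0, 0),
            ("a", pd.Timestamp("2022-01-02 05:00"), pd.Timestamp("2022-01-02 06:00"), "2022-01-02", 60.0, 0))
        kept = select_longest_per_day(spans)
        assert kept.loc[0, "start"] == pd.Timestamp("2022-01-02 05:00")

    def test_at_most_one_session_per_subject_day(self, default_cohort):
        _, tabs = default_cohort
        kept = select_longest_per_day(
            consolidate_sessions(tabs.presence_intervals))
        assert not kept.duplicated(["subject_id", "session_date"]).any()


class TestSleepDebt:
    @pytest.mark.parametrize("goal,dur,expected",
                             [(480, 420, 60), (480, 500, 0), (480, 480, 0)])
    def test_positive_part(self, goal, dur, expected):
        assert compute_sleep_debt(goal, dur) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(DataError):
            compute_sleep_debt(-1, 400)


class TestSRI:
    def test_identical_days_give_100(self):
        day = np.zeros(1440, dtype=bool)
        day[60:480] = True
        assert compute_sri(np.vstack([day, day])) == 100.0

    def test_antiphase_days_give_minus_100(self):
        day = np.zeros(1440, dtype=bool)
        day[:720] = True
        assert compute_sri(np.vstack([day, ~day])) == -100.0

    def test_independent_coin_states_average_near_zero(self):
        rng = np.random.default_rng(42)
        states = rng.integers(0, 2, size=(11, 1000))  # 10,000 epoch pairs
        assert abs(compute_sri(states, window_days=11)) < 3.0

    def test_bounded_and_relabeling_invariant(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 2, size=(6, 200))
        v = compute_sri(states)
        assert -100.0 <= v <= 100.0
        relabeled = np.where(states == 0, "wake", "sleep")
        assert compute_sri(relabeled) == v

    def test_insufficient_history_is_nan(self):
        assert np.isnan(compute_sri(np.zeros((1, 1440), dtype=bool)))

    def test_pipeline_sri_imputes_early_sessions(self, default_cohort):
        cfg, tabs = default_cohort
        sess = select_longest_per_day(
            consolidate_sessions(tabs.presence_intervals))
        merged = sess.merge(tabs.session_physiology,
                            on=["subject_id", "session_date"])
        out = add_sri(merged, cfg.study_start_date, cfg.study_days)
        assert out["sri"].notna().all()
        assert out["sri"].between(-100, 100).all()


class TestFeatureVector:
    session = dict(bed_exits=1, breathing_rate=14.0, heart_rate=60.0,
                   hrv=50.0, percent_motion=0.1, restful_duration=350.0,
                   session_duration=480.0, sleep_debt=0.0,
                   sleep_duration=420.0, quality_score=75.0, sri=80.0,
                   time_to_fall_asleep=15.0)
    subject = dict(age=50.0, gender="female", sleep_goal=480)

    def test_fourteen_components_in_canonical_order(self):
        vec = build_feature_vector(self.session, self.subject)
        assert vec.shape == (14,)
        assert vec[list(FEATURE_ORDER).index("age")] == 50.0
        assert vec[list(FEATURE_ORDER).index("gender_encoded")] == 1.0
        assert vec[list(FEATURE_ORDER).index("sleep_duration")] == 420.0

    def test_pure_function(self):
        a = build_feature_vector(self.session, self.subject)
        b = build_feature_vector(self.session, self.subject)
        assert np.array_equal(a, b)

    def test_sleep_debt_positive_part_flows_through(self):
        sess = dict(self.session,
                    sleep_debt=compute_sleep_debt(480, 500))
        vec = build_feature_vector(sess, self.subject)
        assert vec[list(FEATURE_ORDER).index("sleep_debt")] == 0.0

    def test_missing_component_error_names_it(self):
        sess = dict(self.session)
        del sess["hrv"]
        with pytest.raises(DataError, match="hrv"):
            build_feature_vector(sess, self.subject)

    def test_gender_other_gets_configurable_midpoint(self):
        vec = build_feature_vector(self.session,
                                   dict(self.subject, gender="other"))
        assert vec[list(FEATURE_ORDER).index("gender_encoded")] == 0.5


class TestInclusionFilters:
    @staticmethod
    def _cohort(n_sessions, n_waves, sid="a"):
        dates = pd.date_range("2021-10-22", periods=n_sessions, freq="D")
        sessions = pd.DataFrame({"subject_id": sid, "session_date": dates})
        quest = pd.DataFrame({"subject_id": sid,
                              "wave_index": list(range(1, n_waves + 1))})
        subjects = pd.DataFrame({"subject_id": [sid]})
        return sessions, quest, subjects

    def test_119_sessions_excluded(self):
        kept, _ = apply_inclusion_filters(*self._cohort(119, 4))
        assert len(kept) == 0

    def test_120_sessions_3_waves_included(self):
        kept, report = apply_inclusion_filters(*self._cohort(120, 3))
        assert kept["subject_id"].nunique() == 1
        assert report.loc[2, "n_subjects"] == 1

    def test_two_waves_excluded_despite_many_sessions(self):
        kept, _ = apply_inclusion_filters(*self._cohort(150, 2))
        assert len(kept) == 0

    def test_empty_cohort_reports_zero_counts(self):
        s, q, subj = self._cohort(0, 0)
        kept, report = apply_inclusion_filters(
            s.iloc[:0], q.iloc[:0], subj.iloc[:0])
        assert len(kept) == 0 and (report["n_subjects"] == 0).all()

    def test_loosening_thresholds_never_shrinks_retained_set(
            self, default_cohort):
        cfg, tabs = default_cohort
        sess = select_longest_per_day(
            consolidate_sessions(tabs.presence_intervals))
        strict, _ = apply_inclusion_filters(
            sess, tabs.questionnaires, tabs.subjects,
            min_sessions=150, min_questionnaires=4)
        loose, _ = apply_inclusion_filters(
            sess, tabs.questionnaires, tabs.subjects,
            min_sessions=120, min_questionnaires=3)
        assert set(strict["subject_id"]) <= set(loose["subject_id"])


def test_built_sessions_satisfy_domain_invariants(labeled_default):
    _, labeled = labeled_default
    assert (labeled["sleep_duration"] <= labeled["session_duration"] + 1e-9).all()
    assert (labeled["restful_duration"] <= labeled["sleep_duration"] + 1e-9).all()
    assert (labeled["sleep_debt"] >= 0).all()
    assert labeled["percent_motion"].between(0, 1).all()
    assert labeled["sri"].between(-100, 100).all()
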