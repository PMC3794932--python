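"""Event detection, window anchoring, eligibility and exclusion rules."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

import pandas as pd

import pacekit as pk
from helpers import admission, cohort, day, dx, lab


def _labs(values, start_day=4, analyte="potassium"):
    return [lab("P1", "A1", analyte, v, start_day + i) for i, v in enumerate(values)]


class TestThresholdDetection:
    def test_strictly_greater_than_threshold(self):
        c = cohort(labs=_labs([5.4, 5.6]), admissions=[admission("P1", "A1", 0, 20)])
        events = pk.detect_lab_threshold_events(c.labs, "potassium", 5.5)
        assert len(events) == 1
        assert events[0].index_date == pd.Timestamp(day(5))
        assert events[0].severity_value == 5.6

    def test_value_equal_to_threshold_is_not_an_event(self):
        c = cohort(labs=_labs([5.5]), admissions=[admission("P1", "A1", 0, 20)])
        assert pk.detect_lab_threshold_events(c.labs, "potassium", 5.5) == []

    def test_each_crossing_counts_separately(self):
        c = cohort(labs=_labs([5.6, 5.6, 5.6]), admissions=[admission("P1", "A1", 0, 20)])
        events = pk.detect_lab_threshold_events(c.labs, "potassium", 5.5)
        assert len(events) == 3
        assert len({e.index_date for e in events}) == 3

    def test_nominal_analyte_raises_type_error(self):
        c = cohort(
            labs=[lab("P1", "A1", "cdiff_toxin", "positive", 8, order=5)],
            admissions=[admission("P1", "A1", 0, 20)],
        )
        with pytest.raises(TypeError, match="quantitative"):
            pk.detect_lab_threshold_events(c.labs, "cdiff_toxin", 5.5)

    @given(
        values=st.lists(st.floats(min_value=3.0, max_value=8.0), max_size=12),
        t1=st.floats(min_value=4.0, max_value=7.0),
        delta=st.floats(min_value=0.0, max_value=2.0),
    )
    def test_event_count_monotone_nonincreasing_in_threshold(self, values, t1, delta):
        c = cohort(labs=_labs(values), admissions=[admission("P1", "A1", 0, 40)])
        lo = pk.detect_lab_threshold_events(c.labs, "potassium", t1)
        hi = pk.detect_lab_threshold_events(c.labs, "potassium", t1 + delta)
        assert len(hi) <= len(lo)


class TestOrderAndResultEvents:
    def test_order_and_positive_result_events(self):
        c = cohort(
            labs=[lab("P1", "A1", "cdiff_toxin", "positive", 13, order=10)],
            admissions=[admission("P1", "A1", 0, 20)],
        )
        events = pk.detect_order_and_result_events(c.labs, "cdiff_toxin")
        kinds = {e.event_kind: e.index_date for e in events}
        assert kinds == {
            "test_order": pd.Timestamp(day(10)),
            "test_result_positive": pd.Timestamp(day(13)),
        }

    def test_negative_result_maps_to_negative_kind(self):
        c = cohort(
            labs=[lab("P1", "A1", "cdiff_toxin", "negative", 13, order=10)],
            admissions=[admission("P1", "A1", 0, 20)],
        )
        kinds = [e.event_kind for e in pk.detect_order_and_result_events(c.labs, "cdiff_toxin")]
        assert "test_result_negative" in kinds

    def test_unusable_result_token_skipped_with_warning(self):
        c = cohort(
            labs=[
                lab("P1", "A1", "cdiff_toxin", "positive", 13, order=10),
                lab("P1", "A1", "cdiff_toxin", 1.0, 15, order=12),  # numeric: no token
            ],
            admissions=[admission("P1", "A1", 0, 20)],
        )
        with pytest.warns(UserWarning, match="no usable"):
            events = pk.detect_order_and_result_events(c.labs, "cdiff_toxin")
        assert len(events) == 2  # only the usable record contributes

    def test_order_without_result_date_yields_result_event_only_at_result(self):
        # a record with a result but no order date yields just the result event
        c = cohort(
            labs=[lab("P1", "A1", "cdiff_toxin", "positive", 13)],
            admissions=[admission("P1", "A1", 0, 20)],
        )
        events = pk.detect_order_and_result_events(c.labs, "cdiff_toxin")
        assert [e.event_kind for e in events] == ["test_result_positive"]

    def test_before_order_events_shift_index(self):
        c = cohort(
            labs=[lab("P1", "A1", "cdiff_toxin", "positive", 13, order=10)],
            admissions=[admission("P1", "A1", 0, 20)],
        )
        events = pk.events.detect_before_order_events(c.labs, "cdiff_toxin", days_before=5)
        assert len(events) == 1
        assert events[0].index_date == pd.Timestamp(day(5))


def _event(d, aid="A1", pid="P1"):
    return pk.ClinicalEvent(pid, aid, "lab_threshold", pd.Timestamp(day(d)), "potassium", 6.0)


class TestAdmissionEligibility:
    @pytest.mark.parametrize(
        "event_day,expected,reason",
        [
            (3, False, "too_early"),  # admit+3
            (4, True, None),  # admit+4: first eligible day
            (19, True, None),  # discharge-1: last eligible day
            (20, False, "too_late"),  # discharge day
        ],
    )
    def test_window_must_fit_hospitalization(self, event_day, expected, reason):
        c = cohort(admissions=[admission("P1", "A1", 0, 20)])
        (w,) = pk.apply_admission_eligibility([_event(event_day)], c.admissions)
        assert w.eligible is expected
        if reason:
            assert reason in w.exclusion_reasons

    def test_unknown_admission_raises(self):
        c = cohort(admissions=[admission("P1", "A1", 0, 20)])
        with pytest.raises(KeyError, match="A9"):
            pk.apply_admission_eligibility([_event(5, aid="A9")], c.admissions)


class TestBaselineExclusion:
    def _windows(self, baseline_values):
        c = cohort(
            labs=[lab("P1", "A1", "potassium", v, 1 + i) for i, v in enumerate(baseline_values)]
            + [lab("P1", "A1", "potassium", 6.0, 10)],
            admissions=[admission("P1", "A1", 0, 20)],
        )
        windows = pk.apply_admission_eligibility([_event(10)], c.admissions)
        return pk.apply_baseline_exclusion(windows, c.labs, "potassium", 5.5)

    def test_abnormal_baseline_excluded(self):
        (w,) = self._windows([5.8, 4.0])
        assert not w.eligible and "abnormal_baseline" in w.exclusion_reasons

    def test_normal_baseline_kept(self):
        (w,) = self._windows([4.0, 5.8])  # first value decides
        assert w.eligible

    def test_missing_baseline_kept_but_flagged(self):
        c = cohort(
            labs=[lab("P2", "A2", "potassium", 4.0, 1)],
            admissions=[admission("P1", "A1", 0, 20), admission("P2", "A2", 0, 20)],
        )
        windows = pk.apply_admission_eligibility([_event(10)], c.admissions)
        (w,) = pk.apply_baseline_exclusion(windows, c.labs, "potassium", 5.5)
        assert w.eligible and "no_baseline" in w.flags


class TestDiagnosisExclusion:
    def test_prefix_match_excludes_patient(self):
        c = cohort(
            admissions=[admission("P1", "A1", 0, 20)], diagnoses=[dx("P1", "N18.5")]
        )
        windows = pk.apply_admission_eligibility([_event(10)], c.admissions)
        (w,) = pk.apply_diagnosis_exclusion(windows, c.diagnoses, ["N18"])
        assert not w.eligible and "excluded_diagnosis" in w.exclusion_reasons

    def test_empty_prefix_list_disables_filter(self):
        c = cohort(
            admissions=[admission("P1", "A1", 0, 20)], diagnoses=[dx("P1", "N18.5")]
        )
        windows = pk.apply_admission_eligibility([_event(10)], c.admissions)
        (w,) = pk.apply_diagnosis_exclusion(windows, c.diagnoses, [])
        assert w.eligible

    def test_mixed_cohort_counts(self):
        admissions = [admission(f"P{i}", f"A{i}", 0, 20) for i in range(5)]
        diagnoses = [dx("P0", "N18.5"), dx("P2", "I12.0"), dx("P3", "E11.9")]
        events = [_event(10, aid=f"A{i}", pid=f"P{i}") for i in range(5)]
        c = cohort(admissions=admissions, diagnoses=diagnoses)
        windows = pk.apply_admission_eligibility(events, c.admissions)
        out = pk.apply_diagnosis_exclusion(windows, c.diagnoses, ["N18", "I12.0"])
        assert sum(1 for w in out if not w.eligible) == 2


class TestFilterComposition:
    def _scenario(self):
        c = cohort(
            labs=[lab("P1", "A1", "potassium", 5.9, 0), lab("P2", "A2", "potassium", 4.0, 0)],
            admissions=[admission("P1", "A1", 0, 20), admission("P2", "A2", 0, 20)],
            diagnoses=[dx("P2", "N18.5")],
        )
        events = [
            _event(2),  # too early and abnormal baseline
            _event(10),  # abnormal baseline only
            _event(10, aid="A2", pid="P2"),  # diagnosis-excluded
            _event(20, aid="A2", pid="P2"),  # too late and diagnosis-excluded
        ]
        return c, events

    def test_partition_is_preserved_by_each_filter(self):
        c, events = self._scenario()
        windows = pk.apply_admission_eligibility(events, c.admissions)
        assert len(windows) == len(events)
        for step in (
            lambda ws: pk.apply_baseline_exclusion(ws, c.labs, "potassium", 5.5),
            lambda ws: pk.apply_diagnosis_exclusion(ws, c.diagnoses, ["N18"]),
        ):
            new = step(windows)
            assert len(new) == len(windows)
            for before, after in zip(windows, new):
                # filters only ever flip eligible -> ineligible
                assert set(before.exclusion_reasons) <= set(after.exclusion_reasons)
            windows = new

    def test_eligible_set_independent_of_filter_order(self):
        c, events = self._scenario()
        base = pk.apply_admission_eligibility(events, c.admissions)
        filters = {
            "baseline": lambda ws: pk.apply_baseline_exclusion(ws, c.labs, "potassium", 5.5),
            "diagnosis": lambda ws: pk.apply_diagnosis_exclusion(ws, c.diagnoses, ["N18"]),
        }
        outcomes = []
        for order in itertools.permutations(filters):
            ws = base
            for name in order:
                ws = filters[name](ws)
            outcomes.append([w.eligible for w in ws])
        assert all(o == outcomes[0] for o in outcomes)


def test_min_event_gap_thins_consecutive_events():
    events = [_event(10), _event(11), _event(13)]
    assert len(pk.events.dedupe_events(events, 0)) == 3
    kept = pk.events.dedupe_events(events, 3)
    assert [e.index_date.day for e in kept] == [pd.Timestamp(day(10)).day,
                                                pd.Timestamp(day(13)).day]


def test_extract_windows_pipeline_end_to_end():
    c = cohort(
        labs=[
            lab("P1", "A1", "potassium", 4.0, 1),
            lab("P1", "A1", "potassium", 5.8, 10),
            lab("P1", "A1", "potassium", 6.2, 12),
        ],
        admissions=[admission("P1", "A1", 0, 20)],
    )
    windows = pk.extract_windows(c, pk.EventConfig())
    assert len(windows) == 2
    assert all(w.eligible for w in windows)
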