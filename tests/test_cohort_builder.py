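from datetime import date, timedelta

import numpy as np
import pytest

from textps.cohort_builder import (
    build_episodes,
    detect_drug_mentions,
    episodes_from_frame,
    episodes_to_frame,
    prescription_duration,
)

from conftest import ATC_MAP, LEXICON, make_record, random_patients
from oracles import day_by_day_episodes

CLASS_OF = {code: label for label, codes in ATC_MAP.items() for code in codes}


class TestPrescriptionDuration:
    def test_direct_division(self):
        assert prescription_duration(30, 1) == 30
        assert prescription_duration(60, 2) == 30

    def test_round_half_up(self):
        assert prescription_duration(20, 3) == 7  # 6.67 rounds to 7
        assert prescription_duration(13, 2) == 7  # 6.5 rounds up
        assert prescription_duration(19, 3) == 6  # 6.33 rounds down

    def test_clamp_to_one_day(self):
        assert prescription_duration(1, 3) == 1

    @pytest.mark.parametrize("q,dd", [(0, 1), (-5, 1), (30, 0), (30, -2)])
    def test_nonpositive_rejected(self, q, dd):
        with pytest.raises(ValueError):
            prescription_duration(q, dd)


class TestDetectDrugMentions:
    def test_case_insensitive_hit(self):
        notes = [(date(2001, 5, 1), "patient kreeg Ibuprofen")]
        assert detect_drug_mentions(notes, {"ibuprofen"}, date(2001, 1, 1), date(2001, 7, 1))

    def test_boundary_day_before_window(self):
        notes = [(date(2001, 1, 1), "ibuprofen")]
        # window opens the next day; mention one day earlier must not count
        assert not detect_drug_mentions(notes, {"ibuprofen"}, date(2001, 1, 2), date(2001, 7, 1))
        # window end is exclusive
        assert not detect_drug_mentions(notes, {"ibuprofen"}, date(2000, 7, 1), date(2001, 1, 1))

    def test_other_drug_not_matched(self):
        notes = [(date(2001, 5, 1), "gebruik van ibuprofen")]
        assert not detect_drug_mentions(notes, {"naproxen"}, date(2001, 1, 1), date(2001, 7, 1))

    def test_empty_notes(self):
        assert not detect_drug_mentions([], {"ibuprofen"}, date(2001, 1, 1), date(2001, 7, 1))


class TestBuildEpisodesRules:
    def test_continuation_rule(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AE01", 30, 1), ("2002-01-26", "M01AE01", 30, 1)]
        )
        eps = build_episodes([rec], ATC_MAP)
        assert len(eps) == 1
        assert eps[0].start_date == date(2002, 1, 1)
        assert eps[0].end_date == date(2002, 2, 25)  # day 55
        assert eps[0].class_label == "NSNSAID"

    def test_washout_violated_no_second_episode(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AE01", 30, 1), ("2002-03-12", "M01AE01", 30, 1)]
        )
        eps = build_episodes([rec], ATC_MAP)
        assert len(eps) == 1
        assert (eps[0].start_date, eps[0].end_date) == (date(2002, 1, 1), date(2002, 1, 31))

    def test_switch_truncates(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AE01", 30, 1), ("2002-01-11", "M01AH01", 30, 1)]
        )
        eps = build_episodes([rec], ATC_MAP)
        assert len(eps) == 1
        assert eps[0].class_label == "NSNSAID"
        assert eps[0].end_date == date(2002, 1, 11)
        assert eps[0].follow_up_days == 10

    def test_free_text_mention_blocks_episode(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AE01", 30, 1)],
            notes=[("2001-12-01", "patient kreeg Ibuprofen")],
        )
        assert build_episodes([rec], ATC_MAP, LEXICON) == []

    def test_mention_before_window_does_not_block(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AE01", 30, 1)],
            notes=[("2001-07-01", "patient kreeg Ibuprofen")],  # window opens 07-02
        )
        assert len(build_episodes([rec], ATC_MAP, LEXICON)) == 1

    def test_underage_excluded(self):
        rec = make_record(birth_year=1990, rx=[("2002-01-01", "M01AE01", 30, 1)])
        assert build_episodes([rec], ATC_MAP) == []

    def test_short_enrollment_excluded(self):
        rec = make_record(start="2001-09-01", rx=[("2002-01-01", "M01AE01", 30, 1)])
        assert build_episodes([rec], ATC_MAP) == []

    def test_same_day_both_classes_no_episode(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AE01", 30, 1), ("2002-01-01", "M01AH01", 30, 1)]
        )
        assert build_episodes([rec], ATC_MAP) == []

    def test_event_attachment_and_censoring(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AH01", 60, 2)], events=["2002-01-15"]
        )
        eps = build_episodes([rec], ATC_MAP)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.event and ep.outcome_date == date(2002, 1, 15)
        assert ep.follow_up_days == 14
        assert ep.end_date == date(2002, 1, 31)

    def test_event_outside_episode_ignored(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AH01", 30, 1)], events=["2002-06-01"]
        )
        eps = build_episodes([rec], ATC_MAP)
        assert not eps[0].event
        assert eps[0].outcome_date is None

    def test_second_episode_after_clean_washout(self):
        rec = make_record(
            rx=[("2002-01-01", "M01AE01", 20, 3), ("2002-09-01", "M01AE01", 30, 1)]
        )
        eps = build_episodes([rec], ATC_MAP)
        assert len(eps) == 2
        assert eps[0].end_date == date(2002, 1, 8)  # 20/3 -> 7 days
        assert eps[1].start_date == date(2002, 9, 1)

    def test_unknown_nsaid_code_warned_and_skipped(self, caplog):
        rec = make_record(rx=[("2002-01-01", "M01AX99", 30, 1)])
        with caplog.at_level("WARNING"):
            assert build_episodes([rec], ATC_MAP) == []
        assert "M01AX99" in caplog.text

    def test_non_nsaid_code_silently_ignored(self, caplog):
        rec = make_record(
            rx=[("2002-01-01", "N02BE01", 30, 1), ("2002-01-01", "M01AE01", 30, 1)]
        )
        with caplog.at_level("WARNING"):
            eps = build_episodes([rec], ATC_MAP)
        assert len(eps) == 1
        assert "N02BE01" not in caplog.text


HAND_FIXTURE = [
    make_record(pid="H0", rx=[("2002-01-01", "M01AE01", 30, 1), ("2002-01-26", "M01AE01", 30, 1)]),
    make_record(pid="H1", rx=[("2002-01-01", "M01AE01", 30, 1), ("2002-03-12", "M01AE01", 30, 1)]),
    make_record(pid="H2", rx=[("2002-01-01", "M01AE01", 30, 1), ("2002-01-11", "M01AH01", 30, 1)]),
    make_record(pid="H3", rx=[("2002-01-01", "M01AE01", 30, 1)],
                notes=[("2001-12-01", "patient kreeg Ibuprofen")]),
    make_record(pid="H4", rx=[("2002-01-01", "M01AE01", 30, 1)],
                notes=[("2001-07-01", "patient kreeg Ibuprofen")]),
    make_record(pid="H5", birth_year=1990, rx=[("2002-01-01", "M01AE01", 30, 1)]),
    make_record(pid="H6", start="2001-09-01", rx=[("2002-01-01", "M01AE01", 30, 1)]),
    make_record(pid="H7", rx=[("2002-01-01", "M01AE01", 30, 1), ("2002-01-01", "M01AH01", 30, 1)]),
    make_record(pid="H8", rx=[("2002-01-01", "M01AH01", 60, 2)], events=["2002-01-15"]),
    make_record(pid="H9", rx=[("2002-01-01", "M01AE01", 20, 3), ("2002-09-01", "M01AE01", 30, 1)]),
]

# (patient_id, class, start, end, outcome, event, follow_up_days)
HAND_EXPECTED = [
    ("H0", "NSNSAID", "2002-01-01", "2002-02-25", None, False, 55),
    ("H1", "NSNSAID", "2002-01-01", "2002-01-31", None, False, 30),
    ("H2", "NSNSAID", "2002-01-01", "2002-01-11", None, False, 10),
    ("H4", "NSNSAID", "2002-01-01", "2002-01-31", None, False, 30),
    ("H8", "COX2", "2002-01-01", "2002-01-31", "2002-01-15", True, 14),
    ("H9", "NSNSAID", "2002-01-01", "2002-01-08", None, False, 7),
    ("H9", "NSNSAID", "2002-09-01", "2002-10-01", None, False, 30),
]


def test_hand_fixture_expected_table():
    eps = build_episodes(HAND_FIXTURE, ATC_MAP, LEXICON)
    got = [
        (
            e.patient_id,
            e.class_label,
            e.start_date.isoformat(),
            e.end_date.isoformat(),
            e.outcome_date.isoformat() if e.outcome_date else None,
            e.event,
            e.follow_up_days,
        )
        for e in eps
    ]
    assert got == HAND_EXPECTED


@pytest.fixture(scope="module")
def random_eps():
    rng = np.random.default_rng(77)
    records = random_patients(rng, 120)
    return records, build_episodes(records, ATC_MAP, LEXICON)


class TestProperties:

    def test_no_overlapping_episodes_per_patient(self, random_eps):
        _, eps = random_eps
        by_pid = {}
        for e in eps:
            by_pid.setdefault(e.patient_id, []).append(e)
        for group in by_pid.values():
            group.sort(key=lambda e: e.start_date)
            for a, b in zip(group, group[1:]):
                assert a.end_date <= b.start_date

    def test_washout_clear_before_each_start(self, random_eps):
        records, eps = random_eps
        recs = {r.patient_id: r for r in records}
        for e in eps:
            r = recs[e.patient_id]
            lo = e.start_date - timedelta(days=183)
            for p in r.prescriptions:
                if p.atc_code in CLASS_OF:
                    assert not (lo <= p.date < e.start_date)

    def test_age_and_enrollment_invariants(self, random_eps):
        records, eps = random_eps
        recs = {r.patient_id: r for r in records}
        for e in eps:
            assert e.age_at_start >= 18
            assert (e.start_date - recs[e.patient_id].enrollment_start).days >= 365
            assert e.start_date <= e.end_date
            assert e.follow_up_days >= 0
            if e.event:
                assert e.start_date <= e.outcome_date <= e.end_date

    def test_empty_lexicon_never_decreases_episode_count(self, random_eps):
        records, eps = random_eps
        eps_no_lex = build_episodes(records, ATC_MAP, frozenset())
        assert len(eps_no_lex) >= len(eps)

    def test_episode_ids_unique(self, random_eps):
        _, eps = random_eps
        ids = [e.episode_id for e in eps]
        assert len(set(ids)) == len(ids)


def test_oracle_equivalence_random_streams():
    rng = np.random.default_rng(123)
    records = random_patients(rng, 50)
    eps = build_episodes(records, ATC_MAP, LEXICON)
    got = {(e.patient_id, e.class_label, e.start_date, e.end_date) for e in eps}
    want = set()
    for r in records:
        for label, start, end in day_by_day_episodes(r, CLASS_OF, LEXICON):
            want.add((r.patient_id, label, start, end))
    assert got == want


def test_episodes_frame_round_trip():
    eps = build_episodes(HAND_FIXTURE, ATC_MAP, LEXICON)
    frame = episodes_to_frame(eps)
    assert episodes_from_frame(frame) == eps
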