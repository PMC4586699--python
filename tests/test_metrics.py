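"""Spell construction, rate equations, time coverage and stratification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import reshist as rh
from reshist.metrics import (
    SpellMatch,
    _match_vector,
    _union_intersection,
    endpoint_matches,
    records_interval,
    run_metrics,
)
from reshist.types import AddressRecord, MatchVector, StudyWindow

WINDOW = StudyWindow(1995, 2013)


def _study_row(year, house="10", street="MAIN ST", city="RICHMOND", state="VA",
               sid="A", x=None, y=None):
    return AddressRecord(
        subject_id=sid, house_number=house, street_name=street, city=city,
        state=state, first_year=year, x=x, y=y,
        frame="planar-feet" if x is not None else None,
    )


def _rec_row(first, last, house="10", street="MAIN ST", city="RICHMOND",
             state="VA", sid="A", x=None, y=None):
    return AddressRecord(
        subject_id=sid, house_number=house, street_name=street, city=city,
        state=state, first_year=first[0], first_month=first[1],
        last_year=last[0], last_month=last[1], x=x, y=y,
        frame="planar-feet" if x is not None else None, source="records",
    )


class TestBuildSpells:
    def test_duplicates_collapsed_and_sequence_ends_assigned(self):
        rows = [
            _study_row(1996, house="1"),
            _study_row(2000, house="1"),
            _study_row(2005, house="2"),
        ]
        hist = rh.build_spells(rows, WINDOW)
        assert hist.n_i == 2
        a, b = hist.spells
        assert (a.start, a.end) == (1996.5, 2005.5)
        assert (b.start, b.end) == (2005.5, 2013.5)

    def test_single_address_spans_window(self):
        hist = rh.build_spells([_study_row(1996)], WINDOW)
        assert hist.n_i == 1
        assert hist.spells[0].duration == pytest.approx(17.0)

    def test_pre_window_address_clipped(self):
        hist = rh.build_spells([_study_row(1994)], WINDOW)
        sp = hist.spells[0]
        assert sp.start == WINDOW.t0 and sp.clipped
        assert sp.duration == pytest.approx(18.5)

    def test_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            rh.build_spells([], WINDOW)


class TestRates:
    def test_two_subject_worked_example(self):
        mv = MatchVector("detailed", [("A", 0, 1), ("A", 1, 1), ("B", 0, 0)])
        overall, mean = rh.rates(mv)
        assert overall == pytest.approx(2 / 3)
        assert mean == pytest.approx(0.5)

    def test_all_matched_gives_unity(self):
        mv = MatchVector("detailed", [("A", 0, 1), ("B", 0, 1)])
        assert rh.rates(mv) == (1.0, 1.0)

    def test_overall_equals_mean_when_address_counts_equal(self):
        rng = np.random.default_rng(0)
        entries = [
            (f"S{i}", j, int(rng.integers(0, 2))) for i in range(20) for j in range(3)
        ]
        overall, mean = rh.rates(MatchVector("city_state", entries))
        assert overall == pytest.approx(mean)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            rh.rates(MatchVector("detailed", []))


class TestIntervals:
    def test_interval_intersection_examples(self):
        assert _union_intersection(2000, 2010, [(2003, 2013)]) == pytest.approx(7.0)
        assert _union_intersection(2000, 2010, [(1995, 2014)]) == pytest.approx(10.0)
        assert _union_intersection(2000, 2010, [(1996, 1999)]) == 0.0

    def test_union_does_not_double_count_overlaps(self):
        covered = _union_intersection(2000, 2010, [(2000, 2006), (2004, 2012)])
        assert covered == pytest.approx(10.0)

    def test_records_interval_clipping_and_floor(self):
        rec = _rec_row((1990, 1), (2020, 12))
        assert records_interval(rec, WINDOW) == (WINDOW.t0, WINDOW.t_end)
        rec = _rec_row((2000, 3), (2000, 3))  # one-month spell
        s, e = records_interval(rec, WINDOW)
        assert e - s == pytest.approx(1 / 12)
        assert records_interval(_rec_row((1990, 1), (1993, 6)), WINDOW) is None


def _spell_match(sid, idx, t_study, covered=0.0, m=False, t_rec=None, **kw):
    return SpellMatch(
        subject_id=sid, index=idx, state="VA", city="X", start=2000.0,
        end=2000.0 + t_study, t_study=t_study, complete_street=True,
        complete_house=True, m_detailed=m, m_street=m, m_city_state=m,
        covered=covered, best_rec_duration=t_rec, **kw,
    )


class TestCoverageMetrics:
    def test_matched_time_coverage_pools_and_averages(self):
        sms = [
            _spell_match("A", 0, 10.0, covered=7.0, m=True, t_rec=10.0),
            _spell_match("B", 0, 10.0, covered=10.0, m=True, t_rec=10.0),
            _spell_match("B", 1, 5.0, covered=0.0, m=False),
        ]
        overall, mean = rh.matched_time_coverage(sms)
        assert overall == pytest.approx(17 / 20)
        assert mean == pytest.approx((0.7 + 1.0) / 2)

    def test_no_matches_reported_absent(self):
        assert rh.matched_time_coverage([_spell_match("A", 0, 5.0)]) is None

    def test_time_difference_distribution(self):
        sms = [
            _spell_match("A", 0, 10.0, covered=10.0, m=True, t_rec=17.0),
            _spell_match("B", 0, 4.0, covered=4.0, m=True, t_rec=4.0),
        ]
        summary, hist = rh.time_difference_distribution(sms)
        assert summary["max"] == pytest.approx(7.0)
        assert summary["min"] == pytest.approx(0.0)
        assert summary["mean"] == pytest.approx(3.5)
        assert hist["count"].sum() == 2

    def test_subject_time_covered_counts_unmatched_time(self):
        sms = [
            _spell_match("A", 0, 5.0, covered=5.0, m=True, t_rec=5.0),
            _spell_match("A", 1, 5.0, covered=0.0, m=False),
            _spell_match("B", 0, 8.0, covered=0.0, m=False),
        ]
        mean, n_zero = rh.subject_time_covered(sms)
        assert mean == pytest.approx((0.5 + 0.0) / 2)
        assert n_zero == 0


class TestEndpointAndYearMetrics:
    def _run(self, study_rows, rec_rows, d=0):
        return run_metrics(study_rows, rec_rows, d=d, window=WINDOW)

    def test_exact_copy_matches_both_endpoints(self):
        study = [_study_row(1996, house="1"), _study_row(2005, house="2")]
        recs = [
            _rec_row((1996, 7), (2005, 6), house="1"),
            _rec_row((2005, 7), (2013, 6), house="2"),
        ]
        res = self._run(study, recs)
        assert res.reports[8].mean_rate == 1.0
        assert res.reports[9].mean_rate == 1.0

    def test_last_address_only_records(self):
        study = [
            _study_row(1996, house="1", sid="A"), _study_row(2005, house="2", sid="A"),
            _study_row(1996, house="9", sid="B"),
        ]
        recs = [
            _rec_row((2005, 7), (2013, 6), house="2", sid="A"),
            _rec_row((1996, 7), (2013, 6), house="9", sid="B"),
        ]
        mr, base = endpoint_matches(self._run(study, recs).matches)
        assert mr == 1.0
        assert base == pytest.approx(0.5)  # only the single-address subject

    def test_empty_records_gives_zero_everywhere(self):
        study = [_study_row(1996, x=0.0, y=0.0)]
        res = self._run(study, [])
        assert res.reports[8].mean_rate == 0.0
        assert res.reports[9].mean_rate == 0.0
        assert res.reports[1].overall_rate == 0.0
        assert res.reports[7].mean_rate == 0.0
        assert res.reports[11].overall_rate == 0.0
        assert res.reports[5].overall_rate is None  # undefined: no matches

    def test_match_by_year_single_matched_spell(self):
        study = [_study_row(1995)]
        recs = [_rec_row((1995, 7), (2013, 6))]
        per_year = self._run(study, recs).reports[10].per_year
        assert (per_year["percent"] == 100.0).all()
        assert (per_year["count"] == 1).all()

    def test_match_by_year_boundary_year_counts_both_addresses(self):
        study = [_study_row(1996, house="1"), _study_row(2005, house="2")]
        recs = [_rec_row((1996, 7), (2005, 6), house="1")]  # only A matches
        py = self._run(study, recs).reports[10].per_year.set_index("year")
        assert py.loc[1995, "count"] == 0
        assert (py.loc[1996:2004, "percent"] == 100.0).all()
        assert py.loc[2005, "count"] == 2
        assert py.loc[2005, "count_single"] == 1
        assert py.loc[2005, "percent"] == 50.0
        assert (py.loc[2006:2013, "percent"] == 0.0).all()


class TestSpatial:
    @pytest.mark.parametrize(
        ("rec_xy", "expected"), [((0.0, 50.0), 1.0), ((0.0, 150.0), 0.0), ((0.0, 0.0), 1.0)]
    )
    def test_threshold_rule(self, rec_xy, expected):
        study = [_study_row(1996, x=0.0, y=0.0)]
        recs = [_rec_row((1996, 7), (2013, 6), x=rec_xy[0], y=rec_xy[1])]
        res = run_metrics(study, recs, d=0, window=WINDOW, spatial_threshold_ft=100.0)
        assert res.reports[11].overall_rate == expected

    def test_lonlat_frame_uses_great_circle_feet(self):
        # ~0.0002 deg latitude ≈ 73 ft at the equator: inside 100 ft
        study = [_study_row(1996, x=0.0, y=0.0)]
        study[0] = AddressRecord(**{**study[0].__dict__, "frame": "lon-lat"})
        rec = _rec_row((1996, 7), (2013, 6), x=0.0, y=0.0002)
        rec = AddressRecord(**{**rec.__dict__, "frame": "lon-lat"})
        res = run_metrics(study, [rec], d=0, window=WINDOW)
        assert res.reports[11].overall_rate == 1.0

    def test_mixed_frames_error(self):
        study = [_study_row(1996, x=0.0, y=0.0)]
        rec = _rec_row((1996, 7), (2013, 6), x=0.0, y=0.0)
        rec = AddressRecord(**{**rec.__dict__, "frame": "lon-lat"})
        with pytest.raises(ValueError, match="frame"):
            run_metrics(study, [rec], d=0, window=WINDOW)


class TestStratify:
    def _matches(self):
        return [
            _spell_match("A", 0, 5.0, m=True, is_baseline=True, is_last=False),
            _spell_match("A", 1, 5.0, m=True, is_last=True),
            _spell_match("B", 0, 5.0, m=False, is_baseline=True, is_last=True),
        ]

    def test_two_strata_rates(self):
        sms = self._matches()
        sms[2].state = "CA"
        table = rh.stratify(sms, key=lambda sm: sm.state).set_index("stratum")
        assert table.loc["VA", "overall_rate"] == 1.0
        assert table.loc["CA", "overall_rate"] == 0.0

    def test_single_stratum_equals_unstratified(self):
        sms = self._matches()
        table = rh.stratify(sms, key=lambda sm: "all")
        overall, mean = rh.rates(_match_vector(sms, "detailed"))
        assert table.loc[0, "overall_rate"] == pytest.approx(overall)
        assert table.loc[0, "mean_rate"] == pytest.approx(mean)

    def test_binary_strata_average_to_overall(self):
        sms = self._matches()
        sms[1].state = "CA"
        table = rh.stratify(sms, key=lambda sm: sm.state == "CA")
        pooled = (table["overall_rate"] * table["n_addresses"]).sum() / table[
            "n_addresses"
        ].sum()
        overall, _ = rh.rates(_match_vector(sms, "detailed"))
        assert pooled == pytest.approx(overall)

    def test_empty_stratum_absent_not_zero(self):
        table = rh.stratify(self._matches(), key=lambda sm: sm.state)
        assert set(table["stratum"]) == {"VA"}


class TestSimulatedRunProperties:
    def test_metric_ordering(self, small_run):
        _, res = small_run
        r = res.reports
        assert r[3].overall_rate <= r[2].overall_rate <= r[1].overall_rate
        assert r[3].mean_rate <= r[2].mean_rate <= r[1].mean_rate

    def test_coverage_and_difference_bounds(self, small_run):
        _, res = small_run
        assert 0.0 <= res.reports[5].overall_rate <= 1.0
        assert 0.0 <= res.reports[5].mean_rate <= 1.0
        assert 0.0 <= res.reports[7].mean_rate <= 1.0
        d6 = res.reports[6].distribution
        assert abs(d6["min"]) < WINDOW.n_years and abs(d6["max"]) < WINDOW.n_years

    def test_incomplete_street_rows_excluded_from_street_metrics(self):
        study = [
            _study_row(1996, street="", house="1", sid="A"),
            _study_row(1996, house="9", sid="B"),
        ]
        recs = [_rec_row((1996, 7), (2013, 6), house="9", sid="B")]
        res = run_metrics(study, recs, d=0, window=WINDOW)
        assert res.reports[1].counts["n_addresses"] == 2
        assert res.reports[2].counts["n_addresses"] == 1
        assert res.reports[2].overall_rate == 1.0
        assert res.reports[2].counts["n_incomplete_excluded"] == 1
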