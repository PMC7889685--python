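import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypobench import burden_summary, detect_events, find_nonevent_segments
from hypobench.records import ValidationError

from conftest import make_record
from oracles import event_samples_by_window_scan, segments_by_feasibility_scan


def event_sample_set(record, events):
    out = set()
    for ev in events:
        idx = np.flatnonzero(
            (record.times_s >= ev.start_s) & (record.times_s < ev.end_s)
        )
        out.update(int(i) for i in idx)
    return out


class TestDetectEvents:
    def test_never_below_threshold(self):
        assert detect_events(make_record([80, 80, 80, 80])) == []

    def test_minimum_duration_run(self):
        """Three samples at or below 65 mmHg are exactly one minute."""
        events = detect_events(make_record([70, 60, 64, 65, 70]))
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_s, ev.end_s) == (20, 80)
        assert ev.duration_min == pytest.approx(1.0)
        assert ev.mean_map_mmhg == pytest.approx((60 + 64 + 65) / 3)

    def test_two_samples_too_short(self):
        assert detect_events(make_record([70, 60, 60, 70])) == []

    def test_sixty_five_counts_as_hypotensive(self):
        assert len(detect_events(make_record([65, 65, 65]))) == 1

    def test_single_high_sample_splits_runs(self):
        events = detect_events(make_record([60, 60, 60, 66, 60, 60, 60]))
        assert len(events) == 2

    def test_runs_do_not_bridge_gaps(self):
        times = [0, 20, 40, 120, 140, 160]  # 80-s hole in the grid
        rec = make_record([60] * 6, times=times)
        events = detect_events(rec)
        assert len(events) == 2
        assert [e.start_s for e in events] == [0, 120]

    def test_empty_record_rejected(self):
        with pytest.raises(ValidationError):
            make_record([])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_window_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        maps = rng.choice([60, 63, 64, 65, 65, 66, 70, 80], size=n).astype(float)
        rec = make_record(maps)
        got = event_sample_set(rec, detect_events(rec))
        want = event_samples_by_window_scan(rec.times_s, rec.map_mmhg, 20)
        assert got == want

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        maps=st.lists(
            st.sampled_from([55.0, 64.0, 65.0, 65.0001, 66.0, 90.0]),
            min_size=1,
            max_size=60,
        )
    )
    def test_property_events_are_disjoint_minimal_runs(self, maps):
        rec = make_record(maps)
        events = detect_events(rec)
        prev_end = -1
        for ev in events:
            assert ev.duration_min >= 1.0
            assert ev.start_s >= prev_end
            prev_end = ev.end_s
            sel = (rec.times_s >= ev.start_s) & (rec.times_s < ev.end_s)
            assert np.all(rec.map_mmhg[sel] <= 65.0)
        assert event_sample_set(rec, events) == event_samples_by_window_scan(
            rec.times_s, rec.map_mmhg, 20
        )


class TestNonEventSegments:
    def test_exclusion_zone_starves_short_sides(self):
        """25 min of calm on each side of an event leaves < 30 usable min."""
        maps = [80.0] * 75 + [60.0] * 6 + [80.0] * 75
        rec = make_record(maps)
        events = detect_events(rec)
        assert len(events) == 1
        assert find_nonevent_segments(rec, events) == []

    def test_event_free_record_tiles_by_thirty_minutes(self):
        rec = make_record([85.0] * 300)  # 100 min
        segs = find_nonevent_segments(rec, [])
        assert len(segs) == 3
        assert [(s.start_s, s.end_s) for s in segs] == [
            (0, 1800), (1800, 3600), (3600, 5400),
        ]

    def test_low_map_blocks_segments(self):
        maps = [85.0] * 100 + [74.0] + [85.0] * 100  # one dip below the floor
        segs = find_nonevent_segments(make_record(maps), [])
        assert len(segs) == 2  # one 30-min tile on each side of the dip

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_feasibility_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(150, 500))
        maps = rng.choice(
            [60.0, 70.0, 76.0, 80.0, 90.0], size=n, p=[0.05, 0.05, 0.2, 0.34, 0.36]
        )
        rec = make_record(maps)
        events = detect_events(rec)
        got = [(s.start_s, s.end_s) for s in find_nonevent_segments(rec, events)]
        want = segments_by_feasibility_scan(
            rec.times_s, rec.map_mmhg, 20, [(e.start_s, e.end_s) for e in events]
        )
        assert got == want

    def test_segments_respect_exclusion_invariant(self, trial_cohort):
        for rec in trial_cohort["records"]:
            events = trial_cohort["events"][rec.patient_id]
            for seg in trial_cohort["segments"][rec.patient_id]:
                sel = (rec.times_s >= seg.start_s) & (rec.times_s < seg.end_s)
                assert np.all(rec.map_mmhg[sel] > 75.0)
                for ev in events:
                    assert (
                        seg.end_s <= ev.start_s - 1200 or seg.start_s >= ev.end_s + 1200
                    )


class TestBurden:
    def test_constant_dip_toy_case(self):
        """10 min at 60 mmHg in a 100-min record: area 50, TWA 0.5."""
        maps = [80.0] * 150 + [60.0] * 30 + [80.0] * 120
        rec = make_record(maps)
        events = {rec.patient_id: detect_events(rec)}
        per, _ = burden_summary([rec], events)
        row = per.iloc[0]
        assert row["monitoring_time_min"] == pytest.approx(100.0)
        assert row["area_under65_mmhg_min"] == pytest.approx(50.0)
        assert row["twa_under65_mmhg"] == pytest.approx(0.5)
        assert row["mean_map_under65_mmhg"] == pytest.approx(60.0)
        assert row["total_event_duration_min"] == pytest.approx(10.0)
        assert row["total_event_duration_pct"] == pytest.approx(10.0)

    def test_no_hypotension_flags_undefined_mean(self):
        rec = make_record([80.0] * 10)
        per, _ = burden_summary([rec], {rec.patient_id: []})
        row = per.iloc[0]
        assert row["area_under65_mmhg_min"] == 0.0
        assert row["twa_under65_mmhg"] == 0.0
        assert np.isnan(row["mean_map_under65_mmhg"])

    def test_twa_times_span_equals_area(self, trial_cohort):
        per, _ = burden_summary(trial_cohort["records"], trial_cohort["events"])
        resid = per["twa_under65_mmhg"] * per["monitoring_time_min"] - per[
            "area_under65_mmhg_min"
        ]
        assert np.all(np.abs(resid) < 1e-9)

    def test_additive_under_split_at_calm_sample(self):
        """Splitting a record at a non-event sample conserves burden."""
        rng = np.random.default_rng(3)
        maps = rng.choice([60.0, 64.0, 80.0, 90.0], size=200, p=[0.1, 0.1, 0.4, 0.4])
        maps[99] = maps[100] = 90.0  # calm split point
        rec = make_record(maps)
        left = make_record(maps[:100], patient_id="L")
        right = make_record(maps[100:], times=np.arange(100, 200) * 20, patient_id="R")
        whole, _ = burden_summary([rec], {"P1": detect_events(rec)})
        parts, _ = burden_summary(
            [left, right], {"L": detect_events(left), "R": detect_events(right)}
        )
        for col in ["monitoring_time_min", "n_events", "total_event_duration_min",
                    "area_under65_mmhg_min"]:
            assert whole[col].sum() == pytest.approx(parts[col].sum())

    def test_cohort_rows_are_median_iqr(self, trial_cohort):
        per, cohort = burden_summary(trial_cohort["records"], trial_cohort["events"])
        med = cohort.set_index("metric")["median"]
        assert med["n_events"] == pytest.approx(per["n_events"].median())
        assert med["twa_under65_mmhg"] == pytest.approx(per["twa_under65_mmhg"].median())
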