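"""Sensorimotor records: stimulus-at-head reconstruction, derivatives,
bearings, event detection and trial merging."""

import numpy as np
import pytest

from sostrack import sensorimotor as sm
from sostrack.calibration import Calibration
from sostrack.errors import IncompatibleUnitsError, SosError, ZeroBaselineError
from sostrack.identity import LabeledTrajectory
from sostrack.landscapes import LinearLandscape, RadialLandscape, SidewaysLightLandscape

from test_identity import make_posture

LINEAR = LinearLandscape(slope=0.1, direction=(1, 0), ref_value=18.0, units="degC")
CAL = Calibration(mm_per_pixel=1.0, frames_per_second=1.0)


def straight_run_trajectory(v=0.4, n=30, heading=(1.0, 0.0), length=4.0):
    """Body of `length` mm advancing at v mm/s along `heading` (1 fps)."""
    u = np.asarray(heading, float) / np.linalg.norm(heading)
    postures = []
    for i in range(n):
        head = np.array([10.0, 10.0]) + v * i * u
        tail = head - length * u
        postures.append(make_posture(head, tail))
    return LabeledTrajectory(postures=postures)


class TestRelativeChange:
    def test_50nM_on_1uM_background_is_five_percent(self):
        assert sm.relative_change(0.05, 1.0) == pytest.approx(5.0)

    def test_zero_delta(self):
        assert sm.relative_change(0.0, 3.0) == 0.0

    def test_zero_baseline_raises(self):
        with pytest.raises(ZeroBaselineError):
            sm.relative_change(1.0, 0.0)


class TestBuildRecords:
    def test_chain_rule_on_linear_gradient(self):
        v = 0.4
        traj = straight_run_trajectory(v=v)
        records = sm.build_records(traj, CAL, LINEAR)
        expected = LINEAR.slope * v
        for r in records[1:-1]:
            assert r.head_value_derivative == pytest.approx(expected, rel=0.02)

    def test_stationary_animal_zero_derivative(self):
        traj = straight_run_trajectory(v=0.0)
        records = sm.build_records(traj, CAL, LINEAR)
        assert all(r.head_value_derivative == pytest.approx(0.0) for r in records)

    def test_head_value_matches_field_at_head(self):
        radial = RadialLandscape(source=(40.0, 10.0), peak=2.0, decay_length=5.0)
        traj = straight_run_trajectory(v=0.4)
        records = sm.build_records(traj, CAL, radial)
        for r, p in zip(records, traj.postures):
            assert r.head_value == pytest.approx(radial.field_at(p.head))

    def test_bearing_zero_running_up_gradient(self):
        records = sm.build_records(straight_run_trajectory(v=0.4), CAL, LINEAR)
        for r in records[1:-1]:
            assert r.bearing == pytest.approx(0.0, abs=1e-6)

    def test_flat_field_bearing_missing_not_error(self):
        flat = LinearLandscape(slope=0.0)
        records = sm.build_records(straight_run_trajectory(v=0.4), CAL, flat)
        assert all(np.isnan(r.bearing) for r in records)

    def test_discarded_frames_excluded(self):
        traj = straight_run_trajectory(v=0.4, n=10)
        traj.postures[4].flags.add("discarded")
        records = sm.build_records(traj, CAL, LINEAR)
        assert len(records) == 9
        assert [r.frame for r in records] == [i for i in range(10) if i != 4]

    def test_timestamps_use_frame_rate(self):
        cal = Calibration(mm_per_pixel=1.0, frames_per_second=7.0)
        records = sm.build_records(straight_run_trajectory(v=0.4, n=8), cal, LINEAR)
        assert records[3].t == pytest.approx(3 / 7)

    def test_relative_change_per_frame(self):
        records = sm.build_records(straight_run_trajectory(v=0.4, n=5), CAL, LINEAR)
        assert records[0].relative_change == 0.0
        v1, v0 = records[1].head_value, records[0].head_value
        assert records[1].relative_change == pytest.approx(100 * (v1 - v0) / v0)

    def test_light_fraction_only_for_sideways_light(self):
        light = SidewaysLightLandscape(source_point=(0, 0), intensity_at_source=10,
                                       decay_length=5, normal=(1, 0))
        recs_light = sm.build_records(straight_run_trajectory(v=0.4, n=5), CAL, light)
        recs_linear = sm.build_records(straight_run_trajectory(v=0.4, n=5), CAL, LINEAR)
        assert all(0 <= r.light_fraction <= 100 for r in recs_light)
        assert all(np.isnan(r.light_fraction) for r in recs_linear)


class TestDetectEvents:
    def test_constant_heading_single_run(self):
        records = sm.build_records(straight_run_trajectory(v=0.4, n=40), CAL, LINEAR)
        events = sm.detect_events(records)
        assert [e.type for e in events] == ["run"]
        assert events[0].start_frame == 0 and events[0].end_frame == 39

    def test_gradual_turn_detected_once(self):
        # 90 degrees over 2 s at 45 deg/s against a 20 deg/s threshold
        postures = []
        heading = 0.0
        pos = np.array([10.0, 10.0])
        for i in range(40):
            if 15 <= i < 17:
                heading += 45.0
            u = np.array([np.cos(np.deg2rad(heading)), np.sin(np.deg2rad(heading))])
            pos = pos + 0.4 * u
            postures.append(make_posture(pos, pos - 4.0 * u))
        records = sm.build_records(LabeledTrajectory(postures=postures), CAL)
        events = sm.detect_events(records)
        turns = [e for e in events if e.type == "turn"]
        assert len(turns) == 1
        assert turns[0].start_frame <= 18 and turns[0].end_frame >= 15
        assert turns[0].magnitude == pytest.approx(90.0, abs=15.0)

    def test_cast_counted_once_per_sweep(self):
        # body advances, pauses and bends twice: two casts, no turns
        postures = []
        pos = np.array([10.0, 10.0])
        u = np.array([1.0, 0.0])
        for i in range(60):
            bend = 0.0
            moving = True
            for t0 in (20, 40):
                if t0 <= i < t0 + 6:
                    bend = np.deg2rad(60.0) * np.sin(np.pi * (i - t0) / 6)
                    moving = False
            if moving:
                pos = pos + 0.4 * u
            head_dir = np.array([np.cos(bend), np.sin(bend)])
            mid = pos - 2.0 * u
            head = mid + 2.0 * head_dir
            tail = mid - 2.0 * u
            p = make_posture(head, tail)
            p.midpoint = mid
            postures.append(p)
        records = sm.build_records(LabeledTrajectory(postures=postures), CAL)
        events = sm.detect_events(records)
        casts = [e for e in events if e.type == "cast"]
        turns = [e for e in events if e.type == "turn"]
        assert len(casts) == 2 and len(turns) == 0
        assert all(e.magnitude > 30.0 for e in casts)

    def test_event_partition_covers_all_frames_no_overlap(self):
        records = sm.build_records(straight_run_trajectory(v=0.4, n=25), CAL, LINEAR)
        events = sm.detect_events(records)
        covered = []
        for e in events:
            covered.extend(range(e.start_frame, e.end_frame + 1))
        assert sorted(covered) == [r.frame for r in records]
        assert all(r.event_label in ("run", "turn", "cast") for r in records)

    def test_non_monotonic_timestamps_rejected(self):
        records = sm.build_records(straight_run_trajectory(v=0.4, n=5), CAL, LINEAR)
        records[2].t = records[1].t
        with pytest.raises(SosError):
            sm.detect_events(records)

    def test_too_few_records_rejected(self):
        records = sm.build_records(straight_run_trajectory(v=0.4, n=5), CAL, LINEAR)
        with pytest.raises(SosError):
            sm.detect_events(records[:2])


class TestMergeTrials:
    def _df(self, n, units="degC", trial_id="t0"):
        records = sm.build_records(straight_run_trajectory(v=0.4, n=n), CAL, LINEAR)
        return sm.records_to_dataframe(records, units=units, trial_id=trial_id)

    def test_concatenates_with_trial_ids(self):
        merged = sm.merge_trials([self._df(100, trial_id="a"),
                                  self._df(150, trial_id="b")])
        assert len(merged) == 250
        assert set(merged["trial_id"]) == {"a", "b"}

    def test_single_trial_identity(self):
        df = self._df(30)
        merged = sm.merge_trials([df])
        assert len(merged) == 30 and "trial_id" in merged.columns

    def test_unit_mismatch_rejected(self):
        with pytest.raises(IncompatibleUnitsError):
            sm.merge_trials([self._df(10, units="degC"),
                             self._df(10, units="uM")])

    def test_empty_list_rejected(self):
        with pytest.raises(SosError):
            sm.merge_trials([])
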