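import math

import numpy as np
import pytest

from vigilkit import looming
from vigilkit.simulate import LoomGenParams, gen_loom_session
from vigilkit.types import ArenaGeometry, UniformSeries, ValidationError

from conftest import make_track

TRIGGER = np.array([31.0, 9.85])
SHELTER_EDGE_IN = np.array([6.35, 9.85])   # shelter-zone center
MID = np.array([15.0, 9.85])               # intermediate zone, outside shelter
FAR = np.array([34.5, 9.85])               # deep trigger zone
CUE = 1.0


class TestGeometryClosedForms:
    def test_area_expansion_rates_match_independent_arithmetic(self):
        # slow ramp 0.5 -> 3 cm over 3 s and fast 3 -> 21 cm over 0.5 s
        slow = looming.area_expansion_rate(0.5, 3, 3)
        fast = looming.area_expansion_rate(3, 21, 0.5)
        assert slow == pytest.approx(
            (math.pi * 1.5**2 - math.pi * 0.25**2) / 3.0, abs=1e-9
        )
        assert round(slow, 3) == 2.291
        assert fast == pytest.approx(
            (math.pi * 10.5**2 - math.pi * 1.5**2) / 0.5, abs=1e-9
        )
        assert round(fast, 1) == 678.6

    def test_equal_diameters_zero_rate(self):
        assert looming.area_expansion_rate(5.0, 5.0, 2.0) == 0.0

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValidationError):
            looming.area_expansion_rate(1, 2, 0)

    @pytest.mark.parametrize(
        "diameter,expected", [(3.0, 5.7), (21.0, 38.6), (0.0, 0.0)]
    )
    def test_visual_angle_at_30cm(self, diameter, expected):
        assert round(looming.visual_angle_deg(diameter, 30.0), 1) == expected

    def test_visual_angle_matches_atan_form(self):
        got = looming.visual_angle_deg(7.3, 22.0)
        assert got == pytest.approx(
            math.degrees(2 * math.atan(7.3 / 44.0)), abs=1e-9
        )

    def test_michelson_contrast(self):
        assert looming.michelson_contrast(127, 0) == pytest.approx(100.0)
        assert looming.michelson_contrast(55, 55) == 0.0
        assert looming.michelson_contrast(200, 100) == pytest.approx(100 / 3)
        with pytest.raises(ValidationError):
            looming.michelson_contrast(0, 0)


class TestStimulusProfile:
    def test_endpoints_and_segments(self):
        profile = looming.stimulus_profile(frame_rate_hz=100.0)
        assert profile["diameter_cm"].iloc[0] == pytest.approx(0.5)
        at3 = profile[np.isclose(profile["time_s"], 3.0)]["diameter_cm"].iloc[0]
        assert at3 == pytest.approx(3.0)
        assert profile["diameter_cm"].max() == pytest.approx(21.0, rel=0.01)
        assert profile["time_s"].iloc[-1] < 6.0
        # both expansions reach full size and the disc holds to the end
        exp2 = profile[profile["segment"] == "expansion_2"]
        assert len(exp2) > 0
        hold = profile[profile["segment"] == "hold"]
        assert np.allclose(hold["diameter_cm"], 21.0)

    def test_time_beyond_duration_is_error(self):
        with pytest.raises(ValidationError):
            looming._diameter_at(looming.StimulusParams(), 6.5)

    def test_oversized_segments_rejected(self):
        with pytest.raises(ValidationError):
            looming.StimulusParams(ramp_duration_s=5.5, n_expansions=2)


class TestVelocity:
    def test_straight_line_constant_speed(self):
        track = make_track([(0.0, np.array([0.0, 5.0])), (3.0, np.array([30.0, 5.0]))])
        v = looming.compute_velocity(track)
        assert np.allclose(v.values[10:100], 10.0, atol=0.5)

    def test_stationary_is_zero(self):
        track = make_track([(0.0, MID), (3.0, MID)])
        v = looming.compute_velocity(track)
        assert np.allclose(v.values, 0.0, atol=1e-9)

    def test_circular_motion_speed_r_omega(self):
        fps, r, omega = 50.0, 5.0, 2.0
        t = np.arange(0, 4, 1 / fps)
        xy = np.column_stack([10 + r * np.cos(omega * t), 10 + r * np.sin(omega * t)])
        from vigilkit.types import PoseTrack

        track = PoseTrack(fps, {"body_centroid": xy})
        v = looming.compute_velocity(track, smoothing_window_s=0.1)
        assert np.median(v.values[20:-20]) == pytest.approx(r * omega, rel=0.02)


class TestImmobility:
    def _vel(self, values, rate=10.0):
        return UniformSeries(np.asarray(values, dtype=float), rate)

    def test_long_still_interval_found(self):
        v = self._vel([0.5] * 30)  # 3 s below threshold
        intervals = looming.detect_immobility(v)
        assert len(intervals) == 1
        assert intervals[0][1] - intervals[0][0] == pytest.approx(3.0)

    def test_brief_stillness_ignored(self):
        v = self._vel([5.0] * 10 + [0.5] * 8 + [5.0] * 10)  # 0.8 s
        assert looming.detect_immobility(v) == []

    def test_rapid_alternation_ignored(self):
        v = self._vel(([0.5] * 4 + [2.0] * 4) * 10)  # 0.4 s runs
        assert looming.detect_immobility(v) == []


def escape_track():
    """Dash from trigger to shelter at ~50 cm/s, arriving well inside 7 s."""
    return make_track(
        [(0.0, TRIGGER), (CUE + 0.3, TRIGGER), (CUE + 0.8, SHELTER_EDGE_IN)],
        total_s=10.0,
    )


class TestEscapeTruthTable:
    """Hand-constructed trajectories hitting all 8 combinations of the
    three escape criteria (speed, heading, shelter arrival)."""

    def classify(self, track):
        return looming.classify_escape(track, CUE)

    def test_speed_heading_shelter(self):
        rec = self.classify(escape_track())
        assert (rec.speed_ok, rec.heading_ok, rec.shelter_ok) == (True, True, True)
        assert rec.escaped
        assert rec.latency_to_shelter_s <= 7.0

    def test_speed_heading_no_shelter(self):
        # fast shelter-directed dash that stops in the intermediate zone
        track = make_track(
            [(0.0, TRIGGER), (CUE + 0.3, TRIGGER), (CUE + 0.62, MID)], total_s=10.0
        )
        rec = self.classify(track)
        assert (rec.speed_ok, rec.heading_ok, rec.shelter_ok) == (True, True, False)
        assert not rec.escaped

    def test_speed_no_heading_shelter(self):
        # fast dash AWAY first, then slow walk into the shelter
        track = make_track(
            [
                (0.0, MID),
                (CUE + 0.2, MID),
                (CUE + 0.55, FAR),          # ~56 cm/s away from shelter
                (CUE + 1.0, FAR),
                (CUE + 4.5, SHELTER_EDGE_IN),  # ~8 cm/s walk in
            ],
            total_s=10.0,
        )
        rec = self.classify(track)
        assert (rec.speed_ok, rec.heading_ok, rec.shelter_ok) == (True, False, True)
        assert not rec.escaped

    def test_speed_no_heading_no_shelter(self):
        track = make_track(
            [(0.0, MID), (CUE + 0.2, MID), (CUE + 0.55, FAR)], total_s=10.0
        )
        rec = self.classify(track)
        assert (rec.speed_ok, rec.heading_ok, rec.shelter_ok) == (True, False, False)
        assert not rec.escaped

    def test_no_speed_heading_shelter(self):
        # slow (8 cm/s) walk into the shelter: only speed fails
        track = make_track(
            [(0.0, TRIGGER), (CUE + 0.2, TRIGGER), (CUE + 3.3, SHELTER_EDGE_IN)],
            total_s=10.0,
        )
        rec = self.classify(track)
        assert (rec.speed_ok, rec.heading_ok, rec.shelter_ok) == (False, True, True)
        assert not rec.escaped

    def test_no_speed_heading_no_shelter(self):
        track = make_track(
            [(0.0, TRIGGER), (CUE + 0.2, TRIGGER), (CUE + 2.2, MID)], total_s=10.0
        )
        rec = self.classify(track)
        assert (rec.speed_ok, rec.heading_ok, rec.shelter_ok) == (False, True, False)
        assert not rec.escaped

    def test_no_speed_no_heading_shelter(self):
        # walking backward into the shelter: heading points away
        track = make_track(
            [(0.0, MID), (CUE + 0.2, MID), (CUE + 1.8, SHELTER_EDGE_IN)],
            head_sign=-1.0,
            total_s=10.0,
        )
        rec = self.classify(track)
        assert (rec.speed_ok, rec.heading_ok, rec.shelter_ok) == (False, False, True)
        assert not rec.escaped

    def test_no_speed_no_heading_no_shelter(self):
        track = make_track(
            [(0.0, MID), (CUE + 0.2, MID), (CUE + 2.0, np.array([25.0, 9.85]))],
            total_s=10.0,
        )
        rec = self.classify(track)
        assert (rec.speed_ok, rec.heading_ok, rec.shelter_ok) == (False, False, False)
        assert not rec.escaped

    def test_incomplete_window_marks_not_performed(self):
        track = make_track([(0.0, TRIGGER), (2.0, TRIGGER)], total_s=3.0)
        rec = looming.classify_escape(track, CUE)
        assert not rec.performed
        assert not rec.escaped

    def test_determinism(self):
        a = self.classify(escape_track())
        b = self.classify(escape_track())
        assert a == b

    def test_threshold_monotonicity(self):
        """Raising the speed threshold never converts non-escape to escape."""
        track = escape_track()
        prev = None
        for thr in (20.0, 35.0, 55.0, 80.0):
            crit = looming.EscapeCriteria(
                speed_threshold_cm_s=thr, vigor_threshold_cm_s=thr - 1
            )
            rec = looming.classify_escape(track, CUE, criteria=crit)
            if prev is not None:
                assert not (rec.escaped and not prev)
            prev = rec.escaped


class TestEscapeProbability:
    def _trial(self, performed, escaped):
        return looming.TrialRecord(
            0, 0.0, performed, escaped, escaped, escaped, escaped,
            np.nan, 0.0, np.nan, 0.0, "trigger",
        )

    def test_basic_fraction(self):
        trials = [self._trial(True, True)] * 7 + [self._trial(True, False)] * 3
        assert looming.escape_probability(trials) == pytest.approx(0.7)

    def test_zero_escapes(self):
        trials = [self._trial(True, False)] * 10
        assert looming.escape_probability(trials) == 0.0

    def test_not_performed_excluded_from_denominator(self):
        trials = (
            [self._trial(True, True)] * 3
            + [self._trial(True, False)]
            + [self._trial(False, False)] * 6
        )
        assert looming.escape_probability(trials) == pytest.approx(0.75)

    def test_no_completed_trials_is_missing(self):
        assert np.isnan(looming.escape_probability([self._trial(False, False)]))


class TestVigor:
    def test_peak_of_return_run(self):
        rec = looming.classify_escape(escape_track(), CUE)
        # dash covers ~24.7 cm in 0.5 s -> mean ~49 cm/s; peak above that
        assert rec.vigor_cm_s > 45.0

    def test_slow_return_is_missing(self):
        track = make_track(
            [(0.0, TRIGGER), (CUE + 0.2, TRIGGER), (CUE + 1.9, SHELTER_EDGE_IN)],
            total_s=10.0,
        )  # ~15 cm/s, below the relaxed 20 cm/s threshold
        rec = looming.classify_escape(track, CUE)
        assert np.isnan(rec.vigor_cm_s)

    def test_first_qualifying_run_wins(self):
        """Two shelter-directed runs (~25 then ~40 cm/s): vigor reports the
        first qualifying run's peak."""
        track = make_track(
            [
                (0.0, TRIGGER),
                (CUE + 0.2, TRIGGER),
                (CUE + 0.9, np.array([13.5, 9.85])),  # run 1: ~25 cm/s, stops short
                (CUE + 2.1, np.array([13.5, 9.85])),
                (CUE + 2.28, SHELTER_EDGE_IN),        # run 2: ~40 cm/s, enters
            ],
            total_s=10.0,
        )
        rec = looming.classify_escape(track, CUE)
        assert 20.0 < rec.vigor_cm_s < 32.0


class TestImmobilityAndZones:
    def test_cumulative_immobility_clipped_to_window(self):
        trials = []
        for k in range(10):
            trials.append(
                looming.TrialRecord(
                    k, 0.0, True, False, False, False, False,
                    np.nan, 0.0, np.nan, 1.0, "trigger",
                )
            )
        assert looming.cumulative_immobility(trials) == pytest.approx(10.0)

    def test_freeze_trial_immobility_spans_window(self):
        track = make_track([(0.0, TRIGGER), (9.5, TRIGGER)], total_s=10.0)
        rec = looming.classify_escape(track, CUE)
        assert rec.immobile_s == pytest.approx(7.0, abs=0.2)

    def test_fixed_centroid_occupancy(self, arena):
        track = make_track([(0.0, np.array([5.0, 9.0])), (60.0, np.array([5.0, 9.0]))],
                           total_s=60.0)
        occ = looming.zone_occupancy(track, arena).set_index("zone")
        assert occ.loc["shelter", "seconds"] == pytest.approx(60.0, rel=0.01)
        assert occ.loc["trigger", "seconds"] == 0.0

    def test_occupancy_percentages_sum_to_100(self):
        track, _, _ = gen_loom_session(LoomGenParams(n_trials=4), seed=0)
        occ = looming.zone_occupancy(track)
        assert occ["percent"].sum() == pytest.approx(100.0)

    def test_straight_traverse_distance(self):
        track = make_track(
            [(0.0, np.array([0.0, 9.85])), (6.0, np.array([36.0, 9.85]))],
            total_s=7.0,
        )
        d = looming.distance_moved(track)
        assert d == pytest.approx(36.0, rel=0.02)


class TestProgrammedProbabilityRecovery:
    @pytest.mark.parametrize("p", [0.2, 0.8])
    def test_classifier_recovers_programmed_probability(self, p):
        params = LoomGenParams(n_trials=40, escape_probability=p)
        track, events, truth = gen_loom_session(params, seed=12)
        recs = [
            looming.classify_escape(track, t, trial=i)
            for i, t in enumerate(events.times)
        ]
        assert looming.escape_probability(recs) == pytest.approx(p, abs=0.07)
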