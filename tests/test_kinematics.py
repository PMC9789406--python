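"""Body-kinematics tests: curvature anchors, speed, swing, wave timing."""

import numpy as np
import pytest

from depthgait.fin import StrokeError, StrokeSegmentation, segment_strokes
from depthgait.kinematics import (curvature_coefficient, locomotion_speed,
                                  max_amplitude_phase, nose_elevation,
                                  swing_distance, wave_frequency)
from depthgait.midline import LandmarkTrajectory, MidlineSequence, body_frame
from depthgait.synth import TrialSpec, generate_depth_sweep, generate_trial


def straight_seq(n_frames=10, bl=100.0):
    pts = np.zeros((n_frames, 100, 2))
    pts[:, :, 0] = np.linspace(0, bl, 100)
    return MidlineSequence(points=pts, body_length=bl, frame_rate=500.0)


def arc_seq(fraction_closed, bl=100.0, n_frames=5):
    """Midlines bent into a circular arc spanning ``fraction_closed`` turns."""
    theta = np.linspace(0, 2 * np.pi * fraction_closed, 100)
    r = bl / (2 * np.pi * fraction_closed)
    pts = np.zeros((n_frames, 100, 2))
    pts[:, :, 0] = r * np.cos(theta)
    pts[:, :, 1] = r * np.sin(theta)
    return MidlineSequence(points=pts, body_length=bl, frame_rate=500.0)


class TestCurvatureCoefficient:
    def test_straight_fish_is_zero(self):
        assert curvature_coefficient(straight_seq()) == 0.0

    def test_nose_touching_tail_is_one(self):
        assert curvature_coefficient(arc_seq(1.0)) == pytest.approx(1.0,
                                                                    abs=1e-12)

    def test_semicircle_closed_form(self):
        # chord of a semicircle = 2R with BL = pi R
        assert curvature_coefficient(arc_seq(0.5)) == pytest.approx(
            1.0 - 2.0 / np.pi, abs=1e-9)

    def test_rigid_motion_and_scale_invariance(self, rng):
        seq = arc_seq(0.3)
        ang = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])
        moved = 3.7 * (seq.points @ R.T) + rng.normal(size=2)
        seq2 = MidlineSequence(points=moved, body_length=3.7 * seq.body_length,
                               frame_rate=seq.frame_rate)
        assert curvature_coefficient(seq2) == pytest.approx(
            curvature_coefficient(seq), abs=1e-12)

    def test_inconsistent_calibration_raises(self):
        pts = np.zeros((5, 100, 2))
        pts[:, :, 0] = np.linspace(0, 100, 100)  # span 100 but BL claims 90
        seq = MidlineSequence(points=pts, body_length=90.0, frame_rate=500.0)
        with pytest.raises(ValueError, match="calibration"):
            curvature_coefficient(seq)

    def test_window_selects_frames(self):
        seq = straight_seq(n_frames=10)
        bent = arc_seq(0.5, n_frames=1)
        pts = np.concatenate([seq.points, bent.points])
        mixed = MidlineSequence(points=pts, body_length=100.0,
                                frame_rate=500.0)
        early = curvature_coefficient(mixed, cycle=(0.0, 0.01))
        assert early == 0.0
        assert curvature_coefficient(mixed) > 0.3


class TestSpeed:
    def make_lm(self, nose_xy, duration=1.0, bl=100.0):
        T = len(nose_xy)
        pts = np.zeros((T, 3))
        pts[:, :2] = nose_xy
        t = np.linspace(0, duration, T)
        return LandmarkTrajectory(time_s=t, points={"nose": pts},
                                  frame_rate=T / duration, body_length=bl)

    def test_two_bl_per_second(self):
        nose = np.column_stack([np.linspace(0, 200, 50), np.zeros(50)])
        assert locomotion_speed(self.make_lm(nose)) == pytest.approx(2.0)

    def test_stationary_fish(self):
        nose = np.zeros((50, 2))
        assert locomotion_speed(self.make_lm(nose)) == 0.0

    def test_recovers_generator_speed(self, clean_trial):
        assert locomotion_speed(clean_trial.landmarks) == pytest.approx(
            clean_trial.ground_truth.speed_bl_s, rel=0.01)

    def test_missing_nose_raises(self):
        lm = LandmarkTrajectory(time_s=np.arange(3) / 500.0,
                                points={"tail": np.zeros((3, 3))},
                                frame_rate=500.0, body_length=100.0)
        with pytest.raises(KeyError, match="nose"):
            locomotion_speed(lm)


class TestSwingDistance:
    def test_pure_lateral_sinusoid_travels_twice_amplitude(self):
        fs, a, f = 500.0, 5.0, 2.0
        t = np.arange(int(3 * fs)) / fs
        y = a * np.sin(2 * np.pi * f * t)
        xy = np.column_stack([np.zeros_like(y), y])
        sw = swing_distance(xy, y, fs, body_length=100.0)
        assert sw == pytest.approx(2 * a / 100.0, rel=0.02)

    def test_forward_translation_increases_path(self):
        fs, a, f = 500.0, 5.0, 2.0
        t = np.arange(int(3 * fs)) / fs
        y = a * np.sin(2 * np.pi * f * t)
        lateral_only = swing_distance(
            np.column_stack([np.zeros_like(y), y]), y, fs, 100.0)
        with_forward = swing_distance(
            np.column_stack([100.0 * t, y]), y, fs, 100.0)
        assert with_forward > lateral_only

    def test_zero_amplitude_site_raises(self):
        fs = 500.0
        flat = np.zeros(1000)
        with pytest.raises(StrokeError):
            swing_distance(np.zeros((1000, 2)), flat, fs, 100.0)

    def test_recovers_ground_truth(self, clean_trial):
        lat = body_frame(clean_trial.midlines)
        gt = clean_trial.ground_truth.swing_distance_bl
        for site, col in [(40, 39), (60, 59), (80, 79)]:
            est = swing_distance(clean_trial.midlines.points[:, col, :],
                                 lat[:, col], clean_trial.spec.frame_rate,
                                 clean_trial.spec.body_length)
            assert est == pytest.approx(gt[site], rel=0.02)


class TestWaveFrequency:
    def test_two_hertz_wave(self, clean_trial):
        lat = body_frame(clean_trial.midlines)
        est = wave_frequency(lat[:, 59], clean_trial.spec.frame_rate)
        assert est == pytest.approx(2.0, rel=0.02)

    def test_frame_rate_invariance(self):
        for fs in (500.0, 1000.0):
            t = np.arange(int(3 * fs)) / fs
            y = np.sin(2 * np.pi * 2.0 * t)
            assert wave_frequency(y, fs) == pytest.approx(2.0, rel=0.02)

    def test_constant_signal_raises(self):
        with pytest.raises(StrokeError):
            wave_frequency(np.ones(1000), 500.0)


class TestNoseElevation:
    def make_lm(self, z, fs=500.0, bl=100.0):
        T = len(z)
        pts = np.zeros((T, 3))
        pts[:, 0] = np.linspace(0, 100, T)
        pts[:, 2] = z
        return LandmarkTrajectory(time_s=np.arange(T) / fs,
                                  points={"nose": pts}, frame_rate=fs,
                                  body_length=bl)

    def fin_seg(self, period=1.0, n=3):
        events = []
        for k in range(n):
            events.append(("adduction_start", k * period))
            events.append(("abduction_start", (k + 0.5) * period))
        events.append(("adduction_start", n * period))
        return StrokeSegmentation(stroke_kind="fin", events=events)

    def test_flat_trajectory_is_zero(self):
        lm = self.make_lm(np.zeros(1500))
        mag, _ = nose_elevation(lm, self.fin_seg())
        assert mag == pytest.approx(0.0, abs=1e-12)

    def test_peak_at_cycle_midpoint_is_180_degrees(self):
        fs = 500.0
        t = np.arange(1500) / fs
        z = 10.0 * 0.5 * (1 - np.cos(2 * np.pi * 1.0 * t))  # peaks at k+0.5 s
        mag, phases = nose_elevation(self.make_lm(z, fs), self.fin_seg())
        assert np.allclose(phases, 180.0, atol=5.0)
        assert mag == pytest.approx(0.1, rel=0.02)

    def test_recovers_generator_elevation(self, clean_trial):
        from depthgait.fin import fin_angle
        ang = fin_angle(clean_trial.landmarks, "right")
        seg = segment_strokes(ang, clean_trial.spec.frame_rate, "fin")
        mag, phases = nose_elevation(clean_trial.landmarks, seg)
        gt = clean_trial.ground_truth
        assert mag == pytest.approx(gt.nose_elevation_bl, rel=0.02)
        assert np.allclose(phases, gt.nose_elevation_phase_deg, atol=10.0)

    def test_missing_z_raises(self):
        lm = self.make_lm(np.full(1500, np.nan))
        with pytest.raises(ValueError, match="z"):
            nose_elevation(lm, self.fin_seg())


class TestMaxAmplitudePhase:
    def test_phases_are_in_range_and_lag_along_body(self, clean_trial):
        lat = body_frame(clean_trial.midlines)
        fs = clean_trial.spec.frame_rate
        tail = segment_strokes(lat[:, -1], fs, "tail")
        out = max_amplitude_phase(lat, fs, tail)
        for vals in out.values():
            assert np.all((vals >= 0) & (vals < 360))
        # traveling wave: the 80% site peaks (1 - s)/lambda of a cycle before
        # the tail, i.e. later in the cycle than the 40% site by 144 deg
        m40, _ = _circ_mean(out[(40.0, "left")])
        m80, _ = _circ_mean(out[(80.0, "left")])
        assert (m80 - m40) % 360 == pytest.approx(144.0, abs=8.0)

    def test_site_outside_body_raises(self, clean_trial):
        lat = body_frame(clean_trial.midlines)
        fs = clean_trial.spec.frame_rate
        tail = segment_strokes(lat[:, -1], fs, "tail")
        with pytest.raises(ValueError, match="site"):
            max_amplitude_phase(lat, fs, tail, sites=(120.0,))


def _circ_mean(deg):
    z = np.exp(1j * np.radians(deg)).mean()
    return np.degrees(np.angle(z)) % 360, 1 - np.abs(z)


def test_curvature_monotone_in_amplitude_on_noiseless_sweep():
    base = TrialSpec(duration=2.0, seed=11)
    ts = generate_depth_sweep(base, [3.0, 0.9, 0.7])
    by_depth = {}
    for trial in ts:
        scale = trial.ground_truth.mapping["amplitude_slope"]
        by_depth[trial.depth_bd] = curvature_coefficient(trial.midlines)
    assert by_depth[0.7] > by_depth[0.9] > by_depth[3.0]
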