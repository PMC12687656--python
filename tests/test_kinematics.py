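"""Event detection, step geometry, COM model, angles and fall rule."""

import numpy as np
import pytest

from slipsynergy import kinematics as kin
from slipsynergy import synthetic
from slipsynergy.io_model import LoadCellTrial, MarkerTrial
from slipsynergy.kinematics import (
    DEFAULT_SEGMENT_TABLE,
    SegmentRow,
    TrialEvents,
    com_estimate,
    com_state,
    detect_bon,
    detect_fall,
    detect_step_events,
    lowpass_markers,
    step_metrics,
    trunk_arm_angles,
)


def static_markers(n_frames=600, rate=120.0, height=1.70):
    posture = synthetic._standing_posture(height)
    names = list(posture)
    pos = np.empty((len(names), n_frames, 3))
    for i, name in enumerate(names):
        pos[i] = posture[name]
    return MarkerTrial(names, pos, rate)


class TestLowpass:
    def test_constant_unchanged(self):
        m = static_markers()
        out = lowpass_markers(m)
        np.testing.assert_allclose(out.positions, m.positions, atol=1e-9)

    def test_passband_amplitude_preserved(self):
        t = np.arange(1200) / 120.0
        m = static_markers(1200)
        m.positions[0, :, 0] += 0.1 * np.sin(2 * np.pi * 1.0 * t)
        out = lowpass_markers(m, 6.0)
        amp = np.ptp(out.positions[0, 200:-200, 0]) / 2
        assert amp == pytest.approx(0.1, rel=0.01)

    def test_stopband_attenuated(self):
        t = np.arange(1200) / 120.0
        m = static_markers(1200)
        m.positions[0, :, 0] += 0.1 * np.sin(2 * np.pi * 30.0 * t)
        out = lowpass_markers(m, 6.0)
        amp = np.ptp(out.positions[0, 200:-200, 0]) / 2
        assert amp < 0.01  # > 90% attenuation

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_markers(static_markers(), 80.0)


class TestDetectBon:
    def _belt_trial(self, accel=11.35):
        belt = synthetic.make_belt_profile(0.18, 0.45, accel)
        t = np.arange(600) / 120.0
        traj = np.zeros((600, 3))
        onset = 2.0
        traj[:, 0] = np.interp(t - onset, np.arange(belt.position.size) / 120.0,
                               belt.position, left=0.0, right=belt.position[-1])
        return traj, onset

    def test_trapezoid_onset_within_one_frame(self):
        traj, onset = self._belt_trial()
        bon = detect_bon(traj, 120.0)
        # 0.05 m/s at 11.35 m/s^2 is reached 4.4 ms after motion start
        assert abs(bon - onset) <= 1.0 / 120.0

    def test_stationary_belt_rejected(self):
        with pytest.raises(ValueError, match="never exceeds"):
            detect_bon(np.zeros((600, 3)), 120.0)

    def test_single_frame_spike_ignored(self):
        traj = np.zeros((600, 3))
        traj[300, 0] = 0.01  # 1-frame blip, central-diff v ~ 0.6 m/s
        with pytest.raises(ValueError):
            detect_bon(traj, 120.0)


class TestStepEvents:
    def test_scripted_min_jerk_step_recovered(self):
        t = np.arange(720) / 120.0
        lift, td = 3.0, 3.17
        traj = np.zeros((720, 3))
        tau = (t - lift) / (td - lift)
        traj[:, 0] = -0.2 * synthetic._min_jerk(tau)
        got_lift, got_td = detect_step_events(traj, 120.0, bon_s=2.7)
        assert abs(got_lift - lift) <= 1.0 / 120.0
        assert abs(got_td - td) <= 1.0 / 120.0

    def test_stationary_heel_rejected(self):
        with pytest.raises(ValueError, match="burst"):
            detect_step_events(np.zeros((600, 3)), 120.0, bon_s=2.0)

    def test_execution_time_recovered_across_seeded_trials(self, ground_truth):
        errs = []
        for seed in range(17):
            session, _, scripts = synthetic.make_session(ground_truth, "P", seed=seed)
            for b, sc in zip(session.trials[:3], scripts[:3]):
                ev = kin.detect_events(b.markers, b.recovery_side)
                exec_err = (ev.td_s - ev.liftoff_s) - (sc.td_s - sc.liftoff_s)
                errs.append(abs(exec_err))
        assert len(errs) >= 50
        assert max(errs) <= 2.0 / 120.0


class TestStepMetrics:
    def test_times_from_events(self):
        m = static_markers()
        ev = TrialEvents(1.00, 1.25, 1.43)
        init, execu, _, _ = step_metrics(m, ev)
        assert init == pytest.approx(0.25)
        assert execu == pytest.approx(0.18)

    def test_length_and_width_at_touchdown(self):
        m = static_markers()
        # recovery (right) heel 0.2 m behind slipping (left) heel
        r = m.marker_names.index("R_heel")
        l = m.marker_names.index("L_heel")
        m.positions[r, :, 0] = 0.30
        m.positions[l, :, 0] = 0.50
        m.positions[r, :, 1] = 0.105
        m.positions[l, :, 1] = -0.105
        _, _, length, width = step_metrics(m, TrialEvents(1.0, 1.25, 1.43))
        assert length == pytest.approx(0.20)
        assert width == pytest.approx(0.21)


class TestComEstimate:
    def test_single_segment_midpoint(self):
        m = static_markers(10)
        table = [SegmentRow("only", "L_hip", "R_hip", 1.0, 0.5)]
        com = com_estimate(m, table)
        expect = 0.5 * (m.trajectory("L_hip") + m.trajectory("R_hip"))
        np.testing.assert_allclose(com, expect, atol=1e-12)

    def test_two_equal_point_masses(self):
        m = static_markers(10)
        l = m.marker_names.index("L_toe")
        r = m.marker_names.index("R_toe")
        m.positions[l, :, 0] = 0.0
        m.positions[r, :, 0] = 1.0
        table = [SegmentRow("a", "L_toe", "L_toe", 0.5, 0.0),
                 SegmentRow("b", "R_toe", "R_toe", 0.5, 0.0)]
        com = com_estimate(m, table)
        assert com[0, 0] == pytest.approx(0.5)

    def test_generator_self_consistency(self, ground_truth):
        """Noise-free generator markers reproduce the generator COM exactly."""
        sc = synthetic.TrialScript("S1", 2.5, 2.75, 2.93, 0.17)
        belt = synthetic.make_belt_profile(*synthetic.TRAINING_BELT)
        m = synthetic.synthesize_markers(sc, 1.70, belt, noise_sd_m=0.0)
        com = com_estimate(m)
        com2 = com_estimate(m, DEFAULT_SEGMENT_TABLE)
        np.testing.assert_allclose(com, com2, atol=1e-9)
        assert abs(sum(r.mass_fraction for r in DEFAULT_SEGMENT_TABLE) - 1) < 1e-9

    def test_bad_mass_fractions_rejected(self):
        m = static_markers(10)
        with pytest.raises(ValueError, match="mass fractions"):
            com_estimate(m, [SegmentRow("x", "L_hip", "R_hip", 0.9, 0.5)])


class TestComState:
    def _setup(self):
        m = static_markers()
        ev = TrialEvents(1.0, 1.25, 1.43, recovery_side="right")
        return m, ev

    def test_com_at_recovery_heel_gives_zero(self):
        m, ev = self._setup()
        frame = int(round(ev.td_s * m.rate_hz))
        com = np.tile(m.trajectory("R_heel")[frame], (m.n_frames, 1))
        ap, _, _, _ = com_state(com, m, ev)
        assert ap == pytest.approx(0.0, abs=1e-12)

    def test_centered_com_ml_norm(self):
        m, ev = self._setup()
        l = m.marker_names.index("L_toe")
        r = m.marker_names.index("R_toe")
        m.positions[l, :, 1] = -0.15
        m.positions[r, :, 1] = 0.15
        com = np.zeros((m.n_frames, 3))  # ML = 0, centered between toes
        _, ml, _, _ = com_state(com, m, ev)
        assert ml == pytest.approx(0.5)

    def test_relative_ap_velocity(self):
        m, ev = self._setup()
        t = np.arange(m.n_frames) / m.rate_hz
        com = np.zeros((m.n_frames, 3))
        com[:, 0] = 0.5 * t
        r = m.marker_names.index("R_heel")
        m.positions[r, :, 0] = m.positions[r, 0, 0] + 0.2 * t
        _, _, ap_vel, _ = com_state(com, m, ev)
        assert ap_vel == pytest.approx(0.3, abs=1e-9)


class TestAngles:
    def test_upright_trunk_and_hanging_arm(self):
        m = static_markers()
        trunk, arm = trunk_arm_angles(m, TrialEvents(1.0, 1.25, 1.43))
        assert trunk == pytest.approx(90.0, abs=1e-6)
        assert arm == pytest.approx(0.0, abs=1e-6)

    def test_45_degree_trunk(self):
        m = static_markers()
        sh_l = m.marker_names.index("L_shoulder")
        sh_r = m.marker_names.index("R_shoulder")
        hip_mid = 0.5 * (m.trajectory("L_hip") + m.trajectory("R_hip"))
        rise = m.positions[sh_l, 0, 2] - hip_mid[0, 2]
        for idx in (sh_l, sh_r):
            m.positions[idx, :, 0] += rise  # forward by the vertical rise
        trunk, _ = trunk_arm_angles(m, TrialEvents(1.0, 1.25, 1.43))
        assert trunk == pytest.approx(45.0, abs=1e-6)


class TestDetectFall:
    def _load(self, peak_frac, bw=700.0):
        force = np.zeros(100)
        force[50] = peak_frac * bw
        return LoadCellTrial(force, 600.0, bw)

    def test_above_threshold_is_fall(self):
        assert detect_fall(self._load(0.31)) is True

    def test_below_threshold_is_not(self):
        assert detect_fall(self._load(0.29)) is False

    def test_exact_boundary_is_not_a_fall(self):
        assert detect_fall(self._load(0.30)) is False


class TestEventOrdering:
    def test_out_of_order_events_raise(self):
        with pytest.raises(ValueError, match="out of order"):
            TrialEvents(bon_s=2.0, liftoff_s=1.5, td_s=3.0)
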