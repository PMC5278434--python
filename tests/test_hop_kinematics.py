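"""Angle definitions, event detectors, alignment band and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import toadhop as th
from toadhop.hop_kinematics import (DegenerateSegmentError,
                                    EventDetectionError, G, HopEvents,
                                    KinematicSeries, wrap_angle)


def _series(times, *, alpha=None, gamma=None, speed=None, vz=None,
            snout_z=None, az=None, wrist_z=None, wrist_vz=None,
            frame_rate=500.0):
    n = times.size
    z = np.zeros(n)
    alpha = z if alpha is None else np.asarray(alpha, float)
    gamma = z if gamma is None else np.asarray(gamma, float)
    return KinematicSeries(
        times=times, alpha=alpha, gamma=gamma,
        delta=wrap_angle(gamma - alpha),
        snout_speed=z if speed is None else np.asarray(speed, float),
        snout_vertical_velocity=z if vz is None else np.asarray(vz, float),
        snout_height=z if snout_z is None else np.asarray(snout_z, float),
        snout_vertical_acceleration=z if az is None else np.asarray(az, float),
        wrist_height=z if wrist_z is None else np.asarray(wrist_z, float),
        wrist_vertical_velocity=(z if wrist_vz is None
                                 else np.asarray(wrist_vz, float)),
        frame_rate=frame_rate, smoothing_used={})


class TestAngles:
    def test_horizontal_limb_is_zero(self):
        a = th.forelimb_angle(np.array([0.1]), np.array([0.05]),
                              np.array([0.0]), np.array([0.05]))
        assert a[0] == 0.0

    def test_vertical_limb_wrist_below(self):
        a = th.forelimb_angle(np.array([0.0]), np.array([0.0]),
                              np.array([0.0]), np.array([0.05]))
        assert a[0] == pytest.approx(-90.0)

    def test_equal_dx_dz_wrist_lower_forward(self):
        a = th.forelimb_angle(np.array([0.03]), np.array([-0.03]),
                              np.array([0.0]), np.array([0.0]))
        assert a[0] == pytest.approx(-45.0)

    def test_coincident_markers_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            th.forelimb_angle(np.array([0.0]), np.array([0.0]),
                              np.array([0.0]), np.array([0.0]))

    def test_gamma_apex_zero(self):
        g = th.velocity_vector_angle(np.array([1.0]), np.array([0.0]))
        assert g[0] == 0.0

    def test_gamma_vertical_drop(self):
        g = th.velocity_vector_angle(np.array([0.0]), np.array([-2.0]))
        assert g[0] == pytest.approx(-90.0)

    def test_gamma_undefined_at_rest(self):
        g = th.velocity_vector_angle(np.array([0.0, 1.0]),
                                     np.array([0.0, 1.0]))
        assert np.isnan(g[0]) and g[1] == pytest.approx(45.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.floats(-720, 720))
    def test_wrap_angle_range(self, x):
        w = float(wrap_angle(x))
        assert -180.0 < w <= 180.0
        assert abs((x - w) % 360.0) < 1e-9 or abs((x - w) % 360.0 - 360) < 1e-9


class TestEventDetectors:
    def test_t0_at_ramp_crossing(self):
        t = np.arange(100) / 500.0
        speed = np.linspace(0.0, 0.2, 100)       # crosses 0.05 at index 25
        s = _series(t, speed=speed)
        k = int(np.argmax(speed > 0.05))
        assert th.detect_hop_initiation(s) == t[k]

    def test_stationary_recording_no_hop(self):
        s = _series(np.arange(50) / 500.0, speed=np.full(50, 0.01))
        with pytest.raises(EventDetectionError, match="no hop detected"):
            th.detect_hop_initiation(s)

    def test_inclusion_filter_sign(self):
        t = np.arange(20) / 500.0
        up = _series(t, vz=np.full(20, 0.01))
        down = _series(t, vz=np.full(20, -0.01))
        flat = _series(t, vz=np.zeros(20))
        assert th.apply_inclusion_filter(up, t[3])
        assert not th.apply_inclusion_filter(down, t[3])
        # boundary: exactly zero vertical velocity is excluded
        assert not th.apply_inclusion_filter(flat, t[3])

    def test_liftoff_purely_ballistic_series(self):
        t = np.arange(100) / 500.0
        s = _series(t, speed=np.full(100, 1.0), az=np.full(100, -G))
        assert th.detect_liftoff(s, t[0]) == t[0]

    def test_liftoff_missing_ballistic_segment(self):
        t = np.arange(100) / 500.0
        s = _series(t, az=np.zeros(100))
        with pytest.raises(EventDetectionError, match="no liftoff"):
            th.detect_liftoff(s, t[0])

    def test_touchdown_missing_when_truncated(self):
        t = np.arange(50) / 500.0
        s = _series(t, snout_z=0.1 + 0.01 * np.arange(50),
                    wrist_z=np.full(50, 0.08), wrist_vz=np.full(50, 0.1))
        with pytest.raises(EventDetectionError, match="no touchdown"):
            th.detect_touchdown(s)

    def test_contact_tolerance_zero_vs_default(self, noisefree_cohort):
        """On clean data a 0 mm and a 3 mm contact tolerance agree to
        within one frame."""
        recordings, *_ = noisefree_cohort
        for rec in recordings[:8]:
            series = th.compute_kinematics(rec, 0.0)
            td3 = th.detect_touchdown(series, 0.003)
            td0 = th.detect_touchdown(series, 0.0)
            assert abs(td0 - td3) <= 1.0 / rec.frame_rate + 1e-12


class TestEventOracle:
    def test_events_match_ground_truth_within_two_frames(
            self, noisefree_cohort):
        _, truth, metrics, info = noisefree_cohort
        assert not info["skipped"]
        gt = truth.to_frame().set_index("hop_id")
        m = metrics.set_index("hop_id")
        tol = 2.0 / 500.0 + 1e-12
        for ev in ("t0", "liftoff", "touchdown"):
            assert (m[ev] - gt[ev]).abs().max() <= tol


class TestAlignmentBand:
    def test_t_interval_hand_computed(self):
        """{-1, +1}: mean 0, SD sqrt(2), SE 1 -> half-width t(.975, 1)."""
        band = th.build_alignment_band([-1.0, 1.0], method="ci_of_mean")
        assert band.lower == pytest.approx(-12.7062, abs=1e-3)
        assert band.upper == pytest.approx(12.7062, abs=1e-3)

    def test_degenerate_values_flagged_zero_width(self):
        band = th.build_alignment_band([0.0, 0.0, 0.0, 0.0],
                                       method="ci_of_mean")
        assert band.lower == band.upper == 0.0

    def test_fixed_halfwidth_width(self):
        band = th.build_alignment_band([3.0, 7.0], method="fixed_halfwidth",
                                       fixed_halfwidth=15.0)
        assert band.upper - band.lower == 30.0
        assert band.lower <= 5.0 <= band.upper

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="insufficient data"):
            th.build_alignment_band([1.0], method="ci_of_mean")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(-60, 60), min_size=2, max_size=40))
    def test_band_contains_its_mean(self, values):
        band = th.build_alignment_band(values, method="ci_of_mean")
        assert band.lower <= float(np.mean(values)) <= band.upper


class TestAlignmentTime:
    def _events(self, t):
        return HopEvents(t0=t[0], liftoff=t[4], touchdown=t[-1],
                        included=True)

    def test_delta_constant_inside_band(self):
        t = np.arange(50) / 500.0
        s = _series(t, gamma=np.full(50, -5.0))      # delta = -5 everywhere
        band = th.AlignmentBand(-15.0, 15.0, "fixed_halfwidth", 10)
        ta, cont = th.alignment_time(s, band, self._events(t))
        assert ta == t[0] and cont is True

    def test_entry_at_frame_k(self):
        t = np.arange(60) / 500.0
        gamma = np.where(np.arange(60) >= 20, -5.0, 40.0)
        s = _series(t, gamma=gamma)
        band = th.AlignmentBand(-15.0, 15.0, "fixed_halfwidth", 10)
        ta, cont = th.alignment_time(s, band, self._events(t))
        assert ta == t[20] and cont is True

    def test_never_enters_band(self):
        t = np.arange(40) / 500.0
        s = _series(t, gamma=np.full(40, 90.0))
        band = th.AlignmentBand(-5.0, 5.0, "fixed_halfwidth", 10)
        ta, cont = th.alignment_time(s, band, self._events(t))
        assert ta is None and cont is None

    def test_dropout_breaks_continual_alignment(self):
        t = np.arange(60) / 500.0
        gamma = np.zeros(60)
        gamma[40:43] = 60.0                       # 3-frame dropout
        s = _series(t, gamma=gamma)
        band = th.AlignmentBand(-15.0, 15.0, "fixed_halfwidth", 10)
        ta, cont = th.alignment_time(s, band, self._events(t))
        assert ta == t[0] and cont is False
        _, cont_tol = th.alignment_time(s, band, self._events(t),
                                        dropout_tolerance_frames=3)
        assert cont_tol is True


class TestHopMetrics:
    def test_bookkeeping_identities(self, noisy_cohort):
        _, _, metrics, _ = noisy_cohort
        m = metrics[metrics.included].dropna(subset=["t_a"])
        np.testing.assert_allclose(m.o_t0 - m.o_lo, m.liftoff - m.t0,
                                   atol=1e-12)
        np.testing.assert_allclose(m.delta_td, m.gamma_td - m.alpha_td,
                                   atol=1e-12)
        assert (m.d_a >= 0).all()
        assert ((m.t0 < m.liftoff) & (m.liftoff < m.touchdown)).all()
        assert ((m.t0 <= m.t_a) & (m.t_a <= m.touchdown)).all()

    def test_excursion_endpoint_difference(self):
        t = np.arange(80) / 500.0
        gamma = np.linspace(20.0, -40.0, 80)
        s = _series(t, gamma=gamma, wrist_z=np.linspace(0.05, -0.01, 80),
                    wrist_vz=np.full(80, -0.5),
                    snout_z=np.concatenate([np.linspace(0, 0.05, 10),
                                            np.linspace(0.05, 0.0, 70)]))
        band = th.AlignmentBand(-999.0, 999.0, "fixed_halfwidth", 10)
        ev = HopEvents(t0=t[0], liftoff=t[4], touchdown=t[-1], included=True)
        rec = type("R", (), {"hop_id": "h", "animal_id": "a",
                             "treatment": "flat"})()
        hm = th.hop_metrics(rec, s, ev, band)
        assert hm.excursion == pytest.approx(60.0)
        assert hm.t_a == t[0]
        assert hm.o_lo == pytest.approx(t[0] - t[4])
        assert hm.d_a == pytest.approx(t[-1] - t[0])

    def test_delta_equals_gamma_minus_alpha_everywhere(self, noisy_cohort):
        recordings, *_ = noisy_cohort
        series = th.compute_kinematics(recordings[0])
        mask = np.isfinite(series.gamma)
        np.testing.assert_array_equal(
            series.delta[mask],
            wrap_angle(series.gamma[mask] - series.alpha[mask]))

    def test_mean_d_a_increases_with_platform_height(self, noisy_cohort):
        _, _, metrics, _ = noisy_cohort
        m = metrics[metrics.included]
        da = m.groupby("treatment")["d_a"].mean()
        assert da["flat"] < da["low"] < da["high"]
        aer = m.groupby("treatment")["aerial_duration"].mean()
        assert aer["flat"] < aer["low"] < aer["high"]
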