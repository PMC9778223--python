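"""Angle sensing, ROM, repetition detection and phase segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kneemon as km
from kneemon.errors import ConfigurationError, DataQualityError


class TestAccelToAngle:
    @pytest.mark.parametrize(
        "sample,expected_deg",
        [
            ((0.0, 0.0, 1.0), 0.0),  # sitting reference pose
            ((1.0, 0.0, 0.0), 90.0),  # fully stretched knee
            ((np.sin(np.radians(45)), 0.0, np.cos(np.radians(45))), 45.0),
            ((0.0, np.sin(np.radians(30)), np.cos(np.radians(30))), 30.0),
        ],
    )
    def test_tilt_angles(self, sample, expected_deg):
        trace = km.accel_to_angle(np.array([sample]))
        assert trace.theta_deg[0] == pytest.approx(expected_deg, abs=1e-9)

    def test_free_fall_rejected(self):
        with pytest.raises(DataQualityError, match="0.5 g"):
            km.accel_to_angle(np.array([[0.1, 0.0, 0.1]]))

    def test_shake_warns(self):
        with pytest.warns(UserWarning, match="quasi-static"):
            km.accel_to_angle(np.array([[0.0, 0.0, 1.6]]))

    def test_default_cadence_is_100_ms(self):
        trace = km.accel_to_angle(np.tile([0.0, 0.0, 1.0], (5, 1)))
        np.testing.assert_allclose(np.diff(trace.timestamps_s), 0.1)


class TestRomAndExtrema:
    def test_constant_trace(self):
        trace = km.AngleTrace(np.arange(10) * 0.1, np.zeros(10))
        assert km.extract_extrema(trace, 0.0, 0.9) == (0.0, 0.0)

    def test_triangle(self):
        theta = np.concatenate([np.linspace(0, 80, 9), np.linspace(80, 0, 9)[1:]])
        trace = km.AngleTrace(np.arange(len(theta)) * 0.1, theta)
        assert km.extract_extrema(trace, 0.0, 1.6) == (80.0, 0.0)

    @given(st.lists(st.floats(min_value=-10, max_value=100), min_size=2, max_size=60))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_extrema_match_exhaustive_scan(self, values):
        trace = km.AngleTrace(np.arange(len(values)) * 0.1, np.asarray(values))
        mx, mn = km.extract_extrema(trace, -1.0, 1e9)
        assert mx == max(values) and mn == min(values)

    @given(
        st.floats(min_value=-100, max_value=200, allow_nan=False),
        st.floats(min_value=-100, max_value=200, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_rom_symmetric_nonnegative(self, a, b):
        assert km.compute_rom(a, b) == km.compute_rom(b, a) >= 0.0

    @pytest.mark.parametrize("a,b,expected", [(90, 0, 90), (87.5, 0.2, 87.3), (33.3, 33.3, 0.0)])
    def test_rom_arithmetic(self, a, b, expected):
        assert km.compute_rom(a, b) == pytest.approx(expected)

    def test_empty_interval_rejected(self):
        trace = km.AngleTrace(np.arange(10) * 0.1, np.zeros(10))
        with pytest.raises(ConfigurationError):
            km.extract_extrema(trace, 5.0, 6.0)


def trapezoid_trace(peak=85.0, rise=2.0, hold=4.0, fall=2.0, lead=2.0, tail=2.0,
                    dt=0.1, noise=0.0, seed=0):
    cfg = km.SimulationConfig(
        seed=seed, reps=1, rise_s=rise, hold_s=hold, fall_s=fall,
        rest_s=tail, lead_in_s=lead, peak_deg=peak, angle_noise_deg=noise,
        angle_sampling_period_s=dt,
    )
    return km.simulate_angle(cfg)


class TestDetectRepetitions:
    def test_recovers_simulated_session(self, sim_session):
        _, angle, truth = sim_session
        reps = km.detect_repetitions(angle)
        assert len(reps) == len(truth) == 5
        for det, gt in zip(reps, truth):
            assert det.t_peak_s == pytest.approx(gt.t_peak_s, abs=gt.sustained_s)
            assert det.rom_deg == pytest.approx(gt.rom_deg, abs=1.5)
        # peak order preserved and intervals disjoint / time ordered
        for a, b in zip(reps, reps[1:]):
            assert a.t_end_s <= b.t_start_s

    def test_flat_trace_yields_no_repetitions(self):
        trace = km.AngleTrace(np.arange(100) * 0.1, np.zeros(100))
        assert km.detect_repetitions(trace) == []

    def test_single_trapezoid_sustained_duration(self):
        angle, _ = trapezoid_trace(peak=85.0, hold=4.0)
        (rep,) = km.detect_repetitions(angle)
        assert 3.5 <= rep.sustained_s <= 4.5
        assert rep.theta_max_deg == pytest.approx(85.0, abs=0.5)

    def test_min_rom_monotonicity(self):
        """Raising the ROM floor never increases the repetition count."""
        angle, _ = trapezoid_trace(peak=85.0, noise=1.0, seed=3)
        counts = [
            len(km.detect_repetitions(angle, km.DetectionParams(min_rom_deg=m)))
            for m in (10.0, 40.0, 84.0, 90.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_unfinished_movement_not_counted(self):
        # trace ends mid-hold: the movement never returns to rest
        cfg = km.SimulationConfig(seed=0, reps=1, rest_s=2.0, lead_in_s=2.0,
                                  angle_noise_deg=0.0)
        angle, _ = km.simulate_angle(cfg)
        cut = angle.slice_time(0.0, cfg.lead_in + cfg.rise_s + 1.0)
        assert km.detect_repetitions(cut) == []

    def test_count_recovery_100_seeds_sigma2(self):
        """Exact rep count at angle noise up to 2 degrees, 100 seeds."""
        for seed in range(100):
            cfg = km.SimulationConfig(seed=seed, rest_s=2.0, angle_noise_deg=2.0)
            angle, truth = km.simulate_angle(cfg)
            assert len(km.detect_repetitions(angle)) == len(truth)

    def test_rom_recovery_unbiased_within_1_deg(self):
        """Mean detected ROM across 100 seeds within +/-1 deg of the peak."""
        roms = []
        for seed in range(100):
            cfg = km.SimulationConfig(seed=seed, rest_s=2.0, angle_noise_deg=0.5)
            angle, _ = km.simulate_angle(cfg)
            roms += [r.rom_deg for r in km.detect_repetitions(angle)]
        assert np.mean(roms) == pytest.approx(88.0, abs=1.0)


class TestSegmentPhases:
    def test_ideal_trapezoid_phase_durations(self):
        angle, _ = trapezoid_trace(peak=85.0, rise=2.0, hold=4.0, fall=2.0)
        (rep,) = km.detect_repetitions(angle)
        phases = km.segment_phases(rep, angle)
        assert phases.rise_s == pytest.approx(2.0, abs=0.1)
        assert phases.sustained_s == pytest.approx(4.0, abs=0.1)
        assert phases.fall_s == pytest.approx(2.0, abs=0.1)
        assert phases.pre_start_s == pytest.approx(rep.t_start_s, abs=0.1)
        total = phases.rise_s + phases.sustained_s + phases.fall_s
        assert total == pytest.approx(rep.t_end_s - rep.t_start_s, abs=0.3)

    def test_triangle_has_no_sustained_phase(self):
        angle, _ = trapezoid_trace(peak=80.0, rise=2.0, hold=0.0, fall=2.0)
        (rep,) = km.detect_repetitions(angle)
        phases = km.segment_phases(rep, angle)
        assert phases.sustained_s == pytest.approx(0.0, abs=0.15)

    def test_noisy_trapezoid_durations_within_300_ms(self):
        angle, _ = trapezoid_trace(peak=85.0, noise=1.0, seed=11)
        (rep,) = km.detect_repetitions(angle)
        phases = km.segment_phases(rep, angle)
        assert phases.rise_s == pytest.approx(2.0, abs=0.3)
        assert phases.sustained_s == pytest.approx(4.0, abs=0.3)
        assert phases.fall_s == pytest.approx(2.0, abs=0.3)


def test_out_of_range_angles_warn():
    with pytest.warns(UserWarning, match="plausible"):
        km.AngleTrace(np.arange(3) * 0.1, np.array([0.0, 150.0, 0.0]))
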