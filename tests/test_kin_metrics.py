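"""Kinematic performance indicators against analytic and brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ulbench.kin_metrics import (
    IdealPath,
    accuracy_pis,
    amplitude_pis,
    coordination_pis,
    efficacy_pis,
    efficiency_pis,
    normalized_dimensionless_jerk,
    planning_pis,
    smoothness_pis,
    sparc,
    speed_pis,
    variable_error,
)
from ulbench.profiles import (
    minimum_jerk_path,
    minimum_jerk_speed,
)

RATE = 100.0


def straight_reach(length=0.3, duration=1.0, rate=RATE):
    pos = minimum_jerk_path(np.zeros(3), np.array([length, 0, 0]),
                            duration, rate)
    t = np.arange(pos.shape[0]) / rate
    tau = t / duration
    speed = minimum_jerk_speed(tau, length, duration)
    return t, pos, speed


def semicircle(radius=0.15, n=2001):
    theta = np.linspace(0.0, np.pi, n)
    x = radius * (1 - np.cos(theta))
    y = radius * np.sin(theta)
    return np.stack([x, y, np.zeros(n)], axis=1)


class TestAccuracy:
    def test_ideal_path_scores_zero(self):
        t, pos, _ = straight_reach()
        ideal = IdealPath(pos[0], pos[-1], 1.0)
        rec = accuracy_pis(t, pos, ideal)
        assert rec["trajectory_absolute_error"].value == pytest.approx(0, abs=1e-9)
        assert rec["end_point_error"].value == pytest.approx(0, abs=1e-9)
        assert rec["area_index"].value == pytest.approx(0, abs=1e-9)

    def test_semicircular_detour_area_matches_shoelace_oracle(self):
        r = 0.15
        path = semicircle(r)
        t = np.arange(path.shape[0]) / 1000.0
        ideal = IdealPath(path[0], path[-1], t[-1])
        rec = accuracy_pis(t, path, ideal)
        # oracle: dense-polygon shoelace area of a half disc = pi r^2 / 2
        assert rec["area_index"].value == pytest.approx(np.pi * r**2 / 2,
                                                        rel=1e-4)

    def test_identical_endpoints_give_zero_variable_error(self):
        errs = np.full(8, 0.012)
        assert variable_error(errs) == 0.0

    def test_single_repetition_not_computable(self):
        t, pos, _ = straight_reach()
        rec = accuracy_pis(t, pos, IdealPath(pos[0], pos[-1], 1.0),
                           endpoint_errors=None)
        assert not rec["variable_error"].computable


class TestEfficacyEfficiency:
    def test_success_rate_arithmetic(self):
        rec = efficacy_pis(3, 4, movement_stops=0)
        assert rec["success_rate"].value == 0.75
        assert rec["number_of_movement_stops"].value == 0

    def test_zero_attempts_not_computable(self):
        rec = efficacy_pis(0, 0, 0)
        assert not rec["success_rate"].computable

    def test_straight_reach_path_ratio_one(self):
        t, pos, _ = straight_reach()
        rec = efficiency_pis(t, pos, 0.0, 1.0,
                             trunk_position=np.zeros_like(pos))
        assert rec["path_length_ratio"].value == pytest.approx(1.0, abs=1e-6)
        assert rec["movement_time"].value == 1.0
        assert rec["trunk_compensation"].value == 0.0

    def test_semicircular_path_ratio_is_pi_over_two(self):
        path = semicircle()
        t = np.arange(path.shape[0]) / 1000.0
        rec = efficiency_pis(t, path, 0.0, float(t[-1]))
        assert rec["path_length_ratio"].value == pytest.approx(np.pi / 2,
                                                               rel=1e-4)

    def test_zero_chord_not_computable(self):
        n = 100
        pos = np.zeros((n, 3))
        pos[:, 0] = np.sin(np.linspace(0, 2 * np.pi, n))  # loop back
        t = np.arange(n) / RATE
        rec = efficiency_pis(t, pos, 0.0, float(t[-1]))
        assert not rec["path_length_ratio"].computable


class TestCoordination:
    def _q(self, q2):
        q = np.zeros((q2.size, 8))
        q[:, 2] = q2
        return q

    def test_linear_relation_gives_unit_correlation(self):
        t = np.arange(200) / RATE
        q2 = 30 * np.sin(2 * np.pi * 0.5 * t)
        q = self._q(q2)
        q[:, 4] = 2.0 * q2 + 5.0
        rec = coordination_pis(t, q, RATE, 0.0, float(t[-1]))
        assert rec["joint_angle_correlation"].value == pytest.approx(1.0)
        q[:, 4] = -2.0 * q2 + 5.0
        rec = coordination_pis(t, q, RATE, 0.0, float(t[-1]))
        assert rec["joint_angle_correlation"].value == pytest.approx(-1.0)

    def test_constant_trace_not_computable(self):
        t = np.arange(100) / RATE
        q = np.zeros((100, 8))
        rec = coordination_pis(t, q, RATE, 0.0, float(t[-1]))
        assert not rec["joint_angle_correlation"].computable


class TestAmplitude:
    def test_static_limb_zero_rom(self):
        t = np.arange(100) / RATE
        q = np.full((100, 8), 15.0)
        pos = np.zeros((100, 3))
        rec = amplitude_pis(t, q, pos, 0.0, float(t[-1]), 0.55)
        assert rec["joint_range_of_motion"].value == 0.0
        assert rec["maximum_reached_distance"].value == 0.0

    def test_elbow_rom_ninety_degrees(self):
        t = np.arange(100) / RATE
        q = np.zeros((100, 8))
        q[:, 4] = np.linspace(90, 180, 100)
        pos = np.zeros((100, 3))
        rec = amplitude_pis(t, q, pos, 0.0, float(t[-1]), 0.55)
        assert rec["joint_range_of_motion"].value == pytest.approx(90.0)
        assert rec.extras["joint_range_of_motion_per_dof_deg"][4] \
            == pytest.approx(90.0)

    def test_normalized_reaching_area_full_extension(self, geom, layout):
        # reach to B: distance sqrt(0.55^2 - 0.30^2) over arm length
        t, pos, _ = straight_reach(length=layout.reach_distance_m)
        rec = amplitude_pis(t, None, pos, 0.0, 1.0, geom.arm_length_m)
        expected = np.sqrt(0.55**2 - 0.30**2) / 0.55
        assert rec["normalized_reaching_area"].value \
            == pytest.approx(expected, rel=1e-9)


class TestPlanning:
    def test_symmetric_profile_peaks_at_half(self):
        t, pos, speed = straight_reach()
        ideal = IdealPath(pos[0], pos[-1], 1.0)
        rec = planning_pis(t, pos, speed, ideal, go_cue_s=0.0,
                           onset_s=0.0, end_s=1.0)
        assert rec["time_to_peak_velocity"].value == pytest.approx(0.5,
                                                                   abs=0.01)
        assert rec["aiming_angle"].value == pytest.approx(0.0, abs=1e-6)
        assert rec["reaction_time"].value == 0.0

    def test_no_movement_marks_everything_not_computable(self):
        t, pos, speed = straight_reach()
        rec = planning_pis(t, pos, speed, IdealPath(pos[0], pos[-1], 1.0),
                           0.0, None, 1.0)
        assert all(not v.computable for v in rec.values.values())


class TestSmoothness:
    def test_minimum_jerk_reference_values(self):
        rate = 1000.0
        t, pos, speed = straight_reach(rate=rate)
        ideal = IdealPath(pos[0], pos[-1], 1.0)
        rec = smoothness_pis(t, pos, speed, rate, 0.0, 1.0, ideal)
        assert rec["number_of_velocity_peaks"].value == 1
        # oracle: exact integral of squared jerk of the quintic is 720
        assert rec["normalized_dimensionless_jerk"].value \
            == pytest.approx(720.0, rel=0.01)
        # oracle: MAPR = 1 - 2*tau0 with 30 tau^2(1-tau)^2 = 0.1875
        tau0 = brentq(lambda x: 30 * x**2 * (1 - x) ** 2 - 0.1875, 0, 0.5)
        assert rec["movement_arrest_period_ratio"].value \
            == pytest.approx(1 - 2 * tau0, abs=0.005)
        assert rec["speed_correlation_to_ideal"].value \
            == pytest.approx(1.0, abs=1e-6)
        assert rec["peak_speed_ratio"].value == pytest.approx(1 / 1.875,
                                                              rel=0.01)

    def test_bounded_ratios(self):
        t, pos, speed = straight_reach()
        rec = smoothness_pis(t, pos, speed, RATE, 0.0, 1.0)
        assert 0.0 <= rec["movement_arrest_period_ratio"].value <= 1.0
        assert 0.0 < rec["peak_speed_ratio"].value <= 1.0

    def test_sparc_invariant_to_amplitude_scaling(self):
        t = np.linspace(0, 1, 101)
        v = minimum_jerk_speed(t, 0.3, 1.0)
        assert sparc(v, RATE) == pytest.approx(sparc(2.0 * v, RATE))

    def test_ndj_invariant_to_scaling(self):
        # dimensionless by construction: amplitude and time rescaling
        p1 = minimum_jerk_path(np.zeros(3), np.array([0.3, 0, 0]), 1.0, 500)
        p2 = minimum_jerk_path(np.zeros(3), np.array([0.9, 0, 0]), 2.0, 250)
        a = normalized_dimensionless_jerk(p1, 500.0)
        b = normalized_dimensionless_jerk(p2, 250.0)
        assert a == pytest.approx(b, rel=0.01)

    def test_second_bump_degrades_smoothness(self):
        rate = 500.0
        one = minimum_jerk_path(np.zeros(3), np.array([0.3, 0, 0]), 1.0, rate)
        half1 = minimum_jerk_path(np.zeros(3), np.array([0.15, 0, 0]),
                                  0.5, rate)
        half2 = minimum_jerk_path(np.array([0.15, 0, 0]),
                                  np.array([0.3, 0, 0]), 0.5, rate)
        two = np.concatenate([half1[:-1], half2], axis=0)
        ndj_one = normalized_dimensionless_jerk(one, rate)
        ndj_two = normalized_dimensionless_jerk(two, rate)
        assert ndj_two > ndj_one
        v_one = np.linalg.norm(np.gradient(one, 1 / rate, axis=0), axis=1)
        v_two = np.linalg.norm(np.gradient(two, 1 / rate, axis=0), axis=1)
        assert sparc(v_two, rate) < sparc(v_one, rate)

    def test_degenerate_movement_rejected(self):
        t = np.arange(30) / RATE
        with pytest.raises(ValueError):
            smoothness_pis(t, np.zeros((30, 3)), np.zeros(30), RATE,
                           0.0, float(t[-1]))


class TestSpeed:
    def test_mean_and_peak_velocity(self):
        rate = 1000.0
        t, pos, speed = straight_reach(rate=rate)
        ideal = IdealPath(pos[0], pos[-1], 1.0)
        rec = speed_pis(t, speed, 0.0, 1.0, ideal)
        assert rec["mean_velocity"].value == pytest.approx(0.3, rel=0.01)
        assert rec["peak_velocity"].value == pytest.approx(1.875 * 0.3,
                                                           rel=0.001)
        assert rec["mean_velocity_variability"].value \
            == pytest.approx(0.0, abs=1e-9)
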