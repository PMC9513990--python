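"""Worksheet schema, target layout geometry, PI selection, reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from ulbench.kinematics import ArmGeometry
from ulbench.protocol import (
    DisturbanceSpec,
    build_target_layout,
    generate_report,
    load_worksheet,
    select_pis,
)
from ulbench.segmentation import ValidityReport
from ulbench.kin_metrics import PIRecord
from ulbench.taxonomy import (
    Domain,
    GravityMode,
    MotorAbility,
    classify_environment,
)


def minimal_sheet(**overrides):
    doc = {
        "subject": {"upper_arm_cm": 30, "forearm_cm": 25},
        "skills": [{"skill": "anterior_reaching_rest_height"}],
    }
    doc.update(overrides)
    return doc


class TestWorksheet:
    def test_minimal_sheet_defaults(self):
        ws = load_worksheet(minimal_sheet())
        assert ws.skills[0].repetitions == 8
        assert ws.system == "subject_only"
        assert ws.object.volume_l == 0.5

    def test_gravity_compensation_out_of_range_rejected(self):
        doc = minimal_sheet(
            system="subject_plus_robot",
            robot={"type": "exoskeleton", "training_modality": "transparent",
                   "n_dofs": 4, "passive_dofs": [["shoulder", 1.2]]})
        with pytest.raises((ValueError, ValidationError), match=r"\[0, 1\]"):
            load_worksheet(doc)

    def test_assistance_out_of_range_rejected(self):
        doc = minimal_sheet(
            system="subject_plus_robot",
            robot={"type": "exoskeleton", "training_modality": "transparent",
                   "n_dofs": 4, "actuated_dofs": [["elbow", -1.5]]})
        with pytest.raises((ValueError, ValidationError), match=r"\[-1, \+1\]"):
            load_worksheet(doc)

    def test_unknown_training_modality_rejected(self):
        doc = minimal_sheet(
            system="subject_plus_robot",
            robot={"type": "exoskeleton", "training_modality": "magic",
                   "n_dofs": 4})
        with pytest.raises((ValueError, ValidationError)):
            load_worksheet(doc)

    def test_transparent_robot_classified_gravity(self):
        doc = minimal_sheet(
            system="subject_plus_robot",
            robot={"type": "end_effector", "training_modality": "transparent",
                   "n_dofs": 2, "actuated_dofs": [["elbow", 0.0]]})
        ws = load_worksheet(doc)
        assert classify_environment(ws).gravity_mode is GravityMode.GRAVITY

    def test_robot_in_charge_classified_micro_gravity(self):
        doc = minimal_sheet(
            system="subject_plus_robot",
            robot={"type": "exoskeleton",
                   "training_modality": "robot_in_charge", "n_dofs": 4,
                   "actuated_dofs": [["elbow", 1.0]]})
        ws = load_worksheet(doc)
        assert classify_environment(ws).gravity_mode \
            is GravityMode.MICRO_GRAVITY

    def test_seatback_angle_range(self):
        with pytest.raises((ValueError, ValidationError), match="100"):
            load_worksheet(minimal_sheet(seatback_angle_deg=90))
        assert load_worksheet(
            minimal_sheet(seatback_angle_deg=105)).seatback_angle_deg == 105

    def test_emg_domain_requires_muscles(self):
        with pytest.raises((ValueError, ValidationError), match="muscles"):
            load_worksheet(minimal_sheet(
                outcome_domains=["kinematics", "emg"]))

    def test_hand_to_mouth_expansion(self):
        ws = load_worksheet(minimal_sheet(skills=[
            {"skill": "hand_to_mouth", "object_present": True},
            {"skill": "hand_to_mouth"},
        ]))
        assert ws.skills[0].skill.value == "hand_to_mouth_with_object"
        assert ws.skills[1].skill.value == "hand_to_mouth_without_object"

    def test_round_trip_identity(self):
        ws = load_worksheet(minimal_sheet())
        ws2 = load_worksheet(ws.dump())
        assert ws2 == ws

    def test_disturbance_must_be_quantitative(self):
        with pytest.raises((ValueError, ValidationError)):
            DisturbanceSpec(kind="motor_perturbation")
        with pytest.raises((ValueError, ValidationError)):
            DisturbanceSpec(kind="other")
        spec = DisturbanceSpec(kind="payload", payload_mass_kg=0.5)
        assert spec.payload_mass_kg == 0.5


class TestTargetLayout:
    def test_rest_height_reach_distance(self, geom):
        lay = build_target_layout(geom, 0.30, "rest_height")
        assert lay.reach_distance_m == pytest.approx(
            np.sqrt(0.55**2 - 0.30**2), abs=1e-9)

    def test_shoulder_height_reach_is_arm_length(self, geom):
        lay = build_target_layout(geom, 0.30, "shoulder_height")
        assert lay.reach_distance_m == pytest.approx(0.55)

    def test_diagonal_targets_at_45_degrees(self, geom):
        lay = build_target_layout(geom, 0.30, "rest_height")
        a, b = lay.point("A"), lay.point("B")
        for lbl in ("C", "D"):
            c = lay.point(lbl)
            u = (b - a)[[0, 2]]
            v = (c - a)[[0, 2]]
            cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            assert np.degrees(np.arccos(cosang)) == pytest.approx(45.0,
                                                                  abs=1e-9)

    @given(st.floats(0.2, 0.4), st.floats(0.18, 0.35), st.floats(0.05, 0.3))
    @settings(max_examples=200, deadline=None)
    def test_layout_invariants_over_random_geometries(self, ua, fa, h):
        geom = ArmGeometry(ua, fa)
        if h >= geom.arm_length_m:
            return
        lay = build_target_layout(geom, h, "rest_height")
        a = lay.point("A")
        r = lay.reach_distance_m
        for lbl in ("B", "C", "D"):
            d = np.linalg.norm((lay.point(lbl) - a)[[0, 2]])
            assert d == pytest.approx(r, abs=1e-9)

    def test_infeasible_layout_rejected(self, geom):
        with pytest.raises(ValueError, match="infeasible"):
            build_target_layout(geom, 0.60, "rest_height")


class TestSelectPIs:
    def test_kinematics_only_excludes_emg(self):
        ws = load_worksheet(minimal_sheet())
        pis = select_pis(ws)
        assert all(d.domain is Domain.KINEMATICS for d in pis)
        mandatory = [d for d in pis if d.mandatory]
        # six of the seven mandatory indicators are kinematic
        assert len(mandatory) == 6

    def test_both_domains_mandatory_only_gives_seven(self):
        ws = load_worksheet(minimal_sheet(
            outcome_domains=["kinematics", "emg"],
            setup={"muscles": ["biceps_brachii", "triceps_brachii"]}))
        pis = select_pis(ws, mandatory_only=True)
        assert len(pis) == 7

    def test_power_with_kinematics_only_is_error(self):
        ws = load_worksheet(minimal_sheet())
        with pytest.raises(ValueError, match="power"):
            select_pis(ws, abilities=[MotorAbility.POWER])


class TestGenerateReport:
    @staticmethod
    def _result(trial_id, valid=True, value=1.0):
        rec = PIRecord(MotorAbility.SPEED)
        rec.add("mean_velocity", value, "m/s")
        validity = (ValidityReport(True, 5.0, 2.0) if valid
                    else ValidityReport(False, 25.0, 2.0, ["trunk_sagittal"]))
        return {"trial_id": trial_id, "skill": "anterior_reaching_rest_height",
                "validity": validity, "pi_records": [rec]}

    def test_eight_valid_repetitions_aggregate(self):
        ws = load_worksheet(minimal_sheet())
        results = [self._result(f"t{i}", value=0.4 + 0.01 * i)
                   for i in range(8)]
        rep = generate_report(ws, results)
        cell = rep["performance_indicators"][
            "anterior_reaching_rest_height"]["speed"]["mean_velocity"]
        assert cell["n"] == 8
        assert cell["mean"] == pytest.approx(np.mean(
            [0.4 + 0.01 * i for i in range(8)]))
        assert rep["exclusions"] == []

    def test_invalid_trial_excluded_and_listed(self):
        ws = load_worksheet(minimal_sheet())
        results = [self._result("ok"), self._result("bad", valid=False)]
        rep = generate_report(ws, results)
        assert rep["n_repetitions_included"] == 1
        assert rep["exclusions"][0]["trial_id"] == "bad"
        assert rep["exclusions"][0]["reasons"] == ["trunk_sagittal"]

    def test_uncomputable_mandatory_pi_raises_warning_block(self):
        ws = load_worksheet(minimal_sheet())
        rec = PIRecord(MotorAbility.SPEED)
        rec.add("mean_velocity", None, "m/s", reason="no movement detected")
        rep = generate_report(ws, [{
            "trial_id": "t0", "skill": "anterior_reaching_rest_height",
            "validity": ValidityReport(True, 1.0, 1.0), "pi_records": [rec]}])
        assert any("mean_velocity" in w for w in rep["warnings"])

    def test_empty_trial_set_rejected(self):
        ws = load_worksheet(minimal_sheet())
        with pytest.raises(ValueError, match="at least one"):
            generate_report(ws, [])
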