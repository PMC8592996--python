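"""Rigid-body chain: posing, moment arms, gravity/load/IAP/passive moments.

The moment-arm matrix is validated against an independent tendon-excursion
oracle: for unit tension, the moment about a joint axis equals minus the
derivative of path length with respect to rotation about that axis.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import spineload as sl
from spineload.kinematics import JOINTS, Posture, RhythmCoefficients
from spineload.model import (
    JOINT_ORDER,
    SEGMENT_ORDER,
    HandLoad,
    IAPConfig,
    fascicle_length,
    pose_chain,
)


def neutral_posture(rhythm, hands=()):
    return Posture.from_total((0, 0, 0), (0, 0, 0), rhythm, hand_positions=hands)


def flexed_posture(rhythm, flexion=40.0, lateral=0.0, axial=0.0, pelvis=(0, 0, 0)):
    return Posture.from_total(pelvis, (flexion, lateral, axial), rhythm)


class TestBuildChain:
    def test_joint_count_is_six(self, male_chain):
        assert male_chain.joint_count == 6
        assert len(JOINT_ORDER) == 6

    def test_lumbar_region_length_scales_with_stature(self, male_subject, male_chain):
        frac = male_chain.geometry["segment_fractions"]["lumbar_height"]
        total = sum(male_chain.segments[s].length for s in ("L5", "L4", "L3", "L2", "L1"))
        assert total == pytest.approx(frac * male_subject.stature, abs=1e-12)

    def test_segment_masses_from_table(self, male_subject, male_params, male_chain):
        expected = sl.segment_masses(male_params.mass_table, male_subject.mass)
        assert male_chain.segments["thorax"].mass == pytest.approx(expected["thorax"])
        lumbar_total = sum(male_chain.segments[s].mass for s in ("L5", "L4", "L3", "L2", "L1"))
        assert lumbar_total == pytest.approx(expected["lumbar"])

    def test_tiny_subject_has_negligible_weights(self, male_params, rhythm):
        subject = sl.SubjectProfile("male", 1.769, 1e-9, 30.0)
        params = sl.make_parameter_set("male_base", subject)
        chain = sl.build_chain(subject, params)
        posed = pose_chain(chain, neutral_posture(rhythm))
        for joint in JOINT_ORDER:
            assert np.linalg.norm(sl.gravity_moment(posed, joint)) < 1e-8

    def test_missing_geometry_segment_rejected(self, male_subject, male_params):
        from spineload.config import default_geometry

        geo = default_geometry()
        geo["fascicles"][0]["origin"]["segment"] = "sacrum"
        with pytest.raises(ValueError, match="unknown segment"):
            sl.build_chain(male_subject, male_params, geo)

    def test_fascicle_strengths(self, male_chain, male_params):
        for fas in male_chain.fascicles:
            assert fas.strength == pytest.approx(
                fas.pcsa * male_params.specific_tension * male_params.strength_scale
            )


class TestPoseChain:
    def test_neutral_positions_are_cumulative_offsets(self, male_subject, male_chain, rhythm):
        posed = pose_chain(male_chain, neutral_posture(rhythm))
        z0 = male_chain.geometry["segment_fractions"]["l5s1_height"] * male_subject.stature
        assert np.allclose(posed.joint_centers["L5S1"], [0, 0, z0])
        h = male_chain.segments["L5"].length
        assert np.allclose(posed.joint_centers["L4L5"], [0, 0, z0 + h])
        assert np.allclose(posed.joint_centers["T12L1"], [0, 0, z0 + 5 * h])

    def test_single_joint_90_degree_flexion(self, male_chain):
        """All flexion at L5-S1 swings the column onto the +X axis."""
        all_caudal = RhythmCoefficients(
            flexion=(0, 0, 0, 0, 0, 1.0), lateral=(1 / 6,) * 6, axial=(1 / 6,) * 6
        )
        posture = Posture.from_total((0, 0, 0), (90, 0, 0), all_caudal)
        posed = pose_chain(male_chain, posture)
        z0 = posed.joint_centers["L5S1"][2]
        h = male_chain.segments["L5"].length
        assert np.allclose(posed.joint_centers["L4L5"], [h, 0, z0], atol=1e-12)
        assert np.allclose(posed.joint_centers["T12L1"], [5 * h, 0, z0], atol=1e-12)

    def test_single_plane_posture_round_trip(self, male_chain, rhythm):
        """For a single-plane rotation the per-joint split composes exactly
        back to the total trunk-pelvis angle."""
        for total in ((35.0, 0, 0), (0, -12.0, 0), (0, 0, 15.0)):
            posture = Posture.from_total((10, 0, 0), total, rhythm)
            posed = pose_chain(male_chain, posture)
            recovered = sl.trunk_pelvis_rotation(
                posed.frames["thorax"], posed.frames["pelvis"]
            )
            assert np.allclose(recovered, total, atol=1e-9)

    def test_multi_plane_posture_composes_joint_rotations(self, male_chain, rhythm):
        """The thorax frame is exactly the composition of the six per-joint
        rotations (cross-plane terms make it differ slightly from a single
        rotation by the summed angles)."""
        from spineload.kinematics import euler_to_matrix

        posture = flexed_posture(rhythm, 35.0, -7.0, 12.0, pelvis=(10, 0, 0))
        posed = pose_chain(male_chain, posture)
        expected = euler_to_matrix(np.asarray(posture.pelvis_angles, dtype=float))
        for angles in posture.joint_rotations[::-1]:  # caudal joint first
            expected = expected @ euler_to_matrix(angles)
        assert np.allclose(posed.frames["thorax"], expected, atol=1e-12)

    def test_posing_is_deterministic(self, male_chain, rhythm):
        posture = flexed_posture(rhythm, 25.0, 5.0, -10.0)
        a = pose_chain(male_chain, posture)
        b = pose_chain(male_chain, posture)
        for name in a.fascicle_points:
            assert np.array_equal(a.fascicle_points[name], b.fascicle_points[name])
        for key in a.frames:
            assert np.array_equal(a.frames[key], b.frames[key])

    def test_joint_centers_shared_between_segments(self, male_chain, rhythm):
        posed = pose_chain(male_chain, flexed_posture(rhythm, 30.0))
        for j, joint in enumerate(JOINT_ORDER):
            sup = SEGMENT_ORDER[j + 1]
            assert np.allclose(posed.joint_centers[joint], posed.origins[sup], atol=1e-9)


class TestMomentArms:
    def test_vertical_probe_fascicle_arm(self, male_subject, male_params, rhythm):
        """A vertical line 0.05 m anterior to the joints has a 0.05 m arm."""
        from spineload.config import default_geometry

        geo = default_geometry()
        geo["fascicles"].append(
            {
                "name": "probe",
                "muscle": "rectus_abdominis",
                "group": "global",
                "weight": 1e-9,
                "origin": {"segment": "pelvis", "xyz": [0.05, 0.0, -0.05]},
                "insertion": {"segment": "thorax", "xyz": [0.05, 0.0, 0.05]},
            }
        )
        chain = sl.build_chain(male_subject, male_params, geo)
        posed = pose_chain(chain, neutral_posture(rhythm))
        arms = sl.moment_arm_matrix(posed, "L3L4")
        names = [f.name for f in chain.fascicles]
        row = arms[names.index("probe_l")]
        scale = male_subject.stature / geo["reference_stature"]
        assert np.allclose(row, [0.0, 0.05 * scale, 0.0], atol=1e-12)

    def test_fascicle_through_joint_centre_has_zero_row(
        self, male_subject, male_params, rhythm
    ):
        from spineload.config import default_geometry

        geo = default_geometry()
        geo["fascicles"].append(
            {
                "name": "axial_probe",
                "muscle": "rectus_abdominis",
                "group": "global",
                "weight": 1e-9,
                "origin": {"segment": "pelvis", "xyz": [0.0, 0.0, -0.05]},
                "insertion": {"segment": "thorax", "xyz": [0.0, 0.0, 0.05]},
            }
        )
        chain = sl.build_chain(male_subject, male_params, geo)
        posed = pose_chain(chain, neutral_posture(rhythm))
        names = [f.name for f in chain.fascicles]
        row = sl.moment_arm_matrix(posed, "L3L4")[names.index("axial_probe_l")]
        assert np.allclose(row, 0.0, atol=1e-12)

    @pytest.mark.parametrize("flexion,lateral,axial", [(0, 0, 0), (40, 0, 0), (20, 10, -15)])
    def test_tendon_excursion_oracle(self, male_chain, rhythm, flexion, lateral, axial):
        """Moment arm about each axis equals -dL/dtheta (finite difference)."""
        posture = flexed_posture(rhythm, flexion, lateral, axial)
        posed = pose_chain(male_chain, posture)
        delta = 1e-6  # rad
        for joint in ("L5S1", "L3L4", "T12L1"):
            j = JOINT_ORDER.index(joint)
            arms = sl.moment_arm_matrix(posed, joint)
            c = posed.joint_centers[joint]
            for axis_idx, axis in enumerate(np.eye(3)):
                rot = Rotation.from_rotvec(delta * axis).as_matrix()
                for k, fas in enumerate(male_chain.fascicles):
                    if not fas.crosses_joint(j):
                        continue
                    points = posed.fascicle_points[fas.name].copy()
                    length0 = np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1))
                    # rotate every path point anchored above the joint
                    for i, (seg, _) in enumerate(fas.path):
                        if SEGMENT_ORDER.index(seg) > j:
                            points[i] = c + rot @ (points[i] - c)
                    length1 = np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1))
                    oracle_arm = -(length1 - length0) / delta
                    assert arms[k, axis_idx] == pytest.approx(oracle_arm, abs=1e-4)


class TestGravityAndHandMoments:
    def test_gravity_moment_matches_brute_force(self, male_chain, rhythm):
        posed = pose_chain(male_chain, flexed_posture(rhythm, 45.0, 5.0, 0.0, pelvis=(20, 0, 0)))
        for joint in JOINT_ORDER:
            m = sl.gravity_moment(posed, joint)
            c = posed.joint_centers[joint]
            j = JOINT_ORDER.index(joint)
            above = set(SEGMENT_ORDER[j + 1 :])
            brute = np.zeros(3)
            for name, mass, com in posed.point_masses:
                if name in above or name.split("_")[0] in ("head", "upper", "lower", "hands"):
                    brute += np.cross(com - c, mass * posed.gravity)
            assert np.allclose(m, brute, atol=1e-9)

    def test_gravity_moment_linear_in_g(self, male_chain, rhythm):
        posed = pose_chain(male_chain, flexed_posture(rhythm, 30.0))
        m1 = sl.gravity_moment(posed, "L5S1")
        posed.gravity = posed.gravity * 2.0
        assert np.allclose(sl.gravity_moment(posed, "L5S1"), 2.0 * m1)

    def test_hand_load_above_joint_no_flexion_moment(self, male_chain, rhythm):
        posed = pose_chain(male_chain, neutral_posture(rhythm))
        c = posed.joint_centers["L5S1"]
        load = HandLoad(10.0, "bilateral_box", (tuple(c + [0, 0, 0.5]),))
        assert np.allclose(sl.hand_load_moment(load, posed, "L5S1"), 0.0, atol=1e-12)

    def test_hand_load_anterior_offset(self, male_chain, rhythm):
        posed = pose_chain(male_chain, neutral_posture(rhythm))
        c = posed.joint_centers["L5S1"]
        load = HandLoad(10.0, "bilateral_box", (tuple(c + [0.40, 0, -0.2]),))
        m = sl.hand_load_moment(load, posed, "L5S1")
        assert m[1] == pytest.approx(10.0 * 9.81 * 0.40, abs=1e-9)

    def test_unilateral_lateral_offset_cross_product(self, male_chain, rhythm):
        posed = pose_chain(male_chain, neutral_posture(rhythm))
        c = posed.joint_centers["L5S1"]
        pos = c + np.array([0.0, -0.20, 0.0])
        load = HandLoad(10.0, "unilateral", (tuple(pos),))
        m = sl.hand_load_moment(load, posed, "L5S1")
        oracle = np.cross(pos - c, np.array([0, 0, -10.0 * 9.81]))
        assert np.allclose(m, oracle, atol=1e-12)
        assert m[0] == pytest.approx(-0.20 * 10.0 * 9.81 * -1.0, abs=1e-9)

    def test_unilateral_load_with_two_positions_rejected(self):
        with pytest.raises(ValueError):
            HandLoad(10.0, "unilateral", ((0, 0, 1), (0, 0, 1)))

    def test_bilateral_split_halves_mass(self):
        load = HandLoad(10.0, "bilateral_dumbbells", ((0.1, 0.2, 1.0), (0.1, -0.2, 1.0)))
        masses = [m for m, _ in load.point_masses()]
        assert masses == [5.0, 5.0]

    def test_symmetric_posture_no_out_of_plane_moments(self, male_chain, rhythm, tasks):
        """Left/right symmetric geometry + load: lateral and axial moments vanish."""
        from spineload.synth import task_posture

        posture, load = task_posture(tasks["T6"], male_chain.subject)
        posed = pose_chain(male_chain, posture, (load,))
        for joint in JOINT_ORDER:
            m = sl.gravity_moment(posed, joint) + sl.hand_load_moment(load, posed, joint)
            assert abs(m[0]) < 1e-9 and abs(m[2]) < 1e-9


class TestIAPAndPassive:
    def test_zero_pressure(self):
        assert sl.iap_extensor_moment(0.0, IAPConfig()) == 0.0

    def test_cap_binds_at_26_6_kpa(self):
        cfg = IAPConfig(max_pressure_kpa=26.6, effective_area_m2=0.01, lever_arm_m=0.05)
        assert sl.iap_extensor_moment(40.0, cfg) == pytest.approx(
            26.6e3 * 0.01 * 0.05
        )

    def test_moment_product(self):
        cfg = IAPConfig(max_pressure_kpa=26.6, effective_area_m2=0.01, lever_arm_m=0.05)
        assert sl.iap_extensor_moment(10.0, cfg) == pytest.approx(5.0)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            sl.iap_extensor_moment(-1.0, IAPConfig())

    def test_passive_moment_opposes_rotation(self):
        m = sl.passive_joint_moment(np.array([10.0, 0, 0]), np.array([0.5, 0.5, 0.5]))
        assert m[0] == pytest.approx(-5.0)

    def test_passive_linearity(self):
        k = np.array([0.3, 0.2, 0.1])
        r = np.array([8.0, -4.0, 2.0])
        assert np.allclose(
            sl.passive_joint_moment(2 * r, k), 2 * sl.passive_joint_moment(r, k)
        )
        assert np.allclose(sl.passive_joint_moment(np.zeros(3), k), 0.0)
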