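import numpy as np
import pytest

from psitunnel.planning import (
    DEFAULT_SPECS,
    PRESETS,
    Ligament,
    PsiGuideParams,
    Tunnel,
    TunnelSpec,
    angles_from_direction,
    direction_from_angles,
    plan_knee,
)

from conftest import random_rigid


class TestDirectionFromAngles:
    def test_zero_angles_give_ml_axis(self, lateral_frame):
        d = direction_from_angles(lateral_frame, 0.0, 0.0)
        np.testing.assert_allclose(d, lateral_frame.ml_axis, atol=1e-12)

    def test_30_anterior_axial(self, medial_frame):
        # 30 deg anterior in the axial plane, flat in the coronal plane
        d = direction_from_angles(medial_frame, 30.0, 0.0)
        np.testing.assert_allclose(d, [0.8660, 0.5000, 0.0], atol=1e-4)

    def test_30_30_closed_form(self, medial_frame):
        # normalize(1, tan30, tan30) = (1, 0.57735, 0.57735)/sqrt(5/3)
        d = direction_from_angles(medial_frame, 30.0, 30.0)
        np.testing.assert_allclose(d, [0.7746, 0.4472, 0.4472], atol=1e-4)

    def test_out_of_range_angle_rejected(self, medial_frame):
        with pytest.raises(ValueError):
            direction_from_angles(medial_frame, 90.0, 0.0)


class TestAnglesFromDirection:
    def test_ml_axis_is_zero_zero(self, lateral_frame):
        assert angles_from_direction(lateral_frame, lateral_frame.ml_axis) == (0.0, 0.0)

    def test_closed_form_inverse(self, medial_frame):
        ax, co = angles_from_direction(medial_frame, [0.7746, 0.4472, 0.4472])
        assert ax == pytest.approx(30.0, abs=0.01)
        assert co == pytest.approx(30.0, abs=0.01)

    def test_direction_not_into_bone_rejected(self, lateral_frame):
        with pytest.raises(ValueError):
            angles_from_direction(lateral_frame, -lateral_frame.ml_axis)

    @pytest.mark.parametrize("convention", ["projection", "sequential"])
    def test_round_trip_over_angle_grid(self, medial_frame, convention):
        """angles -> direction -> angles is the identity on (-60, 60)^2."""
        for ax in np.arange(-57.5, 60.0, 7.5):
            for co in np.arange(-57.5, 60.0, 7.5):
                d = direction_from_angles(medial_frame, ax, co, convention)
                got = angles_from_direction(medial_frame, d, convention)
                np.testing.assert_allclose(got, (ax, co), atol=1e-9)

    def test_conventions_disagree_at_oblique_angles(self, medial_frame):
        # the two composition conventions coincide in either plane alone but
        # differ by a few degrees at 30/30
        d_proj = direction_from_angles(medial_frame, 30, 30, "projection")
        d_seq = direction_from_angles(medial_frame, 30, 30, "sequential")
        angle = np.degrees(np.arccos(np.clip(d_proj @ d_seq, -1, 1)))
        assert 1.0 < angle < 5.0
        np.testing.assert_allclose(
            direction_from_angles(medial_frame, 30, 0, "sequential"),
            direction_from_angles(medial_frame, 30, 0, "projection"),
            atol=1e-12,
        )


class TestPlanKnee:
    def test_default_plan_matches_prescriptions(self, femur):
        tunnels = plan_knee(femur)
        assert [t.ligament for t in tunnels] == list(Ligament)
        assert [t.diameter_mm for t in tunnels] == [8.0, 8.0, 7.0, 7.0]
        assert all(t.depth_mm == 25.0 for t in tunnels)
        for t in tunnels:
            np.testing.assert_allclose(t.entry, femur.footprints[t.ligament])

    def test_empty_spec_list_gives_empty_plan(self, femur):
        assert plan_knee(femur, specs=[]) == []

    def test_missing_footprint_names_ligament(self, femur):
        import copy

        model = copy.copy(femur)
        model.footprints = {
            k: v for k, v in femur.footprints.items() if k != Ligament.POL
        }
        with pytest.raises(KeyError, match="POL"):
            plan_knee(model)

    def test_angle_between_default_lateral_tunnels(self, femur):
        """LCL (30/0) vs PT (30/30) on the shared lateral frame.

        Closed form: dot = (1 + tan^2 30)/sqrt((1 + tan^2 30)(1 + 2 tan^2 30))
        = sqrt(4/5), i.e. 26.565 deg.
        """
        tunnels = {t.ligament: t for t in plan_knee(femur)}
        got = np.degrees(
            np.arccos(tunnels[Ligament.LCL].direction @ tunnels[Ligament.PT].direction)
        )
        expected = np.degrees(np.arccos(np.sqrt(4.0 / 5.0)))
        assert got == pytest.approx(expected, abs=0.1)

    def test_planned_angles_invariant_under_rigid_motion(self, simple_landmarks):
        from psitunnel.frames import build_frame

        rng = np.random.default_rng(3)
        frame = build_frame(simple_landmarks, "lateral", "right")
        for _ in range(10):
            T = random_rigid(rng)
            moved = frame.transformed(T.rotation, T.translation)
            d = direction_from_angles(frame, 30, 30)
            got = angles_from_direction(moved, T.rotation @ d)
            np.testing.assert_allclose(got, (30, 30), atol=1e-9)


def test_tunnel_validation_and_exit_point():
    t = Tunnel([0, 0, 0], [2, 0, 0], 8.0, 25.0, "LCL")
    assert np.linalg.norm(t.direction) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(t.exit_point, [25, 0, 0])
    with pytest.raises(ValueError):
        Tunnel([0, 0, 0], [0, 0, 0], 8.0, 25.0, "LCL")
    with pytest.raises(ValueError):
        TunnelSpec("LCL", 30.0, 0.0, -8.0, 25.0)


def test_guide_cannula_inner_diameter():
    assert PsiGuideParams().cannula_inner_diameter_mm == pytest.approx(3.1)


def test_presets_modify_lateral_angles_only():
    by_lig = {s.ligament: s for s in PRESETS["anterior-20-proximal-10"]}
    assert by_lig[Ligament.LCL].axial_angle_deg == 20.0
    assert by_lig[Ligament.LCL].coronal_angle_deg == 10.0
    assert by_lig[Ligament.MCL] == dict(zip([s.ligament for s in DEFAULT_SPECS], DEFAULT_SPECS))[Ligament.MCL]
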