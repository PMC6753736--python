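"""Reconstruction stack: resection, pose, axes, isocenter, scalars, field."""

import dataclasses

import numpy as np
import pytest

from linacqa import (
    MachineConstants,
    TestPlan,
    estimate_collimator_axis,
    estimate_gantry_angle,
    estimate_gantry_axis,
    estimate_isocenter,
    estimate_module_pose,
    estimate_sad,
    estimate_sdd,
    reconstruct_field,
    reconstruct_plan,
    resect_camera,
)
from linacqa import geometry as geo
from linacqa.errors import ReconstructionError
from linacqa.phantom import BallMarker, Mounting, PhantomModule
from linacqa.reconstruct import nominal_camera, nominal_module_pose
from linacqa.simulate import image_rng, nominal_state, simulate_image, simulate_plan

Y = np.array([0.0, 1.0, 0.0])


def exact_image(theta, psi, table, coll, machine, seed=0):
    return simulate_image(theta, psi, table, coll, machine, 0.0, image_rng(seed, 0, 0),
                          check_visibility=False)


class TestResection:
    @pytest.mark.parametrize("use_nominal_init", [True, False])
    @pytest.mark.parametrize("theta,psi", [(0.0, 0.0), (90.0, -120.0), (-165.0, 180.0)])
    def test_exact_recovery_at_zero_noise(self, table6, coll4, machine, theta, psi, use_nominal_init):
        rec = exact_image(theta, psi, table6, coll4, machine)
        init = nominal_camera(theta, psi, machine) if use_nominal_init else None
        cam = resect_camera(rec, table6, init=init)
        st = nominal_state(theta, psi, machine)
        np.testing.assert_allclose(cam.source, st.source, atol=1e-6)
        assert abs(abs(cam.view_dir @ st.beam_direction) - 1.0) < 1e-8
        assert cam.focal == pytest.approx(machine.sdd, abs=1e-6)
        assert cam.rms_residual < 1e-8

    def test_five_markers_under_determined(self, table6, coll4, machine):
        rec = exact_image(0.0, 0.0, table6, coll4, machine)
        short = dataclasses.replace(rec, table_uv=rec.table_uv[:5],
                                    table_ids=rec.table_ids[:5])
        five = PhantomModule(mounting=Mounting.TABLE,
                             markers=table6.markers[:5] + (table6.markers[5],))
        # mismatched observation count must also be refused
        with pytest.raises(ReconstructionError):
            resect_camera(short, five)

    def test_coplanar_markers_degenerate(self, coll4, machine):
        markers = tuple(
            BallMarker(id=i, center=[x, y, 0.0])
            for i, (x, y) in enumerate([(-3, -3), (3, -3), (3, 3), (-3, 3), (0, 2), (1, -2)])
        )
        flat = PhantomModule(mounting=Mounting.TABLE, markers=markers)
        rec = exact_image(0.0, 0.0, flat, coll4, machine)
        with pytest.raises(ReconstructionError):
            resect_camera(rec, flat)

    def test_residual_tracks_noise_level(self, table6, coll4, machine):
        # 12 observations, 7 fitted parameters: E[sum r^2] = (12 - 7) sigma^2,
        # so the expected RMS over 12 coordinates is sigma * sqrt(5/12)
        sigma_mm = 0.2
        sigma_cm = 0.02
        rms = []
        for i in range(200):
            rec = simulate_image(0.0, 0.0, table6, coll4, machine, sigma_mm,
                                 image_rng(42, i, 0), check_visibility=False)
            cam = resect_camera(rec, table6, init=nominal_camera(0.0, 0.0, machine))
            rms.append(cam.rms_residual)
        expected = sigma_cm * np.sqrt(5.0 / 12.0)
        assert np.mean(rms) == pytest.approx(expected, rel=0.15)


class TestModulePose:
    def test_exact_recovery_at_zero_noise(self, table6, coll4, machine):
        theta, psi = 45.0, 60.0
        rec = exact_image(theta, psi, table6, coll4, machine)
        cam = resect_camera(rec, table6, init=nominal_camera(theta, psi, machine))
        pose = estimate_module_pose(rec, cam, coll4)
        truth_R, truth_t = nominal_module_pose(theta, psi, coll4)
        np.testing.assert_allclose(
            pose.apply(coll4.local_centers()),
            coll4.local_centers() @ truth_R.T + truth_t,
            atol=1e-6,
        )
        assert pose.rms_residual < 1e-8

    def test_posit_initialization_path(self, table6, coll4, machine):
        rec = exact_image(20.0, -45.0, table6, coll4, machine)
        cam = resect_camera(rec, table6, init=nominal_camera(20.0, -45.0, machine))
        pose = estimate_module_pose(rec, cam, coll4, init=None)
        truth_R, truth_t = nominal_module_pose(20.0, -45.0, coll4)
        np.testing.assert_allclose(
            pose.apply(coll4.local_centers()),
            coll4.local_centers() @ truth_R.T + truth_t,
            atol=1e-5,
        )

    def test_three_markers_ambiguous(self, table6, coll4, machine):
        rec = exact_image(0.0, 0.0, table6, coll4, machine)
        short = dataclasses.replace(rec, coll_uv=rec.coll_uv[:3], coll_ids=rec.coll_ids[:3])
        cam = resect_camera(rec, table6, init=nominal_camera(0.0, 0.0, machine))
        with pytest.raises(ReconstructionError):
            estimate_module_pose(short, cam, coll4)

    def test_objective_dominates_truth_pose(self, table6, coll4, machine):
        # the fitted pose must reproject at least as well as the truth pose
        theta, psi = 0.0, 0.0
        rec = simulate_image(theta, psi, table6, coll4, machine, 0.3, image_rng(5, 0, 0),
                             check_visibility=False)
        cam = nominal_camera(theta, psi, machine)  # exact camera
        pose = estimate_module_pose(rec, cam, coll4)
        truth_R, truth_t = nominal_module_pose(theta, psi, coll4)
        obs = rec.coll_uv
        fit_res = np.linalg.norm(cam.project(pose.apply(coll4.local_centers())) - obs)
        truth_res = np.linalg.norm(
            cam.project(coll4.local_centers() @ truth_R.T + truth_t) - obs
        )
        assert fit_res <= truth_res + 1e-12


class TestAxesAndIsocenter:
    def _marker_sets(self, psi, thetas, table, coll, machine):
        sets = []
        for th in thetas:
            rec = exact_image(th, psi, table, coll, machine)
            cam = resect_camera(rec, table, init=nominal_camera(th, psi, machine))
            pose = estimate_module_pose(rec, cam, coll)
            sets.append(pose.apply(coll.local_centers()))
        return sets

    def test_collimator_axis_exact(self, table6, coll4, machine):
        psi = 30.0
        st = nominal_state(0.0, psi, machine)
        sets = self._marker_sets(psi, [-165.0, -90.0, 0.0, 90.0, 165.0], table6, coll4, machine)
        axis = estimate_collimator_axis(sets, st.source - np.zeros(3))
        assert abs(abs(axis.direction @ st.beam_direction) - 1.0) < 1e-7
        assert geo.point_line_distance(st.source, axis) < 1e-6

    def test_single_collimator_angle_rejected(self, table6, coll4, machine):
        sets = self._marker_sets(10.0, [0.0], table6, coll4, machine)
        with pytest.raises(ReconstructionError):
            estimate_collimator_axis(sets, np.array([0.0, 0.0, 1.0]))

    def test_isocenter_exact(self, table6, coll4, machine):
        axes = []
        for psi in (-90.0, 0.0, 90.0):
            st = nominal_state(0.0, psi, machine)
            axes.append(geo.Line3(st.source, st.beam_direction))
        np.testing.assert_allclose(estimate_isocenter(axes), np.zeros(3), atol=1e-10)

    def test_isocenter_parallel_axes_degenerate(self):
        axes = [geo.Line3([0, 0, 0], [0, 0, 1]), geo.Line3([1, 0, 0], [0, 0, 1])]
        with pytest.raises(Exception):
            estimate_isocenter(axes)

    def test_gantry_axis_recovers_skew_axis(self, rng):
        # collections constructed by exact rotation about a known skew axis
        axis_dir = geo.unit([0.2, 1.0, -0.15])
        pts = rng.normal(scale=5, size=(12, 3))
        colls = [
            pts @ geo.rotation_matrix(axis_dir, ang).T
            for ang in (0.0, 40.0, 80.0, 120.0)
        ]
        est = estimate_gantry_axis(colls)
        np.testing.assert_allclose(est, axis_dir, atol=1e-8)

    def test_gantry_axis_single_angle_rejected(self, rng):
        with pytest.raises(ReconstructionError):
            estimate_gantry_axis([rng.normal(size=(5, 3))])

    @pytest.mark.parametrize("psi,expected", [(0.0, 0.0), (90.0, 90.0), (-90.0, -90.0)])
    def test_gantry_angle_from_axis(self, machine, psi, expected):
        st = nominal_state(0.0, psi, machine)
        axis = geo.Line3(st.source, st.beam_direction)
        unsigned, signed = estimate_gantry_angle(axis, st.source)
        assert unsigned == pytest.approx(abs(expected), abs=1e-10)
        assert signed == pytest.approx(expected, abs=1e-10)


class TestScalars:
    def test_sad_nominal(self, machine):
        st = nominal_state(0.0, 35.0, machine)
        axis = geo.Line3(st.source, st.beam_direction)
        assert estimate_sad(st.source, axis, np.zeros(3)) == pytest.approx(100.0, abs=1e-10)

    def test_sad_axial_displacement(self, machine):
        st = nominal_state(0.0, 0.0, machine)
        axis = geo.Line3(st.source, st.beam_direction)
        moved = st.source + 5.0 * np.array([0, 0, 1.0])
        assert estimate_sad(moved, axis, np.zeros(3)) == pytest.approx(105.0, abs=1e-10)

    def test_sad_two_step_construction_oracle(self, rng):
        for _ in range(10):
            src = rng.normal(scale=50, size=3)
            iso = rng.normal(scale=2, size=3)
            d = geo.unit(rng.normal(size=3))
            axis = geo.Line3(src, d)
            plane = geo.Plane3(iso, d)
            foot = geo.line_plane_intersection(geo.Line3(src, d), plane)
            assert estimate_sad(src, axis, iso) == pytest.approx(
                np.linalg.norm(src - foot), abs=1e-10
            )

    def test_sdd_matches_plane_distance_oracle(self, rng):
        for _ in range(10):
            src = rng.normal(scale=30, size=3)
            plane = geo.Plane3(rng.normal(scale=10, size=3), geo.unit(rng.normal(size=3)))
            hit = geo.line_plane_intersection(geo.Line3(src, plane.normal), plane)
            assert estimate_sdd(src, plane) == pytest.approx(np.linalg.norm(src - hit), abs=1e-12)

    def test_sdd_big_phantom_configuration(self, table6, coll4):
        machine = MachineConstants(sdd=140.0)
        rec = exact_image(0.0, 70.0, table6, coll4, machine)
        cam = resect_camera(rec, table6, init=nominal_camera(0.0, 70.0, machine))
        assert estimate_sdd(cam.source, cam.detector.plane) == pytest.approx(140.0, abs=1e-6)


class TestFieldReconstruction:
    def test_exact_square_recovered(self, table6, coll4, machine):
        theta, psi = 25.0, -40.0
        rec = exact_image(theta, psi, table6, coll4, machine)
        cam = resect_camera(rec, table6, init=nominal_camera(theta, psi, machine))
        st = nominal_state(theta, psi, machine)
        axis = geo.Line3(st.source, st.beam_direction)
        fr = reconstruct_field(rec.corner_uv, cam, axis, np.zeros(3), st.field_corners)
        np.testing.assert_allclose(fr.edge_lengths, 20.0, atol=1e-8)
        np.testing.assert_allclose(fr.corner_angles, 90.0, atol=1e-8)
        np.testing.assert_allclose(fr.corner_deviations, 0.0, atol=1e-8)

    def test_rotation_invariance_of_edges_and_angles(self, table6, coll4, machine):
        psi = 10.0
        results = []
        for theta in (0.0, 77.0):
            rec = exact_image(theta, psi, table6, coll4, machine)
            cam = resect_camera(rec, table6, init=nominal_camera(theta, psi, machine))
            st = nominal_state(theta, psi, machine)
            axis = geo.Line3(st.source, st.beam_direction)
            results.append(reconstruct_field(rec.corner_uv, cam, axis, np.zeros(3)))
        np.testing.assert_allclose(results[0].edge_lengths, results[1].edge_lengths, atol=1e-8)
        np.testing.assert_allclose(results[0].corner_angles, results[1].corner_angles, atol=1e-8)

    def test_ray_parallel_to_plane_degenerate(self, table6, coll4, machine):
        rec = exact_image(0.0, 0.0, table6, coll4, machine)
        cam = resect_camera(rec, table6, init=nominal_camera(0.0, 0.0, machine))
        sideways = geo.Line3(np.zeros(3), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(Exception):
            reconstruct_field(rec.corner_uv, cam, sideways, np.zeros(3))


class TestFullChain:
    # note: 3 evenly spaced gantry angles would be (-180, 0, 180) - physically
    # two coincident beam axes - so the smallest meaningful grid count is 4
    @pytest.mark.parametrize("n_gantry,n_coll", [(5, 5), (4, 9)])
    def test_zero_noise_end_to_end(self, table6, coll4, machine, n_gantry, n_coll):
        plan = TestPlan.grid(n_gantry, n_coll, 0.0, machine)
        records = simulate_plan(plan, table6, coll4, seed=0, check_visibility=False)
        g = reconstruct_plan(records, table6, coll4, machine=machine)
        np.testing.assert_allclose(g.isocenter, 0.0, atol=1e-6)
        np.testing.assert_allclose(g.gantry_axis, Y, atol=1e-6)
        np.testing.assert_allclose(
            geo.wrap_angle_deg(np.array(g.vertical_angles_signed) - np.array(g.gantry_angles)),
            0.0, atol=1e-6,
        )
        np.testing.assert_allclose(g.image_sad, 100.0, atol=1e-6)
        np.testing.assert_allclose(g.image_sdd, 180.0, atol=1e-6)

    def test_single_gantry_angle_rejected(self, table6, coll4, machine):
        plan = TestPlan.grid(1, 5, 0.0, machine)
        records = simulate_plan(plan, table6, coll4, seed=0, check_visibility=False)
        with pytest.raises(ReconstructionError):
            reconstruct_plan(records, table6, coll4, machine=machine)

    def test_diagnostics_rows_per_image(self, table6, coll4, machine):
        plan = TestPlan.grid(4, 3, 0.1, machine)
        records = simulate_plan(plan, table6, coll4, seed=2, check_visibility=False)
        g = reconstruct_plan(records, table6, coll4, machine=machine)
        rows = g.diagnostics()
        assert len(rows) == 12
        assert all(r["camera_rms_cm"] >= 0 and r["pose_rms_cm"] >= 0 for r in rows)

    def test_truth_blocks_never_read(self, table6, coll4, machine):
        # corrupting (or dropping) every truth block must not change anything
        plan = TestPlan.grid(4, 3, 0.2, machine)
        records = simulate_plan(plan, table6, coll4, seed=13, check_visibility=False)
        stripped = [dataclasses.replace(r, truth=None) for r in records]
        a = reconstruct_plan(records, table6, coll4, machine=machine)
        b = reconstruct_plan(stripped, table6, coll4, machine=machine)
        np.testing.assert_array_equal(a.isocenter, b.isocenter)
        np.testing.assert_array_equal(a.image_sad, b.image_sad)
        np.testing.assert_array_equal(a.gantry_axis, b.gantry_axis)
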