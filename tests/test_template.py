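import numpy as np
import pytest
import trimesh

from orbifab import phantom, template
from orbifab.surface import repair_mesh
from orbifab.template import (
    ClosedCurve,
    RigidTransform,
    best_fit_align,
    build_template,
    mirror_mesh,
    offset_boundary,
    trace_defect_boundary,
)


def rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


def asymmetric_cap():
    cap = phantom.make_test_mesh("cap", size_mm=10, resolution=3)
    cap.apply_scale([1.0, 0.7, 1.0])
    return cap


class TestRigidTransform:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2, np.zeros(3))
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1, 1, -1]), np.zeros(3))

    def test_compose_and_inverse(self):
        t1 = RigidTransform(rot_z(30), np.array([1.0, 2.0, 3.0]))
        t2 = RigidTransform(rot_z(-10), np.array([0.5, 0, 0]))
        p = np.random.default_rng(0).normal(size=(20, 3))
        np.testing.assert_allclose(t1.compose(t2).apply(p), t1.apply(t2.apply(p)), atol=1e-12)
        np.testing.assert_allclose(t1.inverse().apply(t1.apply(p)), p, atol=1e-12)


class TestMirror:
    def test_involution(self):
        cap = phantom.make_test_mesh("cap", size_mm=8, resolution=2)
        twice = mirror_mesh(mirror_mesh(cap, (0, 0, 0), (1, 0, 0)), (0, 0, 0), (1, 0, 0))
        np.testing.assert_allclose(
            np.asarray(twice.vertices), np.asarray(cap.vertices), atol=1e-12
        )

    def test_symmetric_sphere_same_vertex_set(self):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=5)
        mirrored = mirror_mesh(sph, (0, 0, 0), (1, 0, 0))
        a = set(map(tuple, np.round(np.asarray(sph.vertices), 9)))
        b = set(map(tuple, np.round(np.asarray(mirrored.vertices), 9)))
        assert a == b

    def test_signed_volume_preserved_after_winding_fix(self):
        cap = phantom.make_test_mesh("cap", size_mm=10, resolution=3)
        mirrored = mirror_mesh(cap, (1.0, 0, 0), (1, 0, 0))
        # divergence-theorem volume keeps magnitude and sign
        assert mirrored.volume == pytest.approx(cap.volume, rel=1e-9)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            mirror_mesh(trimesh.creation.box(), (0, 0, 0), (2, 0, 0))


class TestBestFitAlign:
    def test_identity_alignment(self):
        cap = asymmetric_cap()
        res = best_fit_align(cap, cap, seed=1)
        assert res.rms_mm < 1e-4
        assert res.converged

    def test_recovers_known_transform(self):
        cap = asymmetric_cap()
        gt = RigidTransform(rot_z(5), np.array([0.3, 0, 0]))
        src = cap.copy()
        M = np.eye(4)
        M[:3, :3] = gt.rotation
        M[:3, 3] = gt.translation_mm
        src.apply_transform(M)
        res = best_fit_align(src, cap, tol_mm=1e-4, seed=1)
        pts = np.asarray(src.vertices)
        rms_gt = np.sqrt(
            np.mean(np.sum((res.transform.apply(pts) - gt.inverse().apply(pts)) ** 2, axis=1))
        )
        assert rms_gt < 0.01

    def test_partial_overlap_recovery(self):
        cap = asymmetric_cap()
        gt = RigidTransform(rot_z(5), np.array([0.3, 0, 0]))
        src = cap.copy()
        M = np.eye(4)
        M[:3, :3] = gt.rotation
        M[:3, 3] = gt.translation_mm
        src.apply_transform(M)
        mask = src.triangles.mean(axis=1)[:, 0] > 0  # ~60% of the surface
        part = trimesh.Trimesh(vertices=src.vertices, faces=src.faces[mask], process=False)
        part.remove_unreferenced_vertices()
        res = best_fit_align(part, cap, tol_mm=1e-4, seed=1)
        pts = np.asarray(part.vertices)
        rms_gt = np.sqrt(
            np.mean(np.sum((res.transform.apply(pts) - gt.inverse().apply(pts)) ** 2, axis=1))
        )
        assert rms_gt < 0.01

    def test_rms_monotone_nonincreasing(self):
        cap = asymmetric_cap()
        src = cap.copy()
        src.apply_translation((0.5, 0.2, 0))
        res = best_fit_align(src, cap, tol_mm=1e-5, seed=0)
        assert all(b <= a + 1e-12 for a, b in zip(res.rms_history, res.rms_history[1:]))

    def test_max_iter_exhaustion_still_returns(self):
        cap = asymmetric_cap()
        src = cap.copy()
        src.apply_translation((2.0, 1.0, 0.5))
        res = best_fit_align(src, cap, tol_mm=1e-12, max_iter=2, seed=0)
        assert not res.converged
        assert res.transform is not None

    def test_collinear_samples_rejected(self):
        line = trimesh.Trimesh(
            vertices=np.column_stack([np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)]),
            faces=np.zeros((0, 3), dtype=int),
            process=False,
        )
        with pytest.raises(ValueError, match="collinear|degenerate"):
            best_fit_align(line, asymmetric_cap())


class TestTraceBoundary:
    def test_phantom_defect_loop_length(self, cap_pair):
        intact, damaged, spec = cap_pair
        curve = trace_defect_boundary(damaged, intact, deviation_threshold_mm=0.3)
        r_mid = spec.shell_radius_mm - spec.shell_thickness_mm / 2
        circumference = 2 * np.pi * r_mid * np.sin(np.radians(spec.defect_angle_deg / 2))
        assert curve.n_regions == 1
        assert curve.length() == pytest.approx(circumference, rel=0.10)

    def test_identical_meshes_no_defect(self, cap_pair):
        intact, _, _ = cap_pair
        with pytest.raises(ValueError, match="no defect"):
            trace_defect_boundary(intact, intact, deviation_threshold_mm=0.3)

    def test_two_disjoint_defects_largest_selected(self, cap_pair):
        intact, _, spec = cap_pair
        import trimesh as tm

        from orbifab.phantom import _shell_center

        center = _shell_center(spec)
        d = intact.triangles.mean(axis=1) - center
        dn = d / np.linalg.norm(d, axis=1, keepdims=True)
        t = np.radians(30.0)
        dir1 = np.array([np.sin(t), 0, np.cos(t)])
        dir2 = np.array([-np.sin(t), 0, np.cos(t)])
        ang1 = np.degrees(np.arccos(np.clip(dn @ dir1, -1, 1)))
        ang2 = np.degrees(np.arccos(np.clip(dn @ dir2, -1, 1)))
        keep = (ang1 > 20) & (ang2 > 10)  # big hole at dir1, small at dir2
        damaged2 = tm.Trimesh(vertices=intact.vertices, faces=intact.faces[keep], process=False)
        damaged2.remove_unreferenced_vertices()
        curve = trace_defect_boundary(damaged2, intact, deviation_threshold_mm=0.3)
        assert curve.n_regions == 2
        # largest (the dir1 hole) selected: its centre is on the +x side
        assert curve.points[:, 0].mean() > center[0]


class TestOffsetBoundary:
    def circle(self, r=5.0, n=64):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return ClosedCurve(np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)]))

    def test_circle_offsets_have_expected_lengths(self):
        inner, outer = offset_boundary(self.circle(), 0.5)
        assert inner.length() == pytest.approx(2 * np.pi * 4.5, rel=0.01)
        assert outer.length() == pytest.approx(2 * np.pi * 5.5, rel=0.01)

    def test_zero_offset_identity(self):
        c = self.circle()
        inner, outer = offset_boundary(c, 0.0)
        np.testing.assert_allclose(inner.points, c.points)
        np.testing.assert_allclose(outer.points, c.points)

    def test_collapsing_offset_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            offset_boundary(self.circle(r=0.4), 0.5)


class TestBuildTemplate:
    def test_plate_hole_filled_planar_with_correct_area(self, plate_with_hole):
        plate, th = plate_with_hole
        curve = ClosedCurve(
            np.column_stack([4 * np.cos(th), 4 * np.sin(th), np.zeros(len(th))])
        )
        filled = build_template(plate, curve, extension_mm=2.0, mode="whole")
        assert filled.area - plate.area == pytest.approx(np.pi * 16, rel=0.01)
        assert np.abs(np.asarray(filled.vertices)[:, 2]).max() < 1e-9

    def test_cut_mode_differs_only_in_band(self, cap_pair):
        intact, damaged, _ = cap_pair
        curve = trace_defect_boundary(damaged, intact, deviation_threshold_mm=0.3)
        whole = build_template(damaged, curve, mode="whole", boundary_tol_mm=0.75)
        cut = build_template(damaged, curve, mode="cut", boundary_tol_mm=0.75)
        assert len(cut.vertices) != len(whole.vertices)
        # the shared reference part of the geometry is untouched
        n_ref = len(damaged.vertices)
        np.testing.assert_allclose(
            np.asarray(cut.vertices)[:n_ref], np.asarray(whole.vertices)[:n_ref]
        )

    def test_extension_zero_patch_meets_rim_exactly(self, plate_with_hole):
        plate, th = plate_with_hole
        curve = ClosedCurve(
            np.column_stack([4 * np.cos(th), 4 * np.sin(th), np.zeros(len(th))])
        )
        filled = build_template(plate, curve, extension_mm=0.0, mode="whole")
        from orbifab.template import _boundary_loops

        # the circular rim is gone: only the outer plate boundary remains open
        assert len(_boundary_loops(filled)) == len(_boundary_loops(plate)) - 1

    def test_template_passes_repair_with_zero_defects(self, cap_pair):
        intact, damaged, _ = cap_pair
        curve = trace_defect_boundary(damaged, intact, deviation_threshold_mm=0.3)
        tmpl = build_template(damaged, curve, mode="whole", boundary_tol_mm=0.75)
        _, rep = repair_mesh(tmpl)
        assert rep.clean

    def test_full_chain_recovery_within_tenth_mm(self, cap_pair):
        """Patch rebuilt from the surroundings deviates < 0.1 mm from the
        intact ground truth inside the defect zone."""
        from orbifab import metrology

        intact, damaged, _ = cap_pair
        curve = trace_defect_boundary(damaged, intact, deviation_threshold_mm=0.3)
        tmpl = build_template(damaged, curve, mode="whole", boundary_tol_mm=0.75)
        dev = metrology.deviation_map(np.asarray(tmpl.vertices), intact, tol=0.2)
        patch = dev.deviations_mm[len(damaged.vertices):]
        assert len(patch) > 50
        assert np.abs(patch).mean() < 0.1

    def test_distant_boundary_rejected(self, plate_with_hole):
        plate, th = plate_with_hole
        far = ClosedCurve(
            np.column_stack([4 * np.cos(th), 4 * np.sin(th), np.full(len(th), 5.0)])
        )
        with pytest.raises(ValueError, match="boundary"):
            build_template(plate, far, mode="whole")
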