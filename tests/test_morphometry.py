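import numpy as np
import pytest
from scipy import optimize

import tmjmorph as tm
from tmjmorph.meshdist import closest_on_mesh, closest_on_mesh_brute, point_triangle_closest
from tmjmorph.morphometry import GradingLabels, JointModels
from conftest import two_cube_masks


class TestDice:
    def test_identical_masks_give_one(self, clean_phantom):
        condyle = clean_phantom["condyle"]
        res = tm.dice_similarity(condyle, condyle)
        assert res.dsi == 1.0
        assert res.volume_intersection == res.volume_t1 == res.volume_t2

    def test_disjoint_masks_give_zero(self):
        m1, m2 = two_cube_masks(overlap_slabs=0)
        assert tm.dice_similarity(m1, m2).dsi == 0.0

    def test_half_overlap_cubes_give_exactly_half(self):
        m1, m2 = two_cube_masks(overlap_slabs=5)
        res = tm.dice_similarity(m1, m2)
        assert res.dsi == 0.5  # 2*500 / (1000 + 1000), exact
        assert res.volume_intersection == 500.0

    def test_symmetry(self, clean_phantom):
        condyle, disc = clean_phantom["condyle"], clean_phantom["disc"]
        moved = tm.displace_phantom(condyle, tm.RigidTransform(translation=np.array([2.0, 1.0, 0.0])))
        assert tm.dice_similarity(condyle, moved).dsi == tm.dice_similarity(moved, condyle).dsi

    def test_errors(self, clean_phantom):
        condyle = clean_phantom["condyle"]
        other = tm.MaskVolume(np.zeros((4, 4, 4), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            tm.dice_similarity(condyle, other)
        empty = tm.MaskVolume(np.zeros((4, 4, 4), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            tm.dice_similarity(empty, empty)


class TestPointTriangleDistance:
    def test_against_constrained_optimizer(self):
        """Closest point on triangle vs an independent SLSQP barycentric solve."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            tri = rng.uniform(-5, 5, (3, 3))
            p = rng.uniform(-8, 8, 3)
            ours = point_triangle_closest(p[None], tri[None])[0]
            d_ours = np.linalg.norm(p - ours)

            def objective(w):
                q = w @ tri
                return np.sum((p - q) ** 2)

            res = optimize.minimize(
                objective, np.full(3, 1 / 3), method="SLSQP",
                bounds=[(0, 1)] * 3,
                constraints={"type": "eq", "fun": lambda w: w.sum() - 1},
                options={"ftol": 1e-14, "maxiter": 200},
            )
            assert d_ours == pytest.approx(np.sqrt(res.fun), abs=1e-6)


class TestHausdorffRmsd:
    def test_self_distance_zero(self, small_sphere_mesh):
        res = tm.hausdorff_rmsd(small_sphere_mesh, small_sphere_mesh)
        assert res.rmsd == 0.0 and res.hausdorff_max == 0.0

    def test_parallel_planes_distance(self):
        """Two parallel planar patches d apart measure rmsd = d away from edges."""
        n = 11
        xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        verts0 = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        plane0 = tm.SurfaceMesh(verts0, np.array(faces))
        d = 2.5
        plane1 = tm.SurfaceMesh(verts0 + [0, 0, d], np.array(faces))
        res = tm.hausdorff_rmsd(plane0, plane1)
        assert res.rmsd == pytest.approx(d, abs=1e-9)
        assert res.hausdorff_max == pytest.approx(d, abs=1e-9)

    def test_rmsd_le_hausdorff_and_symmetric(self, small_sphere_mesh):
        moved = small_sphere_mesh.transformed(
            tm.RigidTransform(translation=np.array([1.0, -2.0, 0.5])))
        a = tm.hausdorff_rmsd(small_sphere_mesh, moved)
        b = tm.hausdorff_rmsd(moved, small_sphere_mesh)
        assert a.rmsd <= a.hausdorff_max
        assert a.rmsd == pytest.approx(b.rmsd, abs=1e-12)
        assert a.hausdorff_max == pytest.approx(b.hausdorff_max, abs=1e-12)

    def test_translated_sphere_rmsd_is_fraction_of_shift(self):
        """Nearest-point RMSD of a translated sphere is ~d/sqrt(3), not d:
        side points contribute |t.n| ~ 0.  The translation magnitude itself
        is recovered by the Hausdorff maximum."""
        sphere = tm.mask_to_mesh(tm.ball_mask(10.0, spacing=0.5))
        d = 2.0
        moved = sphere.transformed(tm.RigidTransform(translation=np.array([0, 0, d])))
        res = tm.hausdorff_rmsd(sphere, moved)
        assert res.hausdorff_max == pytest.approx(d, rel=0.05)
        assert res.rmsd == pytest.approx(d / np.sqrt(3), rel=0.10)

    def test_empty_mesh_rejected(self, small_sphere_mesh):
        empty = tm.SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="empty"):
            tm.hausdorff_rmsd(small_sphere_mesh, empty)


class TestDistanceMap:
    def test_source_equals_target_gives_zeros(self, small_sphere_mesh):
        rel = tm.distance_map(small_sphere_mesh, small_sphere_mesh)
        assert rel.mxd == 0.0
        assert np.all(rel.signed_distances == 0.0)

    def test_concentric_spheres(self):
        outer = tm.mask_to_mesh(tm.ball_mask(10.0, spacing=0.25))
        inner = tm.mask_to_mesh(tm.ball_mask(8.0, spacing=0.25))
        rel = tm.distance_map(inner, outer)
        assert rel.mxd == pytest.approx(2.0, abs=0.05)
        assert np.all(rel.signed_distances < 0)  # inner lies inside the outer surface
        rel_out = tm.distance_map(outer, inner)
        assert np.all(rel_out.signed_distances > 0)
        assert rel_out.mxd == pytest.approx(2.0, abs=0.05)

    def test_signed_channel_attached_for_export(self, small_sphere_mesh, tmp_path):
        moved = small_sphere_mesh.transformed(
            tm.RigidTransform(translation=np.array([0.0, 0.0, 1.0])))
        rel = tm.distance_map(small_sphere_mesh, moved)
        assert rel.colored_mesh.vertex_scalars is not None
        assert rel.color_range[0] == pytest.approx(rel.signed_distances.max())
        tm.write_scalar_mesh(rel.colored_mesh, tmp_path / "map.ply")
        back = tm.read_scalar_mesh(tmp_path / "map.ply")
        assert np.allclose(back.vertex_scalars, rel.signed_distances, atol=1e-5)


class TestOracleEquivalence:
    """KD-pruned distances must equal all-pairs brute force exactly."""

    def test_pruned_equals_brute_force(self, clean_phantom, small_sphere_mesh):
        disc_mesh = tm.mask_to_mesh(tm.ball_mask(4.0, spacing=1.0))
        for source, target in [
            (small_sphere_mesh, disc_mesh),
            (disc_mesh, small_sphere_mesh),
        ]:
            assert len(source) <= 500
            d_fast, p_fast, _ = closest_on_mesh(source.vertices, target)
            d_brute, _, _ = closest_on_mesh_brute(source.vertices, target)
            assert np.allclose(d_fast, d_brute, atol=1e-6)
            # the returned point realizes the minimal distance (ties may pick
            # a different but equidistant triangle)
            realized = np.linalg.norm(source.vertices - p_fast, axis=1)
            assert np.allclose(realized, d_brute, atol=1e-6)


class TestShapeVsDisplacement:
    def test_high_overlap_with_large_distance_tail(self):
        """High DSI can coexist with a large Hausdorff distance: a thin spur
        on an otherwise identical body leaves overlap nearly perfect while the
        maximum surface distance is huge (shape change, not displacement)."""
        base = np.zeros((72, 34, 34), dtype=np.uint8)
        base[2:32, 2:32, 2:32] = 1
        spur = base.copy()
        spur[32:68, 14:18, 14:18] = 1  # 36 mm long, 4x4 spur
        m1 = tm.MaskVolume(base, spacing=(1, 1, 1))
        m2 = tm.MaskVolume(spur, spacing=(1, 1, 1))
        dsi = tm.dice_similarity(m1, m2).dsi
        res = tm.hausdorff_rmsd(tm.mask_to_mesh(m1), tm.mask_to_mesh(m2))
        assert dsi > 0.98
        assert res.hausdorff_max > 30.0
        assert res.rmsd < 0.2 * res.hausdorff_max  # summary hides the tail


class TestJointChangeReport:
    def test_identity_displacement(self, clean_phantom):
        t1 = JointModels(condyle_mask=clean_phantom["condyle"], disc_mask=clean_phantom["disc"])
        t2 = JointModels(condyle_mask=clean_phantom["condyle"], disc_mask=clean_phantom["disc"])
        rec = tm.joint_change_report(t1, t2, joint_id=1)
        assert rec.condyle_dsi == pytest.approx(1.0, abs=0.02)
        assert rec.disc_dsi == pytest.approx(1.0, abs=0.02)
        assert rec.condyle_rmsd <= 0.5  # <= grid spacing
        assert rec.mxd_t1 == pytest.approx(rec.mxd_t2, abs=1e-9)

    def test_disc_translation_with_fixed_condyle(self, clean_phantom):
        shift = tm.RigidTransform(translation=np.array([4.0, 0.0, 0.0]))
        disc_t2 = tm.displace_phantom(clean_phantom["disc"], shift)
        t1 = JointModels(condyle_mask=clean_phantom["condyle"], disc_mask=clean_phantom["disc"])
        t2 = JointModels(condyle_mask=clean_phantom["condyle"], disc_mask=disc_t2)
        rec = tm.joint_change_report(t1, t2, joint_id=2)
        assert rec.disc_dsi < rec.condyle_dsi
        assert rec.condyle_dsi == pytest.approx(1.0, abs=0.02)

    def test_missing_disc_yields_missing_fields(self, clean_phantom):
        t1 = JointModels(condyle_mask=clean_phantom["condyle"], disc_mask=clean_phantom["disc"])
        t2 = JointModels(condyle_mask=clean_phantom["condyle"], disc_mask=None)
        rec = tm.joint_change_report(t1, t2, joint_id=3)
        assert rec.disc_dsi is None and rec.disc_rmsd is None and rec.mxd_t2 is None
        assert rec.condyle_dsi is not None and rec.mxd_t1 is not None


def test_grading_labels_vocabulary():
    GradingLabels(disc_position="moderate", osseous="DJD")
    with pytest.raises(ValueError):
        GradingLabels(disc_position="extreme", osseous="normal")
    with pytest.raises(ValueError):
        GradingLabels(disc_position="normal", osseous="erosion")
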