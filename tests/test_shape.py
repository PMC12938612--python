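"""Mesh pipeline: mirroring, meshing, ICP, correspondence, octants, BSDM."""

from dataclasses import replace

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from hipshape import (FemurPhantomSpec, LabelVolume, SurfaceMesh,
                      align_to_atlas, apply_shaft_cutoff, bsdm_summary,
                      compare_pair, correspond, estimate_axes, extract_mesh,
                      fit_head_sphere, icp_register, make_asymmetric_pair,
                      make_femur_volume, mirror_right, partition_head,
                      vertex_distance)
from hipshape.shape import (AxisSet, DistanceMap, RigidTransform,
                            _laplacian_smooth, barycentric_coordinates,
                            cohort_shaft_cutoff, measure_shaft_length)
from hipshape.synthetic import OCTANTS


def random_rigid(rng, max_deg=30.0, max_t=20.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(
        np.deg2rad(rng.uniform(0, max_deg)) * axis).as_matrix()
    return RigidTransform(rot, rng.uniform(-max_t, max_t, 3))


class TestMirror:
    def test_involution(self, left_volume):
        assert np.array_equal(mirror_right(mirror_right(left_volume)).grid,
                              left_volume.grid)
        assert mirror_right(mirror_right(left_volume)).axes == left_volume.axes

    def test_mirror_pair_matches_left(self, femur_spec, left_volume):
        right = make_femur_volume(femur_spec, "right")
        assert np.array_equal(mirror_right(right).grid, left_volume.grid)

    def test_index_mapping_along_lr_axis(self):
        grid = np.zeros((6, 4, 4), dtype=np.uint8)
        grid[1, 2, 3] = 1
        v = LabelVolume(grid, (1, 1, 1))
        m = mirror_right(v)
        assert m.grid[6 - 1 - 1, 2, 3] == 1
        assert m.grid.sum() == 1
        assert m.axes == "LAS"


class TestExtractMesh:
    def test_zero_iterations_keeps_raw_isosurface(self, sphere_volume):
        raw = extract_mesh(sphere_volume, smoothing_iters=0)
        again = extract_mesh(sphere_volume, smoothing_iters=0)
        assert np.array_equal(raw.vertices, again.vertices)

    def test_sphere_radius_before_and_after_smoothing(self, sphere_volume):
        for iters in (0, 10):
            mesh = extract_mesh(sphere_volume, smoothing_iters=iters)
            radii = np.linalg.norm(mesh.vertices - mesh.vertices.mean(0),
                                   axis=1)
            assert abs(radii.mean() - 22.0) < 0.8  # within one voxel

    def test_smoothing_shrinks_area_monotonically(self, sphere_volume):
        mesh = extract_mesh(sphere_volume, smoothing_iters=0)
        areas = []
        v = mesh.vertices
        for _ in range(6):
            areas.append(trimesh.Trimesh(v, mesh.faces, process=False).area)
            v = _laplacian_smooth(v, mesh.faces, 1, 0.5)
        assert all(a1 > a2 for a1, a2 in zip(areas, areas[1:]))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_mesh(LabelVolume(np.zeros((4, 4, 4)), (1, 1, 1)))


class TestICP:
    def test_self_registration_is_identity(self, sphere_mesh):
        t = icp_register(sphere_mesh, sphere_mesh)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(t.translation, 0, atol=1e-6)

    def test_known_transform_recovery(self, left_mesh):
        rng = np.random.default_rng(0)
        true = random_rigid(rng, max_deg=10.0, max_t=5.0)
        moved = left_mesh.transformed(true)
        est = icp_register(left_mesh, moved, max_points=6000)
        resid = est.apply(left_mesh.vertices) - moved.vertices
        assert np.sqrt((resid**2).sum(axis=1).mean()) < 0.01

    def test_rms_non_increasing(self, left_mesh):
        rng = np.random.default_rng(3)
        moved = left_mesh.transformed(random_rigid(rng))
        est = icp_register(left_mesh, moved, max_points=4000,
                           init="centroid")
        diffs = np.diff(est.rms_history)
        assert np.all(diffs <= 1e-9)

    def test_degenerate_geometry_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10),
                                np.zeros(10)])
        mesh = SurfaceMesh(line, np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="collinear"):
            icp_register(mesh, mesh)

    def test_transform_invariants(self):
        rng = np.random.default_rng(1)
        t = random_rigid(rng)
        r = t.rotation
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0)
        pts = rng.normal(size=(20, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)


class TestCorrespondence:
    def test_identical_meshes_match_at_zero(self, sphere_mesh):
        corr = correspond(sphere_mesh, sphere_mesh)
        assert np.allclose(corr.matched_points, sphere_mesh.vertices,
                           atol=1e-12)

    def test_planar_offset_distance(self):
        # a flat grid offset 1 mm along its normal: matched distance = 1 mm
        xx, yy = np.meshgrid(np.arange(10.0), np.arange(10.0))
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(100)])
        cells = []
        for i in range(9):
            for j in range(9):
                a = i * 10 + j
                cells += [[a, a + 1, a + 10], [a + 1, a + 11, a + 10]]
        plane = SurfaceMesh(verts, np.asarray(cells))
        shifted = SurfaceMesh(verts + [0, 0, 1.0], np.asarray(cells))
        corr = correspond(plane, shifted)
        d = vertex_distance(corr).d
        assert np.allclose(d, 1.0, atol=1e-9)

    def test_matched_points_lie_on_triangles(self, sphere_mesh):
        rng = np.random.default_rng(5)
        jitter = replace(sphere_mesh,
                         vertices=sphere_mesh.vertices
                         + rng.normal(0, 0.1, sphere_mesh.vertices.shape))
        corr = correspond(jitter, sphere_mesh)
        bary = barycentric_coordinates(corr, sphere_mesh)
        assert np.all(bary > -1e-9) and np.all(bary < 1 + 1e-9)
        assert np.allclose(bary.sum(axis=1), 1.0, atol=1e-9)

    @staticmethod
    def _brute_surface_distance(point, verts, faces):
        """Exhaustive min distance to every triangle, via plane projection
        with edge clamping — an independent formulation of the minimizer."""
        a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
        n = np.cross(b - a, c - a)
        nn = np.linalg.norm(n, axis=1, keepdims=True)
        n = n / np.where(nn > 0, nn, 1.0)
        proj = point - ((point - a) * n).sum(1)[:, None] * n
        # inside test via same-side cross products
        def side(p, q, r, x):
            return (np.cross(q - p, x - p) * n).sum(1)
        inside = ((side(a, b, c, proj) >= -1e-12)
                  & (side(b, c, a, proj) >= -1e-12)
                  & (side(c, a, b, proj) >= -1e-12))
        d_plane = np.linalg.norm(point - proj, axis=1)

        def seg_d(p, q):
            pq = q - p
            t = np.clip(((point - p) * pq).sum(1)
                        / (pq * pq).sum(1), 0, 1)
            return np.linalg.norm(point - (p + t[:, None] * pq), axis=1)

        d_edges = np.minimum.reduce([seg_d(a, b), seg_d(b, c), seg_d(c, a)])
        return np.where(inside, d_plane, d_edges).min()

    def test_matches_exhaustive_closest_point_oracle(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        target = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        rng = np.random.default_rng(6)
        pick = rng.choice(len(target.vertices), 150, replace=False)
        points = target.vertices[pick] + rng.normal(0, 0.5, (150, 3))
        probe = SurfaceMesh(points, np.zeros((0, 3), dtype=int))
        corr = correspond(probe, target, k_candidates=6)
        got = np.linalg.norm(corr.matched_points - points, axis=1)
        want = np.array([
            self._brute_surface_distance(p, target.vertices, target.faces)
            for p in points
        ])
        assert np.allclose(got, want, atol=1e-9)

    def test_empty_target_rejected(self, sphere_mesh):
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            correspond(sphere_mesh, empty)


class TestVertexDistance:
    def test_exact_arithmetic(self):
        from hipshape.shape import Correspondence

        corr = Correspondence(np.array([[0.0, 0, 0], [0, 0, 0]]),
                              np.array([[0.0, 0, 0], [1, 2, 2]]),
                              np.zeros(2, dtype=int), np.zeros(2, dtype=int))
        assert np.allclose(vertex_distance(corr).d, [0.0, 3.0])

    def test_invariance_under_common_rigid_motion(self, sphere_mesh):
        rng = np.random.default_rng(9)
        other = replace(sphere_mesh,
                        vertices=sphere_mesh.vertices
                        + rng.normal(0, 0.2, sphere_mesh.vertices.shape))
        d0 = vertex_distance(correspond(sphere_mesh, other)).d
        t = random_rigid(rng)
        d1 = vertex_distance(correspond(
            sphere_mesh.transformed(t), other.transformed(t))).d
        assert np.abs(d0 - d1).max() < 1e-6


class TestAxesAndSphere:
    def test_shaft_axis_near_vertical(self, left_mesh):
        axes = estimate_axes(left_mesh)
        # phantom shaft runs inferior; axis oriented head -> shaft
        angle = np.rad2deg(np.arccos(abs(axes.shaft @ [0, 0, 1])))
        assert angle < 15.0
        assert axes.shaft @ [0, 0, -1] > 0

    def test_axes_orthonormal(self, left_mesh):
        axes = estimate_axes(left_mesh)
        basis = np.stack([axes.anterior, axes.medial, axes.superior])
        assert np.allclose(basis @ basis.T, np.eye(3), atol=1e-9)

    def test_mirroring_flips_medial_axis_only(self, left_volume):
        mirrored = extract_mesh(mirror_right(left_volume), smoothing_iters=0)
        plain = extract_mesh(left_volume, smoothing_iters=0)
        a, b = estimate_axes(plain), estimate_axes(mirrored)
        assert np.allclose(a.medial, -b.medial)
        assert np.allclose(a.anterior, b.anterior)
        assert np.allclose(a.superior, b.superior)

    def test_near_isotropic_scatter_rejected(self, sphere_mesh):
        with pytest.raises(ValueError, match="axis"):
            estimate_axes(sphere_mesh)

    def test_exact_sphere_recovered_exactly(self):
        rng = np.random.default_rng(2)
        dirs = rng.normal(size=(500, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        center, radius = np.array([3.0, -2.0, 7.0]), 13.5
        pts = center + radius * dirs
        mesh = SurfaceMesh(pts, np.zeros((0, 3), dtype=int))
        c, r = fit_head_sphere(mesh, shaft_axis=np.array([0.0, 0, -1.0]),
                               head_fraction=1.0)
        assert np.allclose(c, center, atol=1e-9)
        assert r == pytest.approx(radius, abs=1e-9)

    def test_phantom_head_sphere_recovered(self, left_mesh):
        c, r = fit_head_sphere(left_mesh)
        assert np.linalg.norm(c) < 0.5  # construction centre = origin
        assert r == pytest.approx(22.0, abs=0.5)

    def test_coplanar_candidates_rejected(self):
        pts = np.column_stack([np.random.default_rng(0).normal(size=(20, 2)),
                               np.zeros(20)])
        mesh = SurfaceMesh(pts, np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="coplanar|candidate"):
            fit_head_sphere(mesh, shaft_axis=np.array([0.0, 0, -1.0]),
                            head_fraction=1.0)


class TestShaftCutoff:
    def test_full_length_cutoff_is_identity(self, left_mesh):
        length = measure_shaft_length(left_mesh)
        cut = apply_shaft_cutoff(left_mesh, length + 1.0)
        assert len(cut.vertices) == len(left_mesh.vertices)

    def test_cutoff_limits_extent(self, left_mesh):
        axes = estimate_axes(left_mesh)
        center, _ = fit_head_sphere(left_mesh, axes.shaft)
        cut = apply_shaft_cutoff(left_mesh, 60.0)
        extent = measure_shaft_length(cut, axes=axes, center=center)
        assert extent == pytest.approx(60.0, abs=1.0)

    def test_cutoff_on_volume(self, femur_spec, left_volume):
        cut = apply_shaft_cutoff(left_volume, 60.0)
        assert 0 < cut.foreground_count() < left_volume.foreground_count()
        assert cut.connected_components() == 1

    def test_removing_head_rejected(self, left_mesh):
        with pytest.raises(ValueError, match="head"):
            apply_shaft_cutoff(left_mesh, -100.0)

    def test_cohort_cutoff_is_minimum(self, femur_spec, left_mesh):
        short = extract_mesh(make_femur_volume(
            replace(femur_spec, shaft_length=50.0), "left"))
        cutoff = cohort_shaft_cutoff([left_mesh, short])
        assert cutoff == pytest.approx(measure_shaft_length(short), abs=1e-9)


class TestPartition:
    @staticmethod
    def _unit_axes():
        return AxisSet(np.array([0.0, 0, -1]), np.array([0.0, 1, 0]),
                       np.array([1.0, 0, 0]), np.array([0.0, 0, 1]))

    def test_octants_partition_sphere_evenly(self, sphere_mesh):
        dmap = DistanceMap(sphere_mesh.vertices,
                           np.zeros(len(sphere_mesh.vertices)))
        dmap = partition_head(dmap, self._unit_axes(), np.zeros(3),
                              roi_diameter=55.0)
        counts = np.array([(dmap.octant == o).sum() for o in OCTANTS])
        assert (counts > 0).all()
        assert counts.max() < 1.2 * counts.min()
        # disjoint and exhaustive over the ROI
        assert counts.sum() == dmap.roi.sum()
        assert (dmap.octant[~dmap.roi] == "").all()

    def test_sign_convention(self):
        verts = np.array([[1.0, 1.0, 1.0], [-1.0, -1.0, -1.0],
                          [0.0, 0.0, 0.0]])
        # anterior=+y, medial=+x, superior=+z
        dmap = partition_head(DistanceMap(verts, np.zeros(3)),
                              self._unit_axes(), np.zeros(3), 10.0)
        assert dmap.octant[0] == "AMS"
        assert dmap.octant[1] == "PLI"
        assert dmap.octant[2] == "AMS"  # zero distance -> positive side

    def test_empty_roi_rejected(self, sphere_mesh):
        dmap = DistanceMap(sphere_mesh.vertices,
                           np.zeros(len(sphere_mesh.vertices)))
        with pytest.raises(ValueError):
            partition_head(dmap, self._unit_axes(),
                           np.array([500.0, 0, 0]), 10.0)


class TestBSDM:
    def test_zero_distances_zero_table(self, sphere_mesh):
        dmap = DistanceMap(sphere_mesh.vertices,
                           np.zeros(len(sphere_mesh.vertices)))
        dmap = partition_head(dmap, TestPartition._unit_axes(), np.zeros(3))
        table = bsdm_summary(dmap)
        assert (table["mean_mm"] == 0).all()
        assert (table["sd_mm"] == 0).all()

    def test_head_mean_is_count_weighted_octant_mean(self, sphere_mesh):
        rng = np.random.default_rng(4)
        dmap = DistanceMap(sphere_mesh.vertices,
                           rng.uniform(0, 2, len(sphere_mesh.vertices)))
        dmap = partition_head(dmap, TestPartition._unit_axes(), np.zeros(3))
        table = bsdm_summary(dmap)
        oct_rows = table.drop("head")
        weighted = (oct_rows["mean_mm"] * oct_rows["n_vertices"]).sum() \
            / oct_rows["n_vertices"].sum()
        assert table.loc["head", "mean_mm"] == pytest.approx(weighted)
        assert oct_rows["n_vertices"].sum() == table.loc["head", "n_vertices"]

    def test_empty_octant_reported_missing(self):
        verts = np.array([[1.0, 1, 1], [2.0, 1, 1]])
        dmap = partition_head(DistanceMap(verts, np.array([1.0, 2.0])),
                              TestPartition._unit_axes(), np.zeros(3), 20.0)
        table = bsdm_summary(dmap)
        assert np.isnan(table.loc["PLI", "mean_mm"])
        assert table.loc["PLI", "n_vertices"] == 0


class TestAtlasAlignment:
    def test_atlas_to_itself_identity(self, left_mesh):
        (aligned, t), = align_to_atlas([left_mesh], left_mesh,
                                       max_points=4000)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(aligned.vertices, left_mesh.vertices, atol=1e-5)

    def test_recovers_applied_rotations(self, left_mesh):
        rng = np.random.default_rng(8)
        true = random_rigid(rng, max_deg=20.0, max_t=10.0)
        moved = left_mesh.transformed(true)
        (_, est), = align_to_atlas([moved], left_mesh, max_points=4000)
        # est should invert true
        comp = est.compose(true)
        assert np.allclose(comp.rotation, np.eye(3), atol=1e-4)
        assert np.allclose(comp.translation, 0.0, atol=1e-3)


class TestFullPipeline:
    def test_bump_localizes_and_bsdm_invariant_to_atlas_frame(self):
        spec = FemurPhantomSpec(bump_region="PLS", bump_height=3.0,
                                spacing=1.2)
        pair = make_asymmetric_pair(spec)
        res = compare_pair(pair.left, pair.right)
        octs = res.table.drop("head")
        assert octs["mean_mm"].idxmax() == "PLS"
        peak = res.distance_map.d[res.distance_map.roi].max()
        assert peak == pytest.approx(3.0, rel=0.15)
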