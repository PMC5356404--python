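"""Wall shear stress estimation and the ten-region summary."""
import numpy as np
import pytest

import aorta4d as a
from aorta4d import phantom, wss
from aorta4d.phantom import VelocityField4D
from aorta4d.wss import WSSMap

from conftest import lumen_mask_of


def flat_field(speeds_per_frame, shape=(8, 8, 8)):
    """Uniform axial field with a prescribed per-frame speed."""
    T = len(speeds_per_frame)
    vel = np.zeros((T, 3) + shape, dtype=np.float32)
    for t, v in enumerate(speeds_per_frame):
        vel[t, 0] = v
    return VelocityField4D(vel, np.ones((T,) + shape, dtype=np.float32),
                           (1.0, 1.0, 1.0), 40.0, 150.0)


class TestPeakDetection:
    def test_phantom_waveform_peak(self, tube_15mm_spacing):
        field, truth = tube_15mm_spacing
        assert wss.detect_peak_systole(field, truth.true_mask) == 5

    def test_flat_waveform_ties_resolve_earliest(self):
        field = flat_field([50.0] * 7)
        mask = np.ones((8, 8, 8), dtype=bool)
        assert wss.detect_peak_systole(field, mask) == 2  # earliest admissible

    def test_two_peak_waveform_takes_higher(self):
        field = flat_field([0, 0, 40.0, 0, 0, 60.0, 0, 0])
        mask = np.ones((8, 8, 8), dtype=bool)
        assert wss.detect_peak_systole(field, mask) == 5

    def test_peak_near_boundary_rejected(self):
        field = flat_field([90.0, 10.0, 10.0, 10.0, 10.0])
        mask = np.ones((8, 8, 8), dtype=bool)
        with pytest.raises(ValueError):
            wss.detect_peak_systole(field, mask)


class TestWSSVectors:
    def test_zero_field_zero_wss(self, tube_1mm):
        field, truth = tube_1mm
        zero = field.copy()
        zero.velocity[:] = 0
        mesh = a.make_true_wall_mesh(truth)
        vecs, ok = wss.estimate_wss_vectors(zero, mesh, 5)
        assert np.allclose(vecs, 0)

    def test_poiseuille_magnitude_and_direction(self, tube_1mm):
        """Per-vertex magnitude within 10% of 2*mu*v_peak/R = 0.64 Pa;
        direction within 10 degrees of the axial flow direction."""
        field, truth = tube_1mm
        mesh = a.make_true_wall_mesh(truth, ds_mm=2.0, n_theta=48)
        vecs, ok = wss.estimate_wss_vectors(field, mesh, truth.peak_frame_index)
        mag = np.linalg.norm(vecs[ok], axis=1)
        assert np.all(np.abs(mag - 0.64) / 0.64 < 0.10)
        axial = np.array([1.0, 0.0, 0.0])
        cosang = (vecs[ok] @ axial) / mag
        assert np.all(np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 10.0)

    def test_linear_in_viscosity(self, tube_1mm):
        field, truth = tube_1mm
        mesh = a.make_true_wall_mesh(truth)
        v1, _ = wss.estimate_wss_vectors(field, mesh, 5, mu=0.0032)
        v2, _ = wss.estimate_wss_vectors(field, mesh, 5, mu=0.0064)
        assert np.allclose(v2, 2.0 * v1, rtol=1e-10)

    def test_vectors_tangential_to_wall(self, tube_1mm):
        field, truth = tube_1mm
        mesh = a.make_true_wall_mesh(truth)
        vecs, ok = wss.estimate_wss_vectors(field, mesh, 5)
        mag = np.linalg.norm(vecs, axis=1)
        normal_part = np.abs(np.einsum("ij,ij->i", vecs, mesh.inward_normals))
        sel = mag > 1e-9
        assert np.all(normal_part[sel] < 1e-6 * mag[sel])


class TestSystolicMean:
    def test_mean_over_five_frames(self, tube_1mm):
        """Systolic mean equals the analytic mean of the per-frame truth."""
        field, truth = tube_1mm
        mesh = a.make_true_wall_mesh(truth, ds_mm=4.0, n_theta=24)
        wmap = wss.systolic_mean_wss(field, mesh, truth.true_mask)
        assert wmap.peak_frame_index == truth.peak_frame_index
        expected = truth.true_wss_pa[0]
        rel = np.abs(wmap.systolic_mean_magnitude[wmap.valid] - expected) / expected
        assert np.median(rel) < 0.10

    def test_steady_flow_mean_equals_single_frame(self):
        """All frames identical: the five-frame mean equals one frame."""
        field = flat_field([50.0] * 7, shape=(24, 24, 24))
        g = np.mgrid[0:24, 0:24, 0:24]
        r = np.sqrt((g[1] - 12.0) ** 2 + (g[2] - 12.0) ** 2)
        prof = np.where(r < 8.0, 50.0 * (1 - (r / 8.0) ** 2), 0.0)
        field.velocity[:, 0] = prof[None].astype(np.float32)
        field.velocity[:, 1:] = 0
        mask = np.broadcast_to(r < 8.0, (24, 24, 24))
        pts = np.stack([np.linspace(4, 20, 9), np.full(9, 12.0), np.full(9, 12.0)],
                       axis=1)
        from aorta4d.segmentation import WallMesh
        normals = np.tile([0.0, 0.0, 1.0], (9, 1))
        verts = pts + np.array([0.0, 0.0, -8.0])
        mesh = WallMesh(verts, np.array([[0, 1, 2]]), normals, np.ones(9))
        wmap = wss.systolic_mean_wss(field, mesh, np.asarray(mask), peak_frame=3)
        single, _ = wss.estimate_wss_vectors(field, mesh, 3)
        assert np.allclose(wmap.systolic_mean_magnitude,
                           np.linalg.norm(single, axis=1), rtol=1e-6)

    def test_arithmetic_mean_of_magnitudes(self):
        """Per-frame magnitudes {0.5, 0.6, 0.7, 0.6, 0.5} average to 0.58."""
        mags = np.array([0.5, 0.6, 0.7, 0.6, 0.5])
        vectors = np.zeros((5, 1, 3))
        vectors[:, 0, 0] = mags
        wmap = WSSMap(vectors_pa=vectors, frames=np.arange(5),
                      systolic_mean_magnitude=np.linalg.norm(vectors, axis=2).mean(axis=0),
                      peak_frame_index=2, viscosity_pa_s=0.0032,
                      valid=np.ones(1, dtype=bool))
        assert wmap.systolic_mean_magnitude[0] == pytest.approx(0.58)


class TestPartition:
    def test_ten_nonempty_regions(self, candy_cane):
        _, _, _, mesh, cl = candy_cane
        part = wss.partition_ten_regions(mesh, cl)
        for idx in range(1, 11):
            assert (part.labels == idx).sum() > 0, wss.REGION_NAMES[idx - 1]

    def test_concave_side_is_inner(self, candy_cane):
        """Arch vertices labeled inner lie closer to the torus center."""
        _, truth, _, mesh, cl = candy_cane
        geom = truth.geometry
        torus_center = np.array([geom.arch_radius_mm, 0.0, geom.limb1_mm])
        s, _, _ = cl.nearest(mesh.vertices)
        arch = ((s > cl.landmarks["dAAo"] + 10) &
                (s < cl.landmarks["isthmus"] - 10))
        part = wss.partition_ten_regions(mesh, cl)
        d = np.linalg.norm(mesh.vertices - torus_center, axis=1)
        inner_arch = arch & (part.labels == 5)
        outer_arch = arch & (part.labels == 6)
        assert d[inner_arch].max() < d[outer_arch].min() + 2.0

    def test_branch_mask_exclusion(self, candy_cane):
        from aorta4d.segmentation import LumenMask
        field, truth, mask, mesh, cl = candy_cane
        apex = mesh.vertices[np.argmax(mesh.vertices[:, 2])]
        branch_vol = np.zeros_like(mask.volume)
        vox = np.round(mask.mm_to_voxel(apex)).astype(int)
        sl = tuple(slice(max(v - 3, 0), v + 4) for v in vox)
        branch_vol[sl] = True
        branch = LumenMask(branch_vol, mask.spacing_mm, mask.origin_mm)
        part = wss.partition_ten_regions(mesh, cl, branch_masks=branch)
        part_no = wss.partition_ten_regions(mesh, cl)
        newly_excluded = (part.labels == 0) & (part_no.labels != 0)
        assert newly_excluded.sum() > 0
        d = np.linalg.norm(mesh.vertices[newly_excluded] - apex, axis=1)
        assert d.max() < 20.0

    def test_moving_one_landmark_moves_only_that_boundary(self, candy_cane):
        _, _, _, mesh, cl = candy_cane
        part1 = wss.partition_ten_regions(mesh, cl)
        shifted = dict(cl.landmarks)
        shifted["midAAo"] = shifted["midAAo"] + 10.0
        import dataclasses
        cl2 = dataclasses.replace(cl, landmarks=shifted)
        part2 = wss.partition_ten_regions(mesh, cl2)
        changed = part1.labels != part2.labels
        s, _, _ = cl.nearest(mesh.vertices)
        lo, hi = cl.landmarks["midAAo"], shifted["midAAo"]
        assert np.all((s[changed] >= lo - 2.0) & (s[changed] <= hi + 2.0))
        # pAAo gained exactly the vertices dAAo lost
        assert np.all(part2.labels[changed] <= 2)
        assert np.all(part1.labels[changed] >= 3)

    def test_unordered_landmarks_rejected(self, candy_cane):
        import dataclasses
        _, _, _, mesh, cl = candy_cane
        bad = dict(cl.landmarks)
        bad["midAAo"], bad["dAAo"] = bad["dAAo"], bad["midAAo"]
        with pytest.raises(ValueError):
            wss.partition_ten_regions(mesh, dataclasses.replace(cl, landmarks=bad))


class TestRegionalMean:
    def test_uniform_wss_reported_everywhere(self, candy_cane):
        _, _, _, mesh, cl = candy_cane
        part = wss.partition_ten_regions(mesh, cl)
        wmap = WSSMap(vectors_pa=np.zeros((5, mesh.n_vertices, 3)),
                      frames=np.arange(5),
                      systolic_mean_magnitude=np.full(mesh.n_vertices, 0.7),
                      peak_frame_index=5, viscosity_pa_s=0.0032,
                      valid=np.ones(mesh.n_vertices, dtype=bool))
        table = wss.regional_wss_mean(wmap, part, mesh)
        assert len(table) == 10
        assert np.allclose(table["wss_mean_pa"], 0.7)

    def test_empty_region_reported_missing(self, candy_cane):
        _, _, _, mesh, cl = candy_cane
        part = wss.partition_ten_regions(mesh, cl)
        part.labels[part.labels == 3] = 0       # empty out one region
        wmap = WSSMap(vectors_pa=np.zeros((5, mesh.n_vertices, 3)),
                      frames=np.arange(5),
                      systolic_mean_magnitude=np.full(mesh.n_vertices, 0.7),
                      peak_frame_index=5, viscosity_pa_s=0.0032,
                      valid=np.ones(mesh.n_vertices, dtype=bool))
        table = wss.regional_wss_mean(wmap, part, mesh)
        row = table[table["region"] == "inner_dAAo"].iloc[0]
        assert np.isnan(row["wss_mean_pa"])
        assert row["n_vertices"] == 0

    def test_tube_segment_mean_near_analytic(self, tube_1mm):
        field, truth = tube_1mm
        mesh = a.make_true_wall_mesh(truth, ds_mm=2.0, n_theta=48)
        wmap = wss.systolic_mean_wss(field, mesh, truth.true_mask)
        from aorta4d.wss import RegionPartition
        from aorta4d import geometry
        cl = geometry.centerline_from_points(truth.true_centerline_points_mm)
        s, _, _ = cl.nearest(mesh.vertices)
        labels = np.where((s > 20) & (s < 80), 7, 0).astype(np.int32)
        table = wss.regional_wss_mean(wmap, RegionPartition(labels=labels), mesh)
        got = table.loc[table["region"] == "inner_pDAo", "wss_mean_pa"].iloc[0]
        assert got == pytest.approx(truth.true_wss_pa[0], rel=0.10)
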