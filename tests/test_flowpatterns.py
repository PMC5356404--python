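"""Pathline integration and helix/vortex grading."""
import numpy as np
import pytest

import aorta4d as a
from aorta4d import flowpatterns as fp, geometry, phantom, segmentation
from aorta4d.phantom import VelocityField4D

from conftest import lumen_mask_of


def uniform_field(vx_cm_s, n=3, shape=(120, 20, 20), spacing=1.0):
    vel = np.zeros((n, 3) + shape)
    vel[:, 0] = vx_cm_s
    return VelocityField4D(vel, np.ones((n,) + shape), (spacing,) * 3,
                           100.0, 150.0)


def all_mask(shape=(120, 20, 20), spacing=1.0):
    return segmentation.LumenMask(np.ones(shape, dtype=bool), (spacing,) * 3)


def rotation_field(omega_rad_s=2 * np.pi, n=3, nx=41):
    g = np.mgrid[0:nx, 0:nx, 0:nx].astype(float)
    vel = np.zeros((n, 3, nx, nx, nx))
    vel[:, 0] = -omega_rad_s * (g[1] - 20.0) * 0.1    # mm/s -> cm/s
    vel[:, 1] = omega_rad_s * (g[0] - 20.0) * 0.1
    return VelocityField4D(vel, np.ones((n, nx, nx, nx)), (1.0, 1.0, 1.0),
                           250.0, 150.0)


class TestIntegration:
    def test_uniform_advection(self):
        """100 cm/s along x for 100 ms displaces exactly 10 cm."""
        field = uniform_field(100.0)
        lines = fp.integrate_pathlines(field, all_mask(),
                                       np.array([[5.0, 10.0, 10.0]]),
                                       dt_ms=5.0, t_end_ms=100.0)
        end = lines[0].positions_mm[-1]
        assert end == pytest.approx([105.0, 10.0, 10.0], abs=1e-6)

    def test_solid_body_rotation_half_turn(self):
        """omega = 2*pi rad/s for 0.5 s rotates a particle by 180 +/- 1 deg."""
        field = rotation_field()
        mask = all_mask(shape=(41, 41, 41))
        lines = fp.integrate_pathlines(field, mask, np.array([[28.0, 20.0, 20.0]]),
                                       dt_ms=5.0, t_end_ms=500.0)
        end = lines[0].positions_mm[-1]
        assert end[:2] == pytest.approx([12.0, 20.0], abs=8 * np.deg2rad(1.0))

    def test_zero_field_stays_at_seed(self):
        field = uniform_field(0.0)
        lines = fp.integrate_pathlines(field, all_mask(),
                                       np.array([[30.0, 10.0, 10.0]]), dt_ms=5.0)
        assert np.allclose(lines[0].positions_mm, [30.0, 10.0, 10.0])

    def test_dt_exceeding_frame_interval_rejected(self):
        field = uniform_field(10.0)
        with pytest.raises(ValueError):
            fp.integrate_pathlines(field, all_mask(),
                                   np.array([[5.0, 10.0, 10.0]]), dt_ms=500.0)

    def test_fourth_order_convergence(self):
        """Halving dt shrinks the endpoint error by at least 8x."""
        field = rotation_field()
        mask = all_mask(shape=(41, 41, 41))
        seed = np.array([[28.0, 20.0, 20.0]])
        exact = np.array([12.0, 20.0, 20.0])
        errs = []
        for dt in (25.0, 12.5):
            lines = fp.integrate_pathlines(field, mask, seed, dt_ms=dt,
                                           t_end_ms=500.0)
            errs.append(np.linalg.norm(lines[0].positions_mm[-1] - exact))
        assert errs[0] / errs[1] >= 8.0

    def test_times_strictly_increasing_and_inside_lumen(self, tube_15mm_spacing):
        field, truth = tube_15mm_spacing
        mask = lumen_mask_of(field, truth)
        cl = geometry.centerline_from_points(truth.true_centerline_points_mm)
        seeds = fp.seed_inlet_plane(cl, mask, n=20, rng=0)
        lines = fp.integrate_pathlines(field, mask, seeds, dt_ms=4.0)
        for pl in lines:
            assert np.all(np.diff(pl.t_ms) > 0)
            s, near, _ = cl.nearest(pl.positions_mm)
            radial = np.linalg.norm(pl.positions_mm - near, axis=1)
            assert radial.max() <= 10.0 + 1.5    # within one voxel of the wall


def helix_phantom(swirl_deg_per_cm, snr=np.inf, seed=0):
    spec = a.PhantomSpec(geometry_kind="straight_tube", radius_mm=10.0,
                         length_mm=140.0, spacing_mm=(1.5, 1.5, 1.5),
                         v_peak_cm_s=100.0, venc_cm_s=150.0, seed=seed)
    field, truth = a.make_phantom(spec)
    field, truth = a.add_swirl(field, truth, swirl_deg_per_cm)
    field = a.degrade(field, truth, snr=snr)
    mask = lumen_mask_of(field, truth)
    cl = geometry.centerline_from_points(truth.true_centerline_points_mm)
    seeds = fp.seed_inlet_plane(cl, mask, n=200, s_mm=5.0,
                                rng=np.random.default_rng(seed + 1))
    lines = fp.integrate_pathlines(field, mask, seeds, dt_ms=4.0)
    return lines, cl


def vortex_phantom(rotation_deg, snr=np.inf, seed=0):
    prof = phantom.bulge_radius_profile(10.0, 5.0, center_mm=70.0, sigma_mm=10.0)
    spec = a.PhantomSpec(geometry_kind="straight_tube", radius_mm=prof,
                         length_mm=140.0, spacing_mm=(1.5, 1.5, 1.5),
                         v_peak_cm_s=15.0, venc_cm_s=150.0, seed=seed)
    field, truth = a.make_phantom(spec)
    if rotation_deg:
        omega = phantom.omega_for_rotation(rotation_deg, 800.0)
        field, truth = a.add_vortex_pocket(field, truth, 70.0, 7.0,
                                           0.1 * omega * 7.0)
    field = a.degrade(field, truth, snr=snr)
    mask = lumen_mask_of(field, truth)
    cl = geometry.centerline_from_points(truth.true_centerline_points_mm)
    seeds = fp.seed_lumen_volume(mask, n=400, rng=np.random.default_rng(seed + 1),
                                 centerline=cl, s_range_mm=(30.0, 110.0))
    lines = fp.integrate_pathlines(field, mask, seeds, dt_ms=4.0)
    return lines, cl


class TestHelixGrading:
    @pytest.mark.parametrize("swirl,expected", [(0.0, 0), (18.0, 1), (40.0, 2)])
    def test_imposed_swirl_grades(self, swirl, expected):
        lines, cl = helix_phantom(swirl)
        grade = fp.grade_helix(lines, cl, (20.0, 120.0))
        assert grade.grade == expected

    def test_measured_rotation_near_truth(self):
        lines, cl = helix_phantom(18.0)
        grade = fp.grade_helix(lines, cl, (20.0, 120.0))
        assert grade.max_rotation_deg == pytest.approx(180.0, rel=0.10)

    def test_grade_zero_under_noise(self):
        """Pure Poiseuille flow grades 0 even at snr = 20."""
        lines, cl = helix_phantom(0.0, snr=20.0, seed=5)
        assert fp.grade_helix(lines, cl, (20.0, 120.0)).grade == 0

    def test_invariant_to_rigid_rotation(self):
        """The same swirl graded on a tube tilted 30 degrees about z."""
        spec = a.PhantomSpec(geometry_kind="straight_tube", radius_mm=10.0,
                             length_mm=140.0, spacing_mm=(1.5, 1.5, 1.5),
                             v_peak_cm_s=100.0,
                             axis=(np.cos(np.pi / 6), np.sin(np.pi / 6), 0.0))
        field, truth = a.make_phantom(spec)
        field, truth = a.add_swirl(field, truth, 18.0)
        mask = lumen_mask_of(field, truth)
        cl = geometry.centerline_from_points(truth.true_centerline_points_mm)
        seeds = fp.seed_inlet_plane(cl, mask, n=200, s_mm=5.0,
                                    rng=np.random.default_rng(9))
        lines = fp.integrate_pathlines(field, mask, seeds, dt_ms=4.0)
        grade = fp.grade_helix(lines, cl, (20.0, 120.0))
        assert grade.grade == 1
        assert grade.max_rotation_deg == pytest.approx(180.0, rel=0.10)

    def test_too_few_traversing_rejected(self):
        lines, cl = helix_phantom(18.0)
        with pytest.raises(fp.InsufficientPathlinesError):
            fp.grade_helix(lines[:5], cl, (20.0, 120.0))


class TestVortexGrading:
    @pytest.mark.parametrize("rotation,expected", [(0.0, 0), (180.0, 1), (720.0, 2)])
    def test_imposed_revolve_grades(self, rotation, expected):
        lines, cl = vortex_phantom(rotation)
        grade = fp.grade_vortex(lines, cl, (30.0, 110.0))
        assert grade.grade == expected

    def test_clean_tube_no_reversal(self):
        """Forward Poiseuille flow has no >90-degree deviating samples."""
        lines, cl = vortex_phantom(0.0)
        grade = fp.grade_vortex(lines, cl, (30.0, 110.0))
        assert grade.grade == 0
        assert grade.max_rotation_deg == 0.0

    def test_grade_zero_under_noise(self):
        lines, cl = vortex_phantom(0.0, snr=20.0, seed=3)
        assert fp.grade_vortex(lines, cl, (30.0, 110.0)).grade == 0

    def test_too_few_visiting_rejected(self):
        lines, cl = vortex_phantom(720.0)
        with pytest.raises(fp.InsufficientPathlinesError):
            fp.grade_vortex(lines[:10], cl, (30.0, 110.0))


class TestCohortSummary:
    def test_prevalence_and_mean(self):
        import pandas as pd
        df = pd.DataFrame({"subject_id": list("abcd"), "group": ["g"] * 4,
                           "segment": ["DAo"] * 4, "pattern": ["vortex"] * 4,
                           "grade": [2, 1, 0, 0]})
        out = fp.cohort_pattern_summary(df)
        assert out["prevalence_pct"].iloc[0] == pytest.approx(50.0)
        assert out["mean_grade"].iloc[0] == pytest.approx(0.75)

    def test_study_shaped_prevalences(self):
        """14 of 25 affected vs 2 of 21 gives 56% vs 9.5% prevalence."""
        import pandas as pd
        rows = []
        for i in range(25):
            rows.append({"subject_id": f"p{i}", "group": "patient",
                         "segment": "DAo", "pattern": "vortex",
                         "grade": 1 if i < 14 else 0})
        for i in range(21):
            rows.append({"subject_id": f"c{i}", "group": "control",
                         "segment": "DAo", "pattern": "vortex",
                         "grade": 1 if i < 2 else 0})
        out = fp.cohort_pattern_summary(pd.DataFrame(rows))
        prev = out.set_index("group")["prevalence_pct"]
        assert prev["patient"] == pytest.approx(56.0)
        assert prev["control"] == pytest.approx(9.5, abs=0.05)

    def test_all_zero_grades(self):
        import pandas as pd
        df = pd.DataFrame({"subject_id": list("ab"), "group": ["g"] * 2,
                           "segment": ["AAo"] * 2, "pattern": ["helix"] * 2,
                           "grade": [0, 0]})
        out = fp.cohort_pattern_summary(df)
        assert out["prevalence_pct"].iloc[0] == 0.0
        assert out["mean_grade"].iloc[0] == 0.0
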