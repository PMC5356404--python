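import numpy as np
import pytest

import aorta4d as a
from aorta4d import geometry, phantom, preprocess, segmentation


@pytest.fixture(scope="session")
def tube_1mm():
    """Clean straight tube, R = 10 mm, 1 mm isotropic, 20 frames."""
    spec = a.PhantomSpec(geometry_kind="straight_tube", radius_mm=10.0,
                         length_mm=100.0, spacing_mm=(1.0, 1.0, 1.0),
                         v_peak_cm_s=100.0)
    field, truth = a.make_phantom(spec)
    return field, truth


@pytest.fixture(scope="session")
def tube_15mm_spacing():
    """Clean straight tube at a coarser, faster-to-build resolution."""
    spec = a.PhantomSpec(geometry_kind="straight_tube", radius_mm=10.0,
                         length_mm=80.0, spacing_mm=(1.5, 1.5, 1.5),
                         v_peak_cm_s=100.0)
    field, truth = a.make_phantom(spec)
    return field, truth


@pytest.fixture(scope="session")
def candy_cane():
    """Candy-cane phantom with a mild proximal-descending bulge, segmented
    end to end (PC-MRA -> lumen -> mesh -> centerline)."""
    prof = phantom.bulge_radius_profile(10.0, 2.0, center_mm=175.0, sigma_mm=10.0)
    spec = a.PhantomSpec(geometry_kind="candy_cane", radius_mm=prof,
                         spacing_mm=(2.0, 1.8, 2.0))
    field, truth = a.make_phantom(spec)
    pcmra = preprocess.compute_pcmra(field)
    seed_vox = np.unravel_index(np.argmax(pcmra), pcmra.shape)
    mask = segmentation.segment_lumen(pcmra, field.spacing_mm, seed_vox,
                                      origin_mm=field.origin_mm)
    mesh = segmentation.extract_wall_mesh(mask)
    centerline = geometry.extract_centerline(
        mask, inlet_hint_mm=truth.true_centerline_points_mm[0])
    centerline.set_landmarks_by_fraction(
        {"STJ": 0.05, "midAAo": 0.15, "dAAo": 0.24, "isthmus": 0.67,
         "midDAo": 0.85, "dDAo": 0.97})
    return field, truth, mask, mesh, centerline


def lumen_mask_of(field, truth):
    return segmentation.LumenMask(truth.true_mask, field.spacing_mm, field.origin_mm)
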