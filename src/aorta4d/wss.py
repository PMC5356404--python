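"""Per-vertex 3D wall shear stress and the ten-region systolic summary.

For each wall point, velocity is sampled by trilinear interpolation along the
inward surface normal, the wall sample is forced to zero (no-slip), and a
quadratic is fitted through the samples; the wall shear stress vector is
tau = mu * d(v_t)/dn evaluated at the wall, where v_t is the velocity
component tangential to the surface.  The systolic WSS magnitude is the mean
over the five cardiac frames centered on peak systole.  Regional means are
area-weighted over ten anatomic wall regions -- the inner and outer halves of
the proximal/distal ascending aorta, arch, and proximal/distal descending
aorta -- with supra-aortic branch and end-cap vertices excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import CenterlineModel
from .phantom import DEFAULT_VISCOSITY_PA_S, VelocityField4D
from .segmentation import WallMesh

REGION_NAMES = (
    "inner_pAAo", "outer_pAAo",
    "inner_dAAo", "outer_dAAo",
    "inner_arch", "outer_arch",
    "inner_pDAo", "outer_pDAo",
    "inner_dDAo", "outer_dDAo",
)
EXCLUDED = 0

#: landmark keys bounding the five longitudinal bins, in order
PARTITION_LANDMARKS = ("STJ", "midAAo", "dAAo", "isthmus", "midDAo", "dDAo")


@dataclass
class WSSMap:
    vectors_pa: np.ndarray              # (5, V, 3) per systolic frame
    frames: np.ndarray                  # the five frame indices
    systolic_mean_magnitude: np.ndarray  # (V,)
    peak_frame_index: int
    viscosity_pa_s: float
    valid: np.ndarray                   # (V,) sampling ray stayed in volume


@dataclass
class RegionPartition:
    labels: np.ndarray                  # (V,) in 0..10; 0 = excluded
    region_names: tuple = REGION_NAMES


def detect_peak_systole(field4d: VelocityField4D, mask: np.ndarray) -> int:
    """Frame of maximal spatial mean speed inside the lumen (ties: earliest).

    Raises if the peak sits within two frames of either end of the cycle,
    since the five-frame systolic window could not be formed.
    """
    if field4d.n_frames < 5:
        raise ValueError("need at least 5 cardiac frames")
    mask = np.asarray(mask, dtype=bool)
    speed = np.linalg.norm(field4d.velocity[:, :, mask].astype(np.float64), axis=1)
    mean_speed = speed.mean(axis=1)
    interior = mean_speed[2:field4d.n_frames - 2]
    if mean_speed.max() > interior.max():
        peak = int(np.argmax(mean_speed))
        raise ValueError(f"peak frame {peak} too close to the cycle boundary "
                         "to form the peak +/- 2 window")
    return 2 + int(np.argmax(interior))


def _sample_velocity(field4d: VelocityField4D, frame: int, pts_mm: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear velocity samples (cm/s) and an in-bounds flag per point."""
    vox = (pts_mm - np.asarray(field4d.origin_mm)) / np.asarray(field4d.spacing_mm)
    shape = np.asarray(field4d.grid_shape)
    inb = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    out = np.empty((pts_mm.shape[0], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(field4d.velocity[frame, c], vox.T,
                                            order=1, mode="constant")
    return out, inb


def estimate_wss_vectors(field4d: VelocityField4D, mesh: WallMesh, frame: int,
                         mu: float = DEFAULT_VISCOSITY_PA_S,
                         n_samples: int = 3, step_mm: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex WSS vectors (Pa) at one frame.

    Velocity is sampled at distances 0, h, 2h, ... along the inward normal
    (h = ``step_mm``, default 1.5x the finest voxel spacing -- deep enough
    that the trilinear stencil of the first off-wall sample stays clear of
    the zero-velocity voxels outside the wall), the wall sample is forced to
    zero, and the wall derivative of a constrained quadratic fit is taken.  The derivative is projected onto the surface so the returned
    vectors are tangential.  Returns (vectors (V, 3), valid (V,)); vertices
    whose sampling ray leaves the volume are flagged invalid.
    """
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    if n_samples < 3:
        raise ValueError("need at least 3 samples along the normal")
    h = float(step_mm) if step_mm is not None else 1.5 * float(np.min(field4d.spacing_mm))

    V = mesh.n_vertices
    d = np.arange(1, n_samples) * h                        # off-wall distances
    samples = np.zeros((n_samples - 1, V, 3))
    valid = np.ones(V, dtype=bool)
    for i, di in enumerate(d):
        pts = mesh.vertices + di * mesh.inward_normals
        samples[i], inb = _sample_velocity(field4d, frame, pts)
        valid &= inb

    if n_samples == 3:
        # constrained quadratic through (0,0),(h,v1),(2h,v2): v'(0) = (4v1-v2)/(2h)
        dvdn = (4.0 * samples[0] - samples[1]) / (2.0 * h)
    else:
        # least squares v(d) = b*d + c*d^2 through the origin
        A = np.stack([d, d ** 2], axis=1)
        coef, *_ = np.linalg.lstsq(A, samples.reshape(n_samples - 1, -1), rcond=None)
        dvdn = coef[0].reshape(V, 3)

    # cm/s per mm -> 1/s
    dvdn_si = dvdn * 10.0
    normal_part = np.einsum("ij,ij->i", dvdn_si, mesh.inward_normals)
    tangential = dvdn_si - normal_part[:, None] * mesh.inward_normals
    return mu * tangential, valid


def systolic_mean_wss(field4d: VelocityField4D, mesh: WallMesh, mask: np.ndarray,
                      mu: float = DEFAULT_VISCOSITY_PA_S,
                      peak_frame: int | None = None, **kwargs) -> WSSMap:
    """WSS vectors over peak +/- 2 frames and their per-vertex mean magnitude."""
    if peak_frame is None:
        peak_frame = detect_peak_systole(field4d, mask)
    frames = np.arange(peak_frame - 2, peak_frame + 3)
    vecs = np.empty((5, mesh.n_vertices, 3))
    valid = np.ones(mesh.n_vertices, dtype=bool)
    for i, f in enumerate(frames):
        vecs[i], ok = estimate_wss_vectors(field4d, mesh, int(f), mu=mu, **kwargs)
        valid &= ok
    mags = np.linalg.norm(vecs, axis=2)
    return WSSMap(vectors_pa=vecs, frames=frames,
                  systolic_mean_magnitude=mags.mean(axis=0),
                  peak_frame_index=peak_frame, viscosity_pa_s=mu, valid=valid)


def partition_ten_regions(mesh: WallMesh, centerline: CenterlineModel,
                          branch_masks=None) -> RegionPartition:
    """Assign each vertex to one of the ten wall regions.

    Longitudinal bins run between the ordered landmarks STJ -> midAAo ->
    dAAo (innominate origin) -> isthmus (left subclavian) -> midDAo -> dDAo,
    using the arc position of the vertex's nearest centerline point.  The
    inner/outer split projects the vertex offset onto the in-arch-plane
    direction toward the centerline centroid: positive projections face the
    concave (inner) side.  Vertices before STJ or after dDAo (including end
    caps) and vertices inside ``branch_masks`` are labeled 0 (excluded).
    """
    missing = [k for k in PARTITION_LANDMARKS if k not in centerline.landmarks]
    if missing:
        raise ValueError(f"centerline lacks landmarks {missing}")
    bounds = np.array([centerline.landmarks[k] for k in PARTITION_LANDMARKS])
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("partition landmarks are not ordered along the centerline")

    s, near_pts, tangents = centerline.nearest(mesh.vertices)
    seg_bin = np.searchsorted(bounds, s, side="right") - 1   # 0..4 valid
    labels = np.zeros(mesh.n_vertices, dtype=np.int32)
    inside = (seg_bin >= 0) & (seg_bin <= 4) & (s <= bounds[-1])

    # inner/outer by projection toward the centerline centroid, in the arch plane
    n_pl = centerline.arch_plane_normal
    centroid = centerline.points_mm.mean(axis=0)
    offset = mesh.vertices - near_pts
    offset_inplane = offset - (offset @ n_pl)[:, None] * n_pl[None, :]
    to_centroid = centroid[None, :] - near_pts
    to_centroid -= (to_centroid @ n_pl)[:, None] * n_pl[None, :]
    to_centroid -= np.einsum("ij,ij->i", to_centroid, tangents)[:, None] * tangents
    norms = np.linalg.norm(to_centroid, axis=1)
    degen = norms < 1e-9
    if np.any(degen):
        # straight-vessel fallback: a fixed in-plane direction
        fallback = np.cross(tangents[degen], n_pl)
        to_centroid[degen] = fallback
        norms = np.linalg.norm(to_centroid, axis=1)
    to_centroid /= np.maximum(norms, 1e-12)[:, None]
    inner = np.einsum("ij,ij->i", offset_inplane, to_centroid) > 0.0

    labels[inside] = (2 * seg_bin[inside] + np.where(inner[inside], 0, 1) + 1)

    if branch_masks is not None:
        if not isinstance(branch_masks, (list, tuple)):
            branch_masks = [branch_masks]
        for bm in branch_masks:
            vox = bm.mm_to_voxel(mesh.vertices)
            inside_bm = ndimage.map_coordinates(
                bm.volume.astype(np.float32), vox.T, order=0, mode="constant") > 0.5
            labels[inside_bm] = EXCLUDED
    return RegionPartition(labels=labels)


def regional_wss_mean(wssmap: WSSMap, partition: RegionPartition,
                      mesh: WallMesh) -> pd.DataFrame:
    """Area-weighted mean systolic WSS magnitude per region.

    Rows follow the canonical region order; empty regions are reported with
    NaN mean (missing, not zero).  Invalid vertices (sampling ray left the
    volume) are ignored.
    """
    rows = []
    mag = wssmap.systolic_mean_magnitude
    for idx, name in enumerate(partition.region_names, start=1):
        sel = (partition.labels == idx) & wssmap.valid
        area = mesh.vertex_areas[sel]
        if sel.sum() == 0 or area.sum() == 0:
            rows.append({"region": name, "wss_mean_pa": np.nan,
                         "n_vertices": 0, "area_mm2": 0.0})
            continue
        rows.append({"region": name,
                     "wss_mean_pa": float(np.average(mag[sel], weights=area)),
                     "n_vertices": int(sel.sum()),
                     "area_mm2": float(area.sum())})
    return pd.DataFrame(rows)
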