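"""Aortic centerline, landmark diameters and BSA-indexed morphometry.

The centerline is the ordered, smoothed ridge of the lumen's interior
distance transform; landmark measurement planes are taken orthogonal to the
local tangent and diameters follow the clinical inner-edge to inner-edge
convention, read as the maximal caliper (Feret) diameter of the lumen
cross-section.  Aortic Z-scores index the measured diameter to body surface
area through a configurable normative model of the form
mean(BSA) = a + b * sqrt(BSA); a Z-score >= 2.0 classifies the level as
dilated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import ConvexHull, cKDTree

from .segmentation import LumenMask

LANDMARK_NAMES = ("Root", "STJ", "midAAo", "dAAo", "distal_arch",
                  "isthmus", "pDAo", "midDAo", "dDAo")

#: landmark whose normative entry substitutes for each landmark without its
#: own entry (the proximal descending aorta is referenced to the isthmus)
NORMATIVE_ALIASES = {"pDAo": "isthmus"}


@dataclass
class CenterlineModel:
    points_mm: np.ndarray           # (M, 3), ordered inlet -> outlet
    tangents: np.ndarray            # (M, 3), unit
    arc_length_mm: np.ndarray       # (M,), cumulative, strictly increasing
    arch_plane_point: np.ndarray
    arch_plane_normal: np.ndarray
    landmarks: dict = field(default_factory=dict)   # name -> arc position (mm)

    def __post_init__(self):
        if np.any(np.diff(self.arc_length_mm) <= 0):
            raise ValueError("arc length must be strictly increasing")
        self._tree = cKDTree(self.points_mm)

    @property
    def total_length_mm(self) -> float:
        return float(self.arc_length_mm[-1])

    def set_landmarks_by_fraction(self, fractions: dict) -> None:
        total = self.total_length_mm
        for name, frac in fractions.items():
            pos = frac * total
            if not (0.0 <= pos <= total):
                raise ValueError(f"landmark {name} outside the centerline")
            self.landmarks[name] = pos

    def nearest(self, pts: np.ndarray):
        """Arc position, nearest centerline point and tangent per query point."""
        pts = np.atleast_2d(pts)
        _, idx = self._tree.query(pts)
        return self.arc_length_mm[idx], self.points_mm[idx], self.tangents[idx]

    def at(self, s_mm: float):
        """Interpolated point and tangent at an arc position."""
        p = np.array([np.interp(s_mm, self.arc_length_mm, self.points_mm[:, k])
                      for k in range(3)])
        t = np.array([np.interp(s_mm, self.arc_length_mm, self.tangents[:, k])
                      for k in range(3)])
        return p, t / np.linalg.norm(t)


@dataclass
class NormativeModel:
    """Per-landmark normative diameter mean(BSA) = a + b*sqrt(BSA) (mm) and sd.

    The shipped default coefficients are synthetic stand-ins fitted to the
    shape of published pediatric nomograms, not measurements from any
    proprietary database; replace them with institution-specific values for
    real use.
    """

    coefficients: dict              # name -> (a_mm, b_mm, sd_mm)
    bsa_range_m2: tuple = (0.5, 2.5)
    provenance: str = "synthetic default (a + b*sqrt(BSA) nomogram shape)"

    def __post_init__(self):
        for name, (a, b, sd) in self.coefficients.items():
            if sd <= 0:
                raise ValueError(f"sd must be positive ({name})")
            lo, hi = self.bsa_range_m2
            if a + b * np.sqrt(lo) <= 0 or a + b * np.sqrt(hi) <= 0:
                raise ValueError(f"mean diameter not positive over BSA range ({name})")

    def entry(self, landmark: str):
        key = NORMATIVE_ALIASES.get(landmark, landmark)
        if key not in self.coefficients:
            raise KeyError(f"no normative entry for landmark {landmark!r}")
        return self.coefficients[key]

    def mean_diameter_mm(self, landmark: str, bsa_m2: float) -> float:
        a, b, _ = self.entry(landmark)
        return a + b * np.sqrt(bsa_m2)

    def sd_mm(self, landmark: str) -> float:
        return self.entry(landmark)[2]


def default_normative_model() -> NormativeModel:
    """Synthetic pediatric-nomogram-shaped defaults (see NormativeModel)."""
    return NormativeModel(coefficients={
        "Root":        (12.0, 18.0, 2.2),
        "STJ":         (10.0, 16.0, 2.0),
        "midAAo":      (8.0, 16.0, 2.0),
        "dAAo":        (7.0, 15.0, 1.9),
        "distal_arch": (6.0, 14.0, 1.8),
        "isthmus":     (5.0, 13.0, 1.7),
        "midDAo":      (4.0, 12.0, 1.6),
        "dDAo":        (3.0, 11.0, 1.5),
    })


@dataclass
class DiameterRecord:
    landmark: str
    diameter_mm: float
    z_score: float
    dilated: bool

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")
        assert self.dilated == (self.z_score >= 2.0)


# ---------------------------------------------------------------------------
# centerline extraction


def _lumen_adjacency(vol: np.ndarray, spacing: np.ndarray):
    """26-connected sparse adjacency over the foreground voxels.

    Returns (coords, csr_distances) with edge weights in mm.
    """
    from scipy.sparse import coo_matrix

    coords = np.argwhere(vol)
    n = coords.shape[0]
    idx_vol = -np.ones(vol.shape, dtype=np.int64)
    idx_vol[tuple(coords.T)] = np.arange(n)
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) > (0, 0, 0)]
    rows, cols, dists = [], [], []
    for off in offsets:
        sa = tuple(slice(max(0, -o), vol.shape[d] - max(0, o))
                   for d, o in enumerate(off))
        sb = tuple(slice(max(0, o), vol.shape[d] - max(0, -o))
                   for d, o in enumerate(off))
        ia = idx_vol[sa].ravel()
        ib = idx_vol[sb].ravel()
        ok = (ia >= 0) & (ib >= 0)
        rows.append(ia[ok])
        cols.append(ib[ok])
        dists.append(np.full(ok.sum(), np.linalg.norm(np.asarray(off) * spacing)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    dists = np.concatenate(dists)
    adj = coo_matrix((np.concatenate([dists, dists]),
                      (np.concatenate([rows, cols]),
                       np.concatenate([cols, rows]))), shape=(n, n))
    return coords, adj.tocsr()


def _medial_path(mask: LumenMask):
    """Ordered voxel path along the ridge of the interior distance transform.

    The two geodesically farthest lumen voxels are found by a double Dijkstra
    sweep; the path between them is then recomputed with edge costs inversely
    weighted by the squared wall distance, which pins it to the medial ridge.
    Raises if part of the lumen lies far from the path (a side branch).
    """
    from scipy.sparse.csgraph import dijkstra

    vol = mask.volume
    spacing = np.asarray(mask.spacing_mm)
    edt = ndimage.distance_transform_edt(vol, sampling=spacing)
    coords, adj = _lumen_adjacency(vol, spacing)
    n = coords.shape[0]
    if n < 10:
        raise ValueError("lumen too small for centerline extraction")

    start = int(np.argmax(edt[tuple(coords.T)]))
    d0 = dijkstra(adj, indices=start)
    e1 = int(np.nanargmax(np.where(np.isfinite(d0), d0, np.nan)))
    d1 = dijkstra(adj, indices=e1)
    e2 = int(np.nanargmax(np.where(np.isfinite(d1), d1, np.nan)))

    # the geodesically farthest voxels sit on the rim of the end faces; snap
    # each endpoint to the deepest (max wall distance) voxel nearby so the
    # path starts and ends on the medial ridge
    edt_nodes_all = edt[tuple(coords.T)]
    d2 = dijkstra(adj, indices=e2)
    # score trades wall depth against distance walked from the end, so the
    # nearest on-axis voxel wins over deeper voxels far along the vessel
    e1 = int(np.argmax(edt_nodes_all - 0.5 * d1))
    e2 = int(np.argmax(edt_nodes_all - 0.5 * d2))

    # medial weighting: cost ~ step / wall-distance^2
    edt_nodes = edt[tuple(coords.T)]
    medial = adj.copy()
    r_pair = 0.5 * (edt_nodes[medial.nonzero()[0]] + edt_nodes[medial.nonzero()[1]])
    medial.data = medial.data / np.maximum(r_pair, 0.25 * spacing.min()) ** 2
    _, pred = dijkstra(medial, indices=e1, return_predecessors=True)
    path = [e2]
    while path[-1] != e1:
        nxt = pred[path[-1]]
        if nxt < 0:
            raise ValueError("lumen is disconnected")
        path.append(int(nxt))
    path_coords = coords[path[::-1]]

    # branch check: every lumen voxel must lie within its local radius scale
    # of the path; a side branch leaves uncovered voxels far from it
    path_mm = mask.voxel_to_mm(path_coords)
    tree = cKDTree(path_mm)
    d2path, _ = tree.query(mask.voxel_to_mm(coords))
    limit = 2.0 * float(edt.max()) + float(spacing.max())
    if d2path.max() > limit:
        raise ValueError("lumen not covered by a single centerline path "
                         "(branching vessel?)")
    return path_coords


def extract_centerline(mask: LumenMask, inlet_hint_mm=None,
                       step_mm: float = 2.0, smooth_mm: float = 1.0) -> CenterlineModel:
    """Centerline as the smoothed, ordered medial ridge of the lumen.

    The ridge path of the interior distance transform is ordered between the
    two geodesically farthest lumen voxels, fitted with a smoothing spline
    and resampled at ``step_mm``.  The best-fit (least squares) plane of the
    points defines the arch plane.
    """
    path_vox = _medial_path(mask)
    pts = mask.voxel_to_mm(path_vox)

    if inlet_hint_mm is not None:
        hint = np.asarray(inlet_hint_mm, dtype=float)
        if (np.linalg.norm(pts[-1] - hint) < np.linalg.norm(pts[0] - hint)):
            pts = pts[::-1]
    # smoothing spline; s scales with expected half-voxel jitter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tck, _ = splprep(pts.T, s=pts.shape[0] * smooth_mm ** 2, k=3)
    n_out = max(int(np.ceil(_polyline_length(pts) / step_mm)) + 1, 8)
    u = np.linspace(0.0, 1.0, n_out)
    smooth_pts = np.stack(splev(u, tck), axis=1)
    deriv = np.stack(splev(u, tck, der=1), axis=1)
    tangents = deriv / np.linalg.norm(deriv, axis=1)[:, None]
    seglen = np.linalg.norm(np.diff(smooth_pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])

    centroid = smooth_pts.mean(axis=0)
    _, _, vt = np.linalg.svd(smooth_pts - centroid, full_matrices=False)
    normal = vt[-1]
    return CenterlineModel(points_mm=smooth_pts, tangents=tangents,
                           arc_length_mm=arc, arch_plane_point=centroid,
                           arch_plane_normal=normal)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def centerline_from_points(points_mm: np.ndarray, landmarks: dict | None = None
                           ) -> CenterlineModel:
    """Build a CenterlineModel from known (e.g. analytic) centerline samples."""
    pts = np.asarray(points_mm, dtype=float)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    tangents = np.gradient(pts, arc, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    model = CenterlineModel(points_mm=pts, tangents=tangents, arc_length_mm=arc,
                            arch_plane_point=centroid, arch_plane_normal=vt[-1])
    if landmarks:
        model.set_landmarks_by_fraction(landmarks)
    return model


# ---------------------------------------------------------------------------
# diameters


def measure_diameter(mask: LumenMask, centerline: CenterlineModel,
                     landmark: str | float, upsample: int = 4,
                     extent_mm: float = 60.0) -> float:
    """Maximal caliper (Feret) diameter of the lumen cross-section at a
    landmark, in the plane orthogonal to the centerline tangent.

    ``landmark`` is a name registered on the centerline or an arc position in
    mm.  The cross-section is rasterized at ``upsample`` times the finest
    in-plane voxel size to stabilize the caliper measure.
    """
    if isinstance(landmark, str):
        if landmark not in centerline.landmarks:
            raise KeyError(f"landmark {landmark!r} not defined on centerline")
        s_mm = centerline.landmarks[landmark]
    else:
        s_mm = float(landmark)
    center, tangent = centerline.at(s_mm)

    b1 = np.array([0.0, 0.0, 1.0])
    if abs(tangent @ b1) > 0.9:
        b1 = np.array([0.0, 1.0, 0.0])
    b1 = b1 - (b1 @ tangent) * tangent
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(tangent, b1)

    px = float(np.min(mask.spacing_mm)) / upsample
    n = int(np.ceil(extent_mm / px)) | 1
    u = (np.arange(n) - n // 2) * px
    uu, vv = np.meshgrid(u, u, indexing="ij")
    plane_pts = (center[None, None, :] + uu[..., None] * b1[None, None, :]
                 + vv[..., None] * b2[None, None, :])
    vox = mask.mm_to_voxel(plane_pts.reshape(-1, 3))
    section = ndimage.map_coordinates(mask.volume.astype(np.float32), vox.T,
                                      order=1, mode="constant")
    section = (section >= 0.5).reshape(n, n)
    if not section.any():
        raise ValueError("empty cross-section at landmark")

    labels, _ = ndimage.label(section)
    center_px = (n // 2, n // 2)
    lab = labels[center_px]
    if lab == 0:
        # fall back to the component nearest the plane center
        fg = np.argwhere(labels > 0)
        d2 = ((fg - np.array(center_px)) ** 2).sum(axis=1)
        lab = labels[tuple(fg[np.argmin(d2)])]
    comp = labels == lab
    pix = np.argwhere(comp).astype(float) * px
    if pix.shape[0] < 3:
        return float(np.ptp(pix, axis=0).max())
    hull = ConvexHull(pix)
    hp = pix[hull.vertices]
    d = np.linalg.norm(hp[:, None, :] - hp[None, :, :], axis=2)
    return float(d.max())


def percent_diameter_change(d_proximal_mm: float, d_distal_mm: float) -> float:
    """|d_prox - d_dist| / d_prox * 100, the clinical segment size-change."""
    if d_proximal_mm <= 0:
        raise ValueError("proximal diameter must be positive")
    return abs(d_proximal_mm - d_distal_mm) / d_proximal_mm * 100.0


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Mosteller body surface area, sqrt(height*weight/3600), m^2."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def aortic_zscore(diameter_mm: float, bsa_m2: float, landmark: str,
                  model: NormativeModel) -> DiameterRecord:
    """BSA-indexed Z-score; z >= 2.0 (boundary inclusive) classifies dilated."""
    lo, hi = model.bsa_range_m2
    if not (lo <= bsa_m2 <= hi):
        warnings.warn(f"BSA {bsa_m2:.2f} m^2 outside normative validity "
                      f"range [{lo}, {hi}]", stacklevel=2)
    mean = model.mean_diameter_mm(landmark, bsa_m2)
    z = (diameter_mm - mean) / model.sd_mm(landmark)
    return DiameterRecord(landmark=landmark, diameter_mm=diameter_mm,
                          z_score=float(z), dilated=bool(z >= 2.0))


def assign_subgroup(records: dict, control: bool = False) -> str:
    """Subject subgroup from the proximal-descending-aorta Z-score.

    Returns 'control', 'pDAo_dilated' (z >= 2.0) or 'pDAo_nondilated'.
    """
    if control:
        return "control"
    if "pDAo" not in records:
        raise KeyError("pDAo diameter record required for subgrouping")
    rec = records["pDAo"]
    return "pDAo_dilated" if rec.dilated else "pDAo_nondilated"
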