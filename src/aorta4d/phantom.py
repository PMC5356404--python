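"""Synthetic 4D-flow phantoms with analytic ground truth.

Generates time-resolved three-component velocity volumes on straight-tube and
candy-cane (aorta-like) geometries.  The velocity field is imposed
analytically -- an axial parabolic (Poiseuille-shaped) profile with no-slip at
the wall, optionally decorated with a helical swirl component or localized
recirculation pockets -- so that wall shear stress, cumulative pathline
rotation and lumen diameters are known in closed form.  Controlled
degradations (Gaussian velocity noise, first-order eddy-current offsets,
velocity-encoding wrap-around, a static-tissue shell) emulate the artifacts
a phase-contrast acquisition produces and that the preprocessing module must
remove.

Units throughout: positions mm, velocities cm/s, time ms, shear stress Pa.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

#: convert cm/s to mm/ms
CM_S_TO_MM_MS = 0.01

#: default dynamic blood viscosity, Pa*s (standard 4D-flow assumption)
DEFAULT_VISCOSITY_PA_S = 3.2e-3

DEFAULT_TUBE_LANDMARKS = {
    "isthmus": 0.35,
    "pDAo": 0.50,
    "midDAo": 0.75,
}

DEFAULT_CANDY_CANE_LANDMARKS = {
    "Root": 0.02,
    "STJ": 0.05,
    "midAAo": 0.15,
    "dAAo": 0.24,
    "distal_arch": 0.45,
    "isthmus": 0.67,
    "pDAo": 0.75,
    "midDAo": 0.85,
    "dDAo": 0.97,
}


def default_waveform(n_frames: int = 20, peak: int = 5, half_width: int = 3,
                     baseline: float = 0.1) -> np.ndarray:
    """Raised-cosine systolic bump over frames peak-hw..peak+hw on a diastolic
    baseline.  Single maximum at ``peak`` with value 1.0."""
    t = np.arange(n_frames, dtype=float)
    w = np.full(n_frames, baseline)
    inside = np.abs(t - peak) <= half_width
    w[inside] = baseline + (1.0 - baseline) * 0.5 * (
        1.0 + np.cos(np.pi * (t[inside] - peak) / half_width))
    return w


def bulge_radius_profile(base_mm: float, extra_mm: float, center_mm: float,
                         sigma_mm: float = 8.0) -> Callable[[np.ndarray], np.ndarray]:
    """Radius profile with a Gaussian dilation (a "dilated pDAo"-like bulge)."""
    def profile(s):
        s = np.asarray(s, dtype=float)
        return base_mm + extra_mm * np.exp(-0.5 * ((s - center_mm) / sigma_mm) ** 2)
    profile.base_mm = base_mm  # type: ignore[attr-defined]
    return profile


# ---------------------------------------------------------------------------
# geometry kernels


class TubeGeometry:
    """Straight tube along an arbitrary axis."""

    def __init__(self, length_mm: float, axis=(1.0, 0.0, 0.0), start_mm=(0.0, 0.0, 0.0)):
        self.length_mm = float(length_mm)
        self.axis = np.asarray(axis, dtype=float)
        self.axis /= np.linalg.norm(self.axis)
        self.start_mm = np.asarray(start_mm, dtype=float)

    @property
    def total_length_mm(self) -> float:
        return self.length_mm

    def centerline_points(self, step_mm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        s = np.arange(0.0, self.length_mm + 0.5 * step_mm, step_mm)
        pts = self.start_mm[None, :] + s[:, None] * self.axis[None, :]
        return s, pts

    def locate(self, pts: np.ndarray):
        rel = pts - self.start_mm
        s_raw = rel @ self.axis
        radial = rel - s_raw[:, None] * self.axis[None, :]
        r = np.linalg.norm(radial, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            radial_unit = np.where(r[:, None] > 1e-12, radial / np.maximum(r, 1e-12)[:, None], 0.0)
        tangent = np.broadcast_to(self.axis, pts.shape).copy()
        inside_axis = (s_raw >= 0.0) & (s_raw <= self.length_mm)
        s = np.clip(s_raw, 0.0, self.length_mm)
        return s, r, tangent, radial_unit, inside_axis


class CandyCaneGeometry:
    """Two straight limbs joined by a half-torus arch, all centerline points in
    the y = 0 plane.  That plane is the reference "arch plane" used downstream
    for the inner/outer wall split."""

    def __init__(self, limb1_mm: float = 60.0, arch_radius_mm: float = 30.0,
                 limb2_mm: float = 80.0):
        self.limb1_mm = float(limb1_mm)
        self.arch_radius_mm = float(arch_radius_mm)
        self.limb2_mm = float(limb2_mm)
        self.center = np.array([arch_radius_mm, 0.0, limb1_mm])

    @property
    def arch_length_mm(self) -> float:
        return np.pi * self.arch_radius_mm

    @property
    def total_length_mm(self) -> float:
        return self.limb1_mm + self.arch_length_mm + self.limb2_mm

    def centerline_points(self, step_mm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        s = np.arange(0.0, self.total_length_mm + 0.5 * step_mm, step_mm)
        pts = np.empty((s.size, 3))
        L1, Ra = self.limb1_mm, self.arch_radius_mm
        a = s <= L1
        pts[a] = np.stack([np.zeros(a.sum()), np.zeros(a.sum()), s[a]], axis=1)
        b = (s > L1) & (s <= L1 + self.arch_length_mm)
        phi = (s[b] - L1) / Ra
        pts[b] = self.center[None, :] + Ra * np.stack(
            [-np.cos(phi), np.zeros(phi.size), np.sin(phi)], axis=1)
        c = s > L1 + self.arch_length_mm
        t = s[c] - L1 - self.arch_length_mm
        pts[c] = np.stack([np.full(t.size, 2 * Ra), np.zeros(t.size), L1 - t], axis=1)
        return s, pts

    def locate(self, pts: np.ndarray):
        L1, Ra, L2 = self.limb1_mm, self.arch_radius_mm, self.limb2_mm
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        n = pts.shape[0]

        # candidate A: ascending limb, axis x=y=0, z in [0, L1]
        tA = np.clip(z, 0.0, L1)
        dA = np.sqrt(x ** 2 + y ** 2 + (z - tA) ** 2)
        # candidate B: arch, half circle in the y=0 plane
        phi = np.arctan2(z - L1, -(x - Ra))
        phi_c = np.clip(phi, 0.0, np.pi)
        nearB = self.center[None, :] + Ra * np.stack(
            [-np.cos(phi_c), np.zeros(n), np.sin(phi_c)], axis=1)
        dB = np.linalg.norm(pts - nearB, axis=1)
        # candidate C: descending limb, axis x=2Ra, y=0, z in [L1-L2, L1]
        tC = np.clip(z, L1 - L2, L1)
        dC = np.sqrt((x - 2 * Ra) ** 2 + y ** 2 + (z - tC) ** 2)

        d = np.stack([dA, dB, dC], axis=0)
        which = np.argmin(d, axis=0)
        r = d[which, np.arange(n)]

        s = np.empty(n)
        tangent = np.empty((n, 3))
        nearest = np.empty((n, 3))
        inside_axis = np.empty(n, dtype=bool)

        mA = which == 0
        s[mA] = tA[mA]
        tangent[mA] = [0.0, 0.0, 1.0]
        nearest[mA] = np.stack([np.zeros(mA.sum()), np.zeros(mA.sum()), tA[mA]], axis=1)
        inside_axis[mA] = (z[mA] >= 0.0) & (z[mA] <= L1)

        mB = which == 1
        s[mB] = L1 + Ra * phi_c[mB]
        tangent[mB] = np.stack(
            [np.sin(phi_c[mB]), np.zeros(mB.sum()), np.cos(phi_c[mB])], axis=1)
        nearest[mB] = nearB[mB]
        inside_axis[mB] = (phi[mB] >= 0.0) & (phi[mB] <= np.pi)

        mC = which == 2
        s[mC] = L1 + self.arch_length_mm + (L1 - tC[mC])
        tangent[mC] = [0.0, 0.0, -1.0]
        nearest[mC] = np.stack(
            [np.full(mC.sum(), 2 * Ra), np.zeros(mC.sum()), tC[mC]], axis=1)
        inside_axis[mC] = (z[mC] <= L1) & (z[mC] >= L1 - L2)

        radial = pts - nearest
        with np.errstate(invalid="ignore", divide="ignore"):
            radial_unit = np.where(r[:, None] > 1e-12, radial / np.maximum(r, 1e-12)[:, None], 0.0)
        return s, r, tangent, radial_unit, inside_axis


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PhantomSpec:
    """Parameters of a synthetic acquisition.

    Defaults emulate the mid-range of a pediatric thoracic 4D-flow protocol:
    spacing (2.4, 1.8, 2.4) mm, 40 ms frame interval and a 150 cm/s velocity
    encoding limit, with 20 cardiac frames and a 100 cm/s peak centerline
    speed.
    """

    geometry_kind: str = "candy_cane"  # or "straight_tube"
    radius_mm: float | Callable[[np.ndarray], np.ndarray] = 10.0
    length_mm: float = 140.0                # straight tube only
    axis: tuple = (1.0, 0.0, 0.0)           # straight tube only
    limb1_mm: float = 60.0                  # candy cane only
    arch_radius_mm: float = 30.0
    limb2_mm: float = 80.0
    spacing_mm: tuple = (2.4, 1.8, 2.4)
    n_frames: int = 20
    frame_interval_ms: float = 40.0
    waveform: Optional[np.ndarray] = None   # per-frame scale in [0, 1]
    v_peak_cm_s: float = 100.0
    swirl_deg_per_cm: float = 0.0
    vortex_pockets: Sequence[tuple] = ()    # (s_mm, pocket_radius_mm, peak_reversed_cm_s)
    venc_cm_s: float = 150.0
    snr: float = np.inf
    eddy_coeffs: tuple = (0.0, 0.0, 0.0, 0.0)
    wrap: bool = False
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S
    shell_voxels: int = 3
    pad_voxels: int = 2
    landmarks: Optional[dict] = None        # name -> arc-length fraction
    seed: int = 0


@dataclass
class VelocityField4D:
    """Time-resolved three-component velocity volume plus magnitude images.

    ``velocity`` has shape (n_frames, 3, nx, ny, nz) in cm/s; ``magnitude``
    (n_frames, nx, ny, nz), arbitrary units, higher inside the lumen.
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    spacing_mm: tuple
    frame_interval_ms: float
    venc_cm_s: float
    origin_mm: tuple = (0.0, 0.0, 0.0)

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.velocity.shape[2:]

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) physical coordinates of all voxel centers, C order."""
        axes = [self.origin_mm[i] + self.spacing_mm[i] * np.arange(self.grid_shape[i])
                for i in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(self.velocity.copy(), self.magnitude.copy(),
                               tuple(self.spacing_mm), self.frame_interval_ms,
                               self.venc_cm_s, tuple(self.origin_mm))


@dataclass
class PhantomTruth:
    """Analytic sidecar carrying ground truth for the imposed field."""

    true_mask: np.ndarray
    static_mask: np.ndarray
    peak_frame_index: int
    true_centerline_s_mm: np.ndarray
    true_centerline_points_mm: np.ndarray
    radius_mm: np.ndarray               # lumen radius per centerline sample
    true_wss_peak_pa: np.ndarray        # analytic WSS at the peak frame
    true_wss_pa: np.ndarray             # systolic (peak +/- 2) mean WSS
    true_diameters_mm: dict
    true_rotation_deg: float = 0.0      # imposed helix rotation over full length
    rotation_deg_per_cm: float = 0.0
    vortex_cores: list = field(default_factory=list)
    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S
    spec: Optional[PhantomSpec] = None
    geometry: object = field(default=None, repr=False)

    def rotation_over(self, s0_mm: float, s1_mm: float) -> float:
        """Imposed helical rotation (deg) accumulated between two arc positions."""
        return self.rotation_deg_per_cm * (s1_mm - s0_mm) / 10.0

    def wss_at(self, s_mm) -> np.ndarray:
        """Interpolate the analytic systolic-mean WSS at arc position(s)."""
        return np.interp(np.asarray(s_mm, dtype=float),
                         self.true_centerline_s_mm, self.true_wss_pa)


# ---------------------------------------------------------------------------
# construction


def _build_geometry(spec: PhantomSpec):
    if spec.geometry_kind == "straight_tube":
        return TubeGeometry(spec.length_mm, axis=spec.axis)
    if spec.geometry_kind == "candy_cane":
        return CandyCaneGeometry(spec.limb1_mm, spec.arch_radius_mm, spec.limb2_mm)
    raise ValueError(f"unknown geometry_kind {spec.geometry_kind!r}")


def _radius_fn(spec: PhantomSpec) -> Callable[[np.ndarray], np.ndarray]:
    if callable(spec.radius_mm):
        return spec.radius_mm
    base = float(spec.radius_mm)
    def profile(s):
        return np.full_like(np.asarray(s, dtype=float), base)
    profile.base_mm = base  # type: ignore[attr-defined]
    return profile


def _reference_radius(radius_fn) -> float:
    return float(getattr(radius_fn, "base_mm", radius_fn(np.zeros(1))[0]))


def make_phantom(spec: PhantomSpec) -> tuple[VelocityField4D, PhantomTruth]:
    """Generate the clean phantom field and its analytic truth sidecar.

    The axial profile at every cross-section is parabolic with no-slip at the
    wall; where the radius profile varies, the centerline speed is rescaled by
    (R_ref/R)^2 so the volumetric flow rate is conserved along the vessel.
    Ground-truth wall shear stress follows from the imposed wall gradient:
    tau(s, t) = 2 * mu * v_center(s) * w(t) / R(s).
    """
    if spec.n_frames < 5:
        raise ValueError("n_frames must be >= 5 (systolic averaging needs peak +/- 2)")
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing_mm must be positive")

    geom = _build_geometry(spec)
    radius_fn = _radius_fn(spec)
    r_ref = _reference_radius(radius_fn)
    s_probe = np.linspace(0.0, geom.total_length_mm, 512)
    radii = radius_fn(s_probe)
    if np.any(radii <= 0):
        raise ValueError("radius profile must be positive everywhere")
    if np.max(spacing) > np.min(radii):
        raise ValueError("voxel spacing larger than the lumen radius: unresolvable")

    waveform = spec.waveform if spec.waveform is not None else default_waveform(spec.n_frames)
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size != spec.n_frames:
        raise ValueError("waveform length must equal n_frames")
    peaks = np.flatnonzero(waveform == waveform.max())
    if peaks.size != 1:
        raise ValueError("waveform must have exactly one maximum")
    peak_frame = int(peaks[0])

    # volume bounds: bounding box of the centerline +/- (max radius + shell + pad)
    _, cl_pts = geom.centerline_points(step_mm=max(1.0, geom.total_length_mm / 512))
    margin = float(np.max(radii)) + (spec.shell_voxels + spec.pad_voxels) * spacing
    lo = cl_pts.min(axis=0) - margin
    hi = cl_pts.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing[i])) + 1 for i in range(3))
    origin = tuple(lo)

    field4d = VelocityField4D(
        velocity=np.zeros((spec.n_frames, 3) + shape, dtype=np.float32),
        magnitude=np.zeros((spec.n_frames,) + shape, dtype=np.float32),
        spacing_mm=tuple(spacing), frame_interval_ms=spec.frame_interval_ms,
        venc_cm_s=spec.venc_cm_s, origin_mm=origin)

    pts = field4d.voxel_centers()
    s, r, tangent, radial_unit, inside_axis = geom.locate(pts)
    R = radius_fn(s)
    lumen_flat = inside_axis & (r < R)
    scale = (r_ref / R) ** 2          # flow-rate conservation along the vessel
    profile = np.where(lumen_flat,
                       spec.v_peak_cm_s * scale * (1.0 - (r / R) ** 2), 0.0)

    for t in range(spec.n_frames):
        v = (waveform[t] * profile)[:, None] * tangent       # (N, 3)
        field4d.velocity[t] = v.T.reshape((3,) + shape).astype(np.float32)

    lumen = lumen_flat.reshape(shape)
    shell = binary_dilation(lumen, iterations=spec.shell_voxels) & ~lumen
    mag = (lumen | shell).astype(np.float32)
    field4d.magnitude[:] = mag[None]

    # analytic truth along the centerline
    step = max(0.5, float(np.min(spacing)) / 2.0)
    s_c, pts_c = geom.centerline_points(step_mm=step)
    R_c = radius_fn(s_c)
    scale_c = (r_ref / R_c) ** 2
    # wall gradient of the axial profile: 2 * v_center / R; cm/s per mm -> 10 s^-1
    tau_per_w = spec.viscosity_pa_s * 10.0 * 2.0 * spec.v_peak_cm_s * scale_c / R_c
    sys_frames = np.arange(peak_frame - 2, peak_frame + 3)
    sys_frames = sys_frames[(sys_frames >= 0) & (sys_frames < spec.n_frames)]
    w_sys = waveform[sys_frames].mean()

    landmarks = spec.landmarks
    if landmarks is None:
        landmarks = (DEFAULT_TUBE_LANDMARKS if spec.geometry_kind == "straight_tube"
                     else DEFAULT_CANDY_CANE_LANDMARKS)
    diam = {name: float(2.0 * radius_fn(np.array([frac * geom.total_length_mm]))[0])
            for name, frac in landmarks.items()}

    truth = PhantomTruth(
        true_mask=lumen, static_mask=shell, peak_frame_index=peak_frame,
        true_centerline_s_mm=s_c, true_centerline_points_mm=pts_c,
        radius_mm=np.asarray(R_c, dtype=float),
        true_wss_peak_pa=tau_per_w * waveform[peak_frame],
        true_wss_pa=tau_per_w * w_sys,
        true_diameters_mm=diam, viscosity_pa_s=spec.viscosity_pa_s,
        spec=spec, geometry=geom)
    return field4d, truth


def add_swirl(field4d: VelocityField4D, truth: PhantomTruth,
              swirl_deg_per_cm: float) -> tuple[VelocityField4D, PhantomTruth]:
    """Superimpose a helical in-plane component.

    The tangential speed v_theta = k * r * v_axial (k in rad/mm) makes the
    rotation rate per unit *advected distance* uniform across the lumen:
    d(theta)/ds = k for every particle, so a pathline accumulates exactly
    ``swirl_deg_per_cm`` degrees per centimeter travelled, independent of its
    radial position.
    """
    if swirl_deg_per_cm == 0.0:
        return field4d, truth
    geom = truth.geometry
    pts = field4d.voxel_centers()
    s, r, tangent, radial_unit, _ = geom.locate(pts)
    theta_hat = np.cross(tangent, radial_unit)
    k_rad_per_mm = np.deg2rad(swirl_deg_per_cm) / 10.0
    shape = field4d.grid_shape
    for t in range(field4d.n_frames):
        v = field4d.velocity[t].reshape(3, -1).T        # (N, 3) cm/s
        v_ax = np.einsum("ij,ij->i", v, tangent)
        v_theta = k_rad_per_mm * r * v_ax
        v = v + v_theta[:, None] * theta_hat
        field4d.velocity[t] = v.T.reshape((3,) + shape).astype(np.float32)
    out = dataclasses.replace(
        truth,
        rotation_deg_per_cm=truth.rotation_deg_per_cm + swirl_deg_per_cm)
    out.true_rotation_deg = out.rotation_deg_per_cm * geom.total_length_mm / 10.0
    return field4d, out


def omega_for_rotation(rotation_deg: float, duration_ms: float) -> float:
    """Angular rate (rad/s) producing ``rotation_deg`` over ``duration_ms``."""
    return np.deg2rad(rotation_deg) / (duration_ms / 1000.0)


def add_vortex_pocket(field4d: VelocityField4D, truth: PhantomTruth,
                      position_mm: float, pocket_radius_mm: float,
                      peak_reversed_cm_s: float,
                      radial_offset_mm: float = 0.0) -> tuple[VelocityField4D, PhantomTruth]:
    """Superimpose a localized recirculation pocket.

    A solid-body rotation about an axis perpendicular to the local bulk-flow
    direction is blended into the field: inside the core radius ``a`` the bulk
    flow is fully replaced by the rotation (closed in-plane streamlines,
    retrograde velocity on one side of the core), with a smooth decay to the
    undisturbed field at 2a.  A particle seeded at core distance d < a
    revolves at the constant angular rate omega = 10 * peak_reversed / a
    (rad/s), so the imposed revolve angle over any time window is exact.
    """
    if peak_reversed_cm_s == 0.0:
        return field4d, truth
    geom = truth.geometry
    a = float(pocket_radius_mm)
    s0 = float(position_mm)

    step = 0.5
    s_c, pts_c = geom.centerline_points(step_mm=step)
    idx = int(np.argmin(np.abs(s_c - s0)))
    c_pt = pts_c[idx]
    s_arr = np.array([s_c[idx]])
    _, _, tan, _, _ = geom.locate(c_pt[None, :] + 1e-9)
    tangent = tan[0]

    # offset direction: in-plane unit vector toward the centerline centroid
    centroid = pts_c.mean(axis=0)
    d_vec = centroid - c_pt
    d_vec -= (d_vec @ tangent) * tangent
    if np.linalg.norm(d_vec) < 1e-6:
        d_vec = np.cross(tangent, [0.0, 0.0, 1.0])
        if np.linalg.norm(d_vec) < 1e-6:
            d_vec = np.cross(tangent, [0.0, 1.0, 0.0])
    offset_dir = d_vec / np.linalg.norm(d_vec)
    core = c_pt + radial_offset_mm * offset_dir

    radius_fn = _radius_fn(truth.spec)
    R_here = float(radius_fn(s_arr)[0])
    if abs(radial_offset_mm) + a > R_here:
        raise ValueError("vortex pocket extends outside the lumen")

    axis = np.cross(tangent, offset_dir)
    axis /= np.linalg.norm(axis)
    omega = 10.0 * peak_reversed_cm_s / a     # rad/s; omega*d [mm] = 0.1*omega*d cm/s

    pts = field4d.voxel_centers()
    rel = pts - core
    d = np.linalg.norm(rel, axis=1)
    beta = np.clip((d - a) / a, 0.0, 1.0)
    blend = 1.0 - (3 * beta ** 2 - 2 * beta ** 3)      # 1 inside a, 0 beyond 2a
    v_rot = 0.1 * omega * np.cross(np.broadcast_to(axis, rel.shape), rel)
    shape = field4d.grid_shape
    for t in range(field4d.n_frames):
        v = field4d.velocity[t].reshape(3, -1).T
        v = (1.0 - blend)[:, None] * v + blend[:, None] * v_rot
        field4d.velocity[t] = v.T.reshape((3,) + shape).astype(np.float32)

    cycle_ms = field4d.n_frames * field4d.frame_interval_ms
    truth.vortex_cores.append({
        "core_mm": core, "axis": axis, "omega_rad_s": omega,
        "pocket_radius_mm": a, "s_mm": s0,
        "rotation_deg_full_cycle": np.rad2deg(omega * cycle_ms / 1000.0)})
    return field4d, truth


def degrade(field4d: VelocityField4D, truth: PhantomTruth, snr: float = np.inf,
            eddy_coeffs=(0.0, 0.0, 0.0, 0.0), wrap: bool = False,
            seed: Optional[int] = None) -> VelocityField4D:
    """Apply acquisition-like degradations (in order: eddy offset, noise, wrap).

    * eddy: a spatially linear velocity offset a0 + ax*x + ay*y + az*z (cm/s,
      physical mm coordinates) added everywhere, including the static shell;
    * noise: i.i.d. Gaussian, std = v_peak / snr per component;
    * wrap: components mapped into [-venc, venc) by modular wrapping.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive (or inf)")
    out = field4d.copy()
    a0, ax, ay, az = eddy_coeffs
    if any(c != 0.0 for c in eddy_coeffs):
        pts = field4d.voxel_centers()
        offset = (a0 + ax * pts[:, 0] + ay * pts[:, 1] + az * pts[:, 2]).reshape(
            field4d.grid_shape).astype(np.float32)
        out.velocity += offset[None, None]
    if np.isfinite(snr):
        rng = np.random.default_rng(truth.spec.seed if seed is None else seed)
        sigma = truth.spec.v_peak_cm_s / snr
        out.velocity += rng.normal(0.0, sigma, size=out.velocity.shape).astype(np.float32)
    if wrap:
        venc = field4d.venc_cm_s
        out.velocity = (np.mod(out.velocity + venc, 2.0 * venc) - venc).astype(np.float32)
    return out


def simulate(spec: PhantomSpec) -> tuple[VelocityField4D, VelocityField4D, PhantomTruth]:
    """Run the full generator: clean field, decorations, degradations.

    Returns (clean_field, degraded_field, truth)."""
    field4d, truth = make_phantom(spec)
    if spec.swirl_deg_per_cm:
        field4d, truth = add_swirl(field4d, truth, spec.swirl_deg_per_cm)
    for pocket in spec.vortex_pockets:
        field4d, truth = add_vortex_pocket(field4d, truth, *pocket)
    degraded = degrade(field4d, truth, snr=spec.snr,
                       eddy_coeffs=spec.eddy_coeffs, wrap=spec.wrap)
    return field4d, degraded, truth


# ---------------------------------------------------------------------------
# analytic wall mesh


def make_true_wall_mesh(truth: PhantomTruth, ds_mm: float = 2.0, n_theta: int = 48):
    """Triangulated wall surface at the exact analytic lumen boundary.

    Vertices lie at r = R(s) with exact inward (radial) normals; used to
    validate the WSS estimator independent of segmentation accuracy.
    Returns a ``segmentation.WallMesh``.
    """
    from .segmentation import WallMesh, compute_vertex_areas

    geom = truth.geometry
    spec = truth.spec
    radius_fn = _radius_fn(spec)
    total = geom.total_length_mm
    # keep one ring off each end so no vertex sits on the open faces
    s_rings = np.arange(ds_mm, total - 0.5 * ds_mm, ds_mm)
    s_cl, cl = geom.centerline_points(step_mm=0.5)

    ring_pts = np.empty((s_rings.size, 3))
    ring_tan = np.empty((s_rings.size, 3))
    for i, sv in enumerate(s_rings):
        j = int(np.argmin(np.abs(s_cl - sv)))
        ring_pts[i] = cl[j]
        _, _, tan, _, _ = geom.locate(cl[j][None, :] + 1e-9)
        ring_tan[i] = tan[0]

    R_rings = radius_fn(s_rings)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)

    verts = np.empty((s_rings.size * n_theta, 3))
    normals = np.empty_like(verts)
    arc = np.empty(s_rings.size * n_theta)
    for i in range(s_rings.size):
        t = ring_tan[i]
        n1 = np.array([0.0, 1.0, 0.0])
        if abs(t @ n1) > 0.9:
            n1 = np.array([1.0, 0.0, 0.0])
        n1 = n1 - (n1 @ t) * t
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(t, n1)
        ring_dir = (np.cos(theta)[:, None] * n1[None, :] +
                    np.sin(theta)[:, None] * n2[None, :])
        sl = slice(i * n_theta, (i + 1) * n_theta)
        verts[sl] = ring_pts[i][None, :] + R_rings[i] * ring_dir
        normals[sl] = -ring_dir
        arc[sl] = s_rings[i]

    tris = []
    for i in range(s_rings.size - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            tris.append([a, b, c])
            tris.append([b, d, c])
    triangles = np.asarray(tris, dtype=np.int64)
    areas = compute_vertex_areas(verts, triangles)
    return WallMesh(vertices=verts, triangles=triangles,
                    inward_normals=normals, vertex_areas=areas)
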