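"""Velocity-field corrections and PC-MRA derivation.

Implements the standard preprocessing chain applied to phase-contrast
velocity data before any quantitative analysis: local median-based phase
unwrapping of velocity aliasing, first-order eddy-current offset removal
fitted on static tissue, masking of unreliable low-signal voxels, and the
angiogram-like PC-MRA volume used for lumen segmentation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .phantom import VelocityField4D


@dataclass
class CorrectionReport:
    n_voxels_unwrapped: int = 0
    eddy_coeffs_fit: np.ndarray | None = None   # (n_frames, 3, 4)
    noise_mask: np.ndarray | None = None
    iterations: int = 0
    notes: list = field(default_factory=list)


_CROSS = np.zeros((3, 3, 3), dtype=bool)
_CROSS[1, 1, :] = _CROSS[1, :, 1] = _CROSS[:, 1, 1] = True
_CROSS[1, 1, 1] = False   # 6-connected neighborhood, center excluded


def _shift_toward_reference(vol: np.ndarray, ref: np.ndarray, venc: float) -> int:
    """Shift voxels differing from ``ref`` by more than venc by whole wraps."""
    k = np.round((ref - vol) / (2.0 * venc))
    bad = (np.abs(vol - ref) > venc) & (k != 0)
    if np.any(bad):
        vol[bad] += 2.0 * venc * k[bad]
    return int(bad.sum())


def unwrap_velocity(field4d: VelocityField4D, max_iter: int = 10
                    ) -> tuple[VelocityField4D, CorrectionReport]:
    """Undo velocity aliasing by temporal, then spatial, median consistency.

    Because a wrap is a shift by an exact multiple of 2*venc, any correctly
    identified wrap is undone exactly.  Two references are used per component:

    1. temporal: the median over the three-frame window centered on each
       frame.  Aliasing is usually confined to the fastest (peak-systolic)
       frames, whose temporal neighbours then provide an uncorrupted
       reference even inside a large wrapped core.
    2. spatial: the median of the 6-connected neighborhood, iterated so that
       wrapped cores are peeled one voxel layer per iteration.

    In both passes a voxel is shifted by whole wraps (+/- 2*venc) toward the
    reference only when it differs from it by more than venc; consistent
    voxels are untouched, so the operation is idempotent.
    """
    venc = field4d.venc_cm_s
    out = field4d.copy()
    vel = out.velocity.astype(np.float64)
    total = 0
    iters = 0

    # temporal pass
    for _ in range(2):
        changed = 0
        for c in range(3):
            comp = vel[:, c]
            ref = median_filter(comp, size=(3, 1, 1, 1), mode="nearest")
            changed += _shift_toward_reference(comp, ref, venc)
        total += changed
        if changed == 0:
            break

    # spatial peeling
    for _ in range(max_iter):
        iters += 1
        changed = 0
        for t in range(vel.shape[0]):
            for c in range(3):
                vol = vel[t, c]
                med = median_filter(vol, footprint=_CROSS, mode="nearest")
                changed += _shift_toward_reference(vol, med, venc)
        total += changed
        if changed == 0:
            break
    else:
        raise RuntimeError(
            f"velocity unwrapping did not converge in {max_iter} iterations "
            f"({total} voxels shifted)")
    out.velocity = vel.astype(np.float32)
    return out, CorrectionReport(n_voxels_unwrapped=total, iterations=iters)


def correct_eddy(field4d: VelocityField4D, static_mask: np.ndarray
                 ) -> tuple[VelocityField4D, CorrectionReport]:
    """Remove a first-order (planar) background velocity offset.

    Per frame and component, a polynomial a0 + ax*x + ay*y + az*z (physical mm
    coordinates) is least-squares fitted to velocities inside ``static_mask``
    -- tissue that should be at rest -- and subtracted from the whole volume.
    Exact for any first-order offset on noiseless data.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    n_static = int(static_mask.sum())
    if n_static < 10:
        raise ValueError(f"static mask has only {n_static} voxels; fit underdetermined")

    out = field4d.copy()
    pts = field4d.voxel_centers()
    design_full = np.column_stack([np.ones(pts.shape[0]), pts])
    flat_static = static_mask.ravel()
    A = design_full[flat_static]
    coeffs = np.zeros((field4d.n_frames, 3, 4))
    shape = field4d.grid_shape
    for t in range(field4d.n_frames):
        for c in range(3):
            v = out.velocity[t, c].ravel().astype(np.float64)
            beta, *_ = np.linalg.lstsq(A, v[flat_static], rcond=None)
            coeffs[t, c] = beta
            v -= design_full @ beta
            out.velocity[t, c] = v.reshape(shape).astype(np.float32)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("eddy-current fit produced non-finite coefficients")
    return out, CorrectionReport(eddy_coeffs_fit=coeffs)


def compute_noise_mask(magnitude: np.ndarray, threshold_rel: float = 0.10) -> np.ndarray:
    """Mark voxels with reliable signal.

    A voxel is reliable if its time-averaged magnitude reaches
    ``threshold_rel`` of the 99th-percentile magnitude.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    avg = magnitude.mean(axis=0) if magnitude.ndim == 4 else magnitude
    if not np.any(avg > 0):
        raise ValueError("magnitude volume is all zero")
    ref = np.percentile(avg, 99)
    return avg >= threshold_rel * ref


def detect_peak_frame(field4d: VelocityField4D, mask: np.ndarray | None = None) -> int:
    """Frame maximizing the spatial mean speed (ties -> earliest frame)."""
    if mask is None:
        mask = compute_noise_mask(field4d.magnitude)
    mask = np.asarray(mask, dtype=bool)
    speed = np.linalg.norm(field4d.velocity, axis=1)        # (T, nx, ny, nz)
    mean_speed = speed[:, mask].mean(axis=1)
    return int(np.argmax(mean_speed))


def compute_pcmra(field4d: VelocityField4D, peak_frame: int | None = None) -> np.ndarray:
    """Pseudo complex-difference angiogram from corrected velocity data.

    Per voxel, the mean over the systolic window (peak frame +/- 2) of
    magnitude * speed.  Static tissue with zero velocity scores zero
    regardless of its signal magnitude, which is what segmentation needs.
    Invariant to a global sign flip of the velocities.
    """
    if peak_frame is None:
        peak_frame = detect_peak_frame(field4d)
    frames = np.arange(peak_frame - 2, peak_frame + 3)
    frames = frames[(frames >= 0) & (frames < field4d.n_frames)]
    speed = np.linalg.norm(field4d.velocity[frames].astype(np.float64), axis=1)
    return (field4d.magnitude[frames] * speed).mean(axis=0)
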