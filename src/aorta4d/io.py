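"""File I/O: NIfTI volumes, PLY meshes, CSV tables, YAML phantom specs."""
from __future__ import annotations

import pathlib
import re

import numpy as np
import pandas as pd
import yaml

from .phantom import PhantomSpec, VelocityField4D
from .segmentation import LumenMask, WallMesh, compute_vertex_areas


def _affine(spacing_mm, origin_mm):
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def save_field(field4d: VelocityField4D, out_dir) -> None:
    """Write velocity as a single 5-D NIfTI (x, y, z, t, component) plus a
    4-D magnitude volume and a small YAML header with the acquisition
    parameters."""
    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(field4d.spacing_mm, field4d.origin_mm)
    vel = np.moveaxis(field4d.velocity, (0, 1), (3, 4))     # (x,y,z,t,c)
    nib.save(nib.Nifti1Image(vel.astype(np.float32), aff), out / "velocity.nii")
    mag = np.moveaxis(field4d.magnitude, 0, 3)
    nib.save(nib.Nifti1Image(mag.astype(np.float32), aff), out / "magnitude.nii")
    header = {"frame_interval_ms": float(field4d.frame_interval_ms),
              "venc_cm_s": float(field4d.venc_cm_s)}
    (out / "field.yaml").write_text(yaml.safe_dump(header))


def load_field(in_dir) -> VelocityField4D:
    """Read a field written by :func:`save_field`, or the per-component
    per-frame dialect ``vel_f<frame>_c<comp>.nii``."""
    import nibabel as nib

    src = pathlib.Path(in_dir)
    header = yaml.safe_load((src / "field.yaml").read_text())
    mag_img = nib.load(src / "magnitude.nii")
    spacing = tuple(float(z) for z in mag_img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in mag_img.affine[:3, 3])
    magnitude = np.moveaxis(np.asarray(mag_img.dataobj, dtype=np.float32), 3, 0)

    if (src / "velocity.nii").exists():
        vel5 = np.asarray(nib.load(src / "velocity.nii").dataobj, dtype=np.float32)
        velocity = np.moveaxis(vel5, (3, 4), (0, 1))
    else:
        pat = re.compile(r"vel_f(\d+)_c(\d+)\.nii$")
        files = sorted(p for p in src.iterdir() if pat.search(p.name))
        if not files:
            raise FileNotFoundError("no velocity volumes found")
        n_frames = magnitude.shape[0]
        velocity = np.zeros((n_frames, 3) + magnitude.shape[1:], dtype=np.float32)
        for p in files:
            m = pat.search(p.name)
            velocity[int(m.group(1)), int(m.group(2))] = np.asarray(
                nib.load(p).dataobj, dtype=np.float32)
    return VelocityField4D(velocity=velocity, magnitude=magnitude,
                           spacing_mm=spacing,
                           frame_interval_ms=header["frame_interval_ms"],
                           venc_cm_s=header["venc_cm_s"], origin_mm=origin)


def save_mask(mask: LumenMask, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.volume.astype(np.uint8),
                             _affine(mask.spacing_mm, mask.origin_mm)), str(path))


def load_mask(path) -> LumenMask:
    import nibabel as nib

    img = nib.load(str(path))
    return LumenMask(volume=np.asarray(img.dataobj) > 0,
                     spacing_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
                     origin_mm=tuple(float(v) for v in img.affine[:3, 3]))


def save_mesh(mesh: WallMesh, path) -> None:
    """PLY (binary little-endian) with per-vertex inward-normal properties."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.vertex_normals = mesh.inward_normals
    tm.export(str(path))


def load_mesh(path) -> WallMesh:
    import trimesh

    tm = trimesh.load(str(path), process=False)
    verts = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    normals = np.asarray(tm.vertex_normals, dtype=float)
    return WallMesh(vertices=verts, triangles=faces, inward_normals=normals,
                    vertex_areas=compute_vertex_areas(verts, faces))


def save_pathlines_csv(pathlines, path) -> None:
    rows = []
    for i, pl in enumerate(pathlines):
        for t, p in zip(pl.t_ms, pl.positions_mm):
            rows.append({"id": i, "t_ms": t, "x": p[0], "y": p[1], "z": p[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_spec(path) -> PhantomSpec:
    """PhantomSpec from a key: value YAML config."""
    data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    for key in ("spacing_mm", "axis", "eddy_coeffs"):
        if key in data:
            data[key] = tuple(data[key])
    if "vortex_pockets" in data:
        data["vortex_pockets"] = [tuple(p) for p in data["vortex_pockets"]]
    if "waveform" in data and data["waveform"] is not None:
        data["waveform"] = np.asarray(data["waveform"], dtype=float)
    return PhantomSpec(**data)
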