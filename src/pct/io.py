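"""Readers and writers for list-mode proton data and RSP volumes.

Proton lists travel as CSV (human-readable, ~6 significant digits) or HDF5
(lossless), with the column/dataset names

    x_in,y_in,z_in,dx_in,dy_in,dz_in,
    x_out,y_out,z_out,dx_out,dy_out,dz_out,wepl_mm,angle_deg

in object-frame mm and degrees.  Volumes travel as NIfTI (isotropic voxel
size in the header) or raw little-endian float32 plus a JSON sidecar
``{shape, voxel_size_mm, origin_mm}``.  Formats are auto-detected by file
extension.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .grid import RSPVolume, VoxelGrid
from .simulate import ProtonList

__all__ = ["read_protons", "write_protons", "read_volume", "write_volume"]

_COLUMNS = [
    "x_in", "y_in", "z_in", "dx_in", "dy_in", "dz_in",
    "x_out", "y_out", "z_out", "dx_out", "dy_out", "dz_out",
    "wepl_mm", "angle_deg",
]


def _protons_to_frame(protons: ProtonList) -> pd.DataFrame:
    cols = {}
    for prefix, arr in (("_in", protons.p_in), ("_out", protons.p_out)):
        for ax, name in enumerate("xyz"):
            cols[f"{name}{prefix}"] = arr[:, ax]
    for prefix, arr in (("_in", protons.d_in), ("_out", protons.d_out)):
        for ax, name in enumerate("xyz"):
            cols[f"d{name}{prefix}"] = arr[:, ax]
    cols["wepl_mm"] = protons.wepl
    cols["angle_deg"] = protons.angle_deg
    return pd.DataFrame(cols)[_COLUMNS]


def _frame_to_protons(df: pd.DataFrame, source: str) -> ProtonList:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {', '.join(missing)}")
    wepl = df["wepl_mm"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(wepl))
    if bad.size:
        raise ValueError(f"{source}: non-finite wepl_mm at row {bad[0]}")
    stack = lambda names: np.stack([df[n].to_numpy(dtype=float) for n in names], axis=1)
    return ProtonList(
        p_in=stack(["x_in", "y_in", "z_in"]),
        d_in=stack(["dx_in", "dy_in", "dz_in"]),
        p_out=stack(["x_out", "y_out", "z_out"]),
        d_out=stack(["dx_out", "dy_out", "dz_out"]),
        wepl=wepl,
        angle_deg=df["angle_deg"].to_numpy(dtype=float),
    )


def write_protons(protons: ProtonList, path, attrs: dict | None = None) -> None:
    """Write a proton list; format chosen by extension (.csv or .h5/.hdf5)."""
    path = Path(path)
    if path.suffix == ".csv":
        _protons_to_frame(protons).to_csv(path, index=False)
    elif path.suffix in (".h5", ".hdf5"):
        df = _protons_to_frame(protons)
        with h5py.File(path, "w") as f:
            for col in _COLUMNS:
                f.create_dataset(col, data=df[col].to_numpy())
            if protons.wepl_true is not None:
                f.create_dataset("wepl_true_mm", data=protons.wepl_true)
            for key, val in (attrs or {}).items():
                f.attrs[key] = val
    else:
        raise ValueError(f"unsupported proton-list extension {path.suffix!r}")


def read_protons(path) -> ProtonList:
    """Read a proton list (CSV or HDF5, by extension)."""
    path = Path(path)
    if path.suffix == ".csv":
        return _frame_to_protons(pd.read_csv(path), str(path))
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            missing = [c for c in _COLUMNS if c not in f]
            if missing:
                raise ValueError(f"{path}: missing dataset(s) {', '.join(missing)}")
            df = pd.DataFrame({c: f[c][:] for c in _COLUMNS})
            plist = _frame_to_protons(df, str(path))
            if "wepl_true_mm" in f:
                plist.wepl_true = f["wepl_true_mm"][:]
        return plist
    raise ValueError(f"unsupported proton-list extension {path.suffix!r}")


def write_volume(volume: RSPVolume, path) -> None:
    """Write an RSP volume as NIfTI (.nii/.nii.gz) or raw float32 + sidecar.

    The raw layout is C-order little-endian float32; the JSON sidecar
    ``<stem>.json`` records shape, voxel size and origin.
    """
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        h = volume.grid.voxel_size
        affine = np.diag([h, h, h, 1.0])
        affine[:3, 3] = volume.grid.origin
        img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
        nib.save(img, path)
    elif path.suffix == ".raw":
        volume.data.astype("<f4").tofile(path)
        sidecar = {
            "shape": list(volume.grid.shape),
            "voxel_size_mm": volume.grid.voxel_size,
            "origin_mm": list(volume.grid.origin),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported volume extension for {path.name!r}")


def read_volume(path) -> RSPVolume:
    """Read an RSP volume (NIfTI or raw + JSON sidecar, by extension)."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-6):
            raise ValueError(
                f"{path}: anisotropic voxels {zooms} are not supported "
                "(the reconstruction assumes an isotropic lattice)"
            )
        origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
        grid = VoxelGrid(shape=img.shape[:3], voxel_size=float(zooms[0]), origin=origin)
        return RSPVolume(grid=grid, data=np.asarray(img.dataobj, dtype=np.float64))
    if path.suffix == ".raw":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise ValueError(f"{path}: missing JSON sidecar {sidecar_path.name}")
        meta = json.loads(sidecar_path.read_text())
        shape = tuple(int(n) for n in meta["shape"])
        data = np.fromfile(path, dtype="<f4")
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"{path}: file holds {data.size} float32 values but sidecar "
                f"shape {shape} implies {int(np.prod(shape))}"
            )
        grid = VoxelGrid(shape=shape, voxel_size=float(meta["voxel_size_mm"]),
                         origin=tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))))
        return RSPVolume(grid=grid, data=data.reshape(shape).astype(np.float64))
    raise ValueError(f"unsupported volume extension for {path.name!r}")
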