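"""Reading and writing OCT volumes as TIFF stacks or NIfTI-1 files.

TIFF carries no physical geometry, so a JSON sidecar ``<name>.json`` with keys
``{n_z, n_y, n_x, extent_z_mm, extent_y_mm, extent_x_mm}`` is written next to
the stack.  NIfTI stores voxel pitch in its ``pixdim`` header field and needs
no sidecar.  Intensities are stored as float32, labels as uint8.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .volume import LabelVolume, OCTVolume, VoxelGeometry

FORMATS = ("tiff_stack", "nifti")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def infer_format(path: str | Path) -> str:
    suffixes = "".join(Path(path).suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return "nifti"
    return "tiff_stack"


def write_volume(
    vol: OCTVolume | LabelVolume, path: str | Path, format: str | None = None
) -> Path:
    """Write a volume to disk; returns the path written.

    Label volumes round-trip losslessly (uint8); intensity volumes round-trip
    at float32 precision.
    """
    path = Path(path)
    fmt = format or infer_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    data = vol.labels if isinstance(vol, LabelVolume) else vol.intensity
    g = vol.geometry
    if fmt == "tiff_stack":
        # one page per z slice
        tifffile.imwrite(path, data)
        _sidecar_path(path).write_text(json.dumps(g.to_dict()))
    else:
        affine = np.diag(
            [g.dz_opt_mm, g.extent_y_mm / g.n_y, g.extent_x_mm / g.n_x, 1.0]
        )
        nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_volume(
    path: str | Path,
    format: str | None = None,
    default_geometry: VoxelGeometry | None = None,
    labels: bool = False,
) -> OCTVolume | LabelVolume:
    """Read a 3D volume; geometry comes from the sidecar/header, else a default.

    With ``labels=True`` the result is a :class:`LabelVolume`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or infer_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    if fmt == "tiff_stack":
        try:
            data = np.asarray(tifffile.imread(path))
        except Exception as exc:  # corrupt or non-TIFF content
            raise ValueError(f"cannot decode TIFF stack {path}: {exc}") from exc
        geom = None
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            geom = VoxelGeometry.from_dict(json.loads(sidecar.read_text()))
    else:
        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise ValueError(f"cannot decode NIfTI file {path}: {exc}") from exc
        data = np.asarray(img.dataobj)
        geom = None
        if data.ndim == 3:
            zooms = img.header.get_zooms()[:3]
            if all(z > 0 for z in zooms):
                geom = VoxelGeometry(
                    *data.shape,
                    extent_z_mm=float(zooms[0]) * data.shape[0],
                    extent_y_mm=float(zooms[1]) * data.shape[1],
                    extent_x_mm=float(zooms[2]) * data.shape[2],
                )
    if data.ndim != 3:
        raise ValueError(f"{path} holds a {data.ndim}D grid; a 3D volume is required")
    if geom is None:
        geom = default_geometry or VoxelGeometry(*data.shape)
    if geom.shape != data.shape:
        raise ValueError(f"geometry {geom.shape} does not match data {data.shape}")
    if labels:
        return LabelVolume(data.astype(np.uint8), geom, identifier=path.stem)
    return OCTVolume(data.astype(np.float32), geom, identifier=path.stem)
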