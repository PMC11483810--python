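"""File I/O: volumes (NIfTI, TIFF), masks, landmarks, transforms, provenance.

NIfTI is the canonical on-disk volume format. Volumes written by this
package carry micron spatial units in the header, so a write/read round
trip preserves values and spacing exactly; files with mm units (the common
convention) are converted to µm on read. TIFF stacks are read-only and
require a JSON sidecar (``<file>.json``) providing ``spacing_um``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import AffineTransform3D, BinaryMask, Grid3D, LandmarkSet, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "write_provenance",
]

_UNIT_TO_UM = {"micron": 1.0, "mm": 1000.0, "meter": 1e6, "unknown": 1000.0}


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    xyz_unit, _ = img.header.get_xyzt_units()
    factor = _UNIT_TO_UM.get(xyz_unit, 1000.0)
    spacing = tuple(float(z) * factor for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) * factor for v in img.affine[:3, 3])
    return arr, spacing, origin


def _read_tiff(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise ValueError(
            f"TIFF input {path} needs a sidecar {sidecar.name} with 'spacing_um'"
        )
    meta = json.loads(sidecar.read_text())
    if "spacing_um" not in meta:
        raise ValueError(f"sidecar {sidecar} is missing the 'spacing_um' field")
    arr = tifffile.imread(str(path))
    # multi-page stacks arrive as (z, y, x); package layout is (x, y, z)
    arr = np.transpose(arr, (2, 1, 0))
    return arr, tuple(float(s) for s in meta["spacing_um"]), tuple(
        float(o) for o in meta.get("origin_um", (0.0, 0.0, 0.0))
    )


def _load(path) -> tuple[np.ndarray, Grid3D]:
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        arr, spacing, origin = _read_nifti(path)
    elif suffixes.endswith((".tif", ".tiff")):
        arr, spacing, origin = _read_tiff(path)
    else:
        raise ValueError(f"unknown volume extension on {path}")
    return arr, Grid3D(arr.shape, spacing, origin)


def read_volume(path) -> Volume:
    """Read a 3D intensity volume; spacing converted to µm internally."""
    arr, grid = _load(path)
    return Volume(grid, arr.astype(np.float32))


def read_mask(path) -> BinaryMask:
    """Read a binary segmentation mask (any non-zero voxel is foreground)."""
    arr, grid = _load(path)
    return BinaryMask(grid, (arr > 0).astype(np.uint8))


def _write_nifti(values: np.ndarray, grid: Grid3D, path) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = grid.spacing
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(values, affine)
    img.header.set_xyzt_units(xyz="micron")
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def write_volume(v: Volume, path) -> None:
    _write_nifti(v.values.astype(np.float32), v.grid, path)


def write_mask(m: BinaryMask, path) -> None:
    _write_nifti(m.values.astype(np.uint8), m.grid, path)


def read_landmarks(path) -> LandmarkSet:
    """Read landmarks from CSV with columns label,x_um,y_um,z_um."""
    df = pd.read_csv(path)
    needed = ["label", "x_um", "y_um", "z_um"]
    if list(df.columns[:4]) != needed:
        raise ValueError(f"landmark CSV must have columns {needed}")
    if df["label"].duplicated().any():
        dup = df["label"][df["label"].duplicated()].iloc[0]
        raise ValueError(f"duplicate landmark label {dup!r}")
    return LandmarkSet(
        {str(r.label): (r.x_um, r.y_um, r.z_um) for r in df.itertuples()}
    )


def write_landmarks(l: LandmarkSet, path) -> None:
    rows = [
        {"label": k, "x_um": p[0], "y_um": p[1], "z_um": p[2]}
        for k, p in sorted(l.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9f")


def write_transform(t: AffineTransform3D, path, note: str = "") -> None:
    """Serialise as JSON 4x4 row-major acting on physical µm, fixed->moving."""
    payload = {
        "matrix_row_major": t.matrix.reshape(-1).tolist(),
        "units": "um",
        "direction": "fixed_to_moving (pull-back warping)",
    }
    if note:
        payload["note"] = note
    Path(path).write_text(json.dumps(payload, indent=2))


def read_transform(path) -> AffineTransform3D:
    payload = json.loads(Path(path).read_text())
    return AffineTransform3D(np.asarray(payload["matrix_row_major"]).reshape(4, 4))


def write_provenance(path, **record) -> None:
    """Write a JSON provenance record (config, seeds, package version)."""
    from . import __version__

    record = {"mesoreg_version": __version__, **record}

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(record, indent=2, default=default, sort_keys=True))
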