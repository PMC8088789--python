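"""File formats: NIfTI volumes, TCK/TRK streamlines, FSL bval/bvec text,
CSV measure tables with JSON sidecars. All streamlines are exposed in world
mm regardless of the on-disk dialect; geometry mismatches between paired
inputs are hard errors, never silently resampled."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Bundle, VoxelGrid

__all__ = [
    "save_nifti",
    "read_volume",
    "read_mask",
    "check_same_grid",
    "save_tck",
    "save_trk",
    "read_streamlines",
    "save_bvals_bvecs",
    "read_bvals_bvecs",
    "write_measure_table",
    "read_measure_table",
    "write_json",
]


def save_nifti(path, data: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim < 3:
        raise ValueError(f"{path}: expected a 3-D or 4-D volume, got {data.ndim}-D")
    grid = VoxelGrid(data.shape[:3], img.affine)
    return data, grid


def read_mask(path) -> tuple[np.ndarray, VoxelGrid]:
    """Load a volume and binarize it at > 0.5."""
    data, grid = read_volume(path)
    mask = data > 0.5
    return mask, grid


def check_same_grid(a: VoxelGrid, b: VoxelGrid, what: str = "inputs") -> None:
    if not a.same_geometry(b):
        raise ValueError(
            f"geometry mismatch between {what}: shapes {a.shape} vs {b.shape}, "
            "affines differ — inputs must share a grid (no silent resampling)"
        )


def save_tck(path, bundle: Bundle) -> None:
    tractogram = nib.streamlines.Tractogram(
        bundle.streamlines, affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(tractogram, str(path))


def save_trk(path, bundle: Bundle, grid: VoxelGrid) -> None:
    tractogram = nib.streamlines.Tractogram(
        bundle.streamlines, affine_to_rasmm=np.eye(4)
    )
    header = {
        nib.streamlines.Field.VOXEL_TO_RASMM: grid.affine.astype(np.float32),
        nib.streamlines.Field.VOXEL_SIZES: grid.voxel_size.astype(np.float32),
        nib.streamlines.Field.DIMENSIONS: np.asarray(grid.shape, dtype=np.int16),
    }
    nib.streamlines.save(tractogram, str(path), header=header)


def read_streamlines(path, name: str | None = None) -> Bundle:
    """Read TCK or TRK; coordinates come back in world mm (RAS) either way."""
    path = Path(path)
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:  # malformed header, truncation, bad dtype
        raise ValueError(f"cannot parse streamline file {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    bundle_name = name or path.stem.replace(".tck", "").replace(".trk", "")
    side = (
        "left" if bundle_name.endswith("_left")
        else "right" if bundle_name.endswith("_right")
        else "commissural"
    )
    return Bundle(name=bundle_name, streamlines=streamlines, side=side)


def save_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    np.savetxt(str(bval_path), np.asarray(bvals, dtype=float)[None, :], fmt="%.1f")
    np.savetxt(str(bvec_path), np.asarray(bvecs, dtype=float).T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bvec shape {bvecs.shape} inconsistent with {bvals.size} b-values"
        )
    return bvals, bvecs


def write_measure_table(df: pd.DataFrame, path, sidecar: dict | None = None) -> None:
    """CSV keyed by subject ID with empty cells for missing values, plus a JSON
    sidecar recording column semantics and dialect choices."""
    path = Path(path)
    df.to_csv(path, index=True, na_rep="")
    meta = {"index": df.index.name or "subject_id", "columns": list(map(str, df.columns))}
    if sidecar:
        meta.update(sidecar)
    write_json(path.with_suffix(".json"), meta)


def read_measure_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    return df


def write_json(path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))
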