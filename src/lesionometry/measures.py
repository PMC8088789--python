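"""The six white-matter measures.

Global: voxel-based lesion load (lesion volume over head size) and whole-brain
tractogram load (lesioned tractogram volume over tractogram volume).
Per bundle: volume, bundle load (lesioned bundle volume over bundle volume),
Tractometry (microstructure averaged over all streamline points) and
lesionometry (the same average restricted to streamlines that traverse
lesions — either only the in-lesion portions, ``mode="portion"``, or the full
length of the affected streamlines, ``mode="full"``).

Voxelization dialect: streamlines are resampled to a step of half the smallest
voxel dimension and a voxel counts as traversed when it contains at least one
resampled point (nearest-voxel containment on the lesion-mask lattice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Bundle, VoxelGrid
from .phantom import _resample_polyline

__all__ = [
    "LesionInteraction",
    "default_step",
    "resample_bundle",
    "voxelize",
    "voxels_to_mask",
    "lesion_load",
    "tractogram_load",
    "bundle_volume",
    "bundle_load",
    "split_by_lesion",
    "tractometry",
    "lesionometry",
    "average_hemispheres",
]


def default_step(grid: VoxelGrid) -> float:
    return float(grid.voxel_size.min()) / 2.0


def resample_bundle(bundle: Bundle, step: float) -> Bundle:
    return Bundle(
        name=bundle.name,
        streamlines=[_resample_polyline(s, step) for s in bundle.streamlines],
        side=bundle.side,
    )


def _streamline_voxels(points: np.ndarray, grid: VoxelGrid, warn: list) -> np.ndarray:
    idx = grid.nearest_voxel(points)
    ok = grid.in_bounds(idx)
    if not ok.all():
        warn.append(int((~ok).sum()))
    return idx[ok]


def voxelize(bundle: Bundle, grid: VoxelGrid, step: float | None = None) -> set:
    """Set of voxel indices containing at least one (resampled) streamline point."""
    step = default_step(grid) if step is None else step
    dropped: list[int] = []
    chunks = [
        _streamline_voxels(_resample_polyline(s, step), grid, dropped)
        for s in bundle.streamlines
    ]
    if dropped:
        warnings.warn(
            f"bundle {bundle.name!r}: {sum(dropped)} streamline points outside the "
            "grid were dropped",
            stacklevel=2,
        )
    if not chunks:
        return set()
    allidx = np.unique(np.concatenate(chunks), axis=0)
    return {tuple(row) for row in allidx}


def voxels_to_mask(voxels: set, grid: VoxelGrid) -> np.ndarray:
    mask = np.zeros(grid.shape, dtype=bool)
    if voxels:
        idx = np.array(sorted(voxels))
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def lesion_load(lesion_mask: np.ndarray, brain_mask: np.ndarray) -> float:
    """Lesion voxel count over brain-mask voxel count (head-size normalization).

    Lesion voxels outside the brain mask are excluded from the numerator with
    a warning; an externally supplied intracranial volume can replace the
    denominator by passing a brain mask with that many voxels.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if lesion_mask.shape != brain_mask.shape:
        raise ValueError("lesion and brain masks are on different grids")
    n_brain = int(brain_mask.sum())
    if n_brain == 0:
        raise ValueError("brain mask is empty")
    outside = int((lesion_mask & ~brain_mask).sum())
    if outside:
        warnings.warn(
            f"{outside} lesion voxels outside the brain mask excluded from lesion load",
            stacklevel=2,
        )
    return float((lesion_mask & brain_mask).sum()) / n_brain


def tractogram_load(
    bundles, lesion_mask: np.ndarray, grid: VoxelGrid, step: float | None = None
) -> float:
    """Lesioned fraction of the whole-brain tractogram (all bundles concatenated)."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    voxels: set = set()
    for bundle in bundles:
        voxels |= voxelize(bundle, grid, step)
    if not voxels:
        raise ValueError("empty tractogram")
    hit = sum(lesion_mask[v] for v in voxels)
    return hit / len(voxels)


def bundle_volume(bundle: Bundle, grid: VoxelGrid, step: float | None = None) -> float:
    """Bundle volume in mm^3 (traversed voxel count times voxel volume)."""
    if len(bundle) == 0:
        raise ValueError(f"empty bundle {bundle.name!r}")
    return len(voxelize(bundle, grid, step)) * grid.voxel_volume


def bundle_load(
    bundle: Bundle, lesion_mask: np.ndarray, grid: VoxelGrid, step: float | None = None
) -> float:
    """Fraction of the bundle's voxelized volume intersecting lesions, in [0, 1]."""
    if len(bundle) == 0:
        raise ValueError(f"empty bundle {bundle.name!r}")
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    voxels = voxelize(bundle, grid, step)
    hit = sum(lesion_mask[v] for v in voxels)
    return hit / len(voxels)


@dataclass
class LesionInteraction:
    """Per-bundle decomposition into lesioned vs non-lesioned streamlines.

    Holds the resampled streamlines, per-point in-lesion flags, the indices of
    streamlines with at least one in-lesion point, and the voxel sets behind
    the volume/load computations (intersection set is a subset of the bundle
    set by construction).
    """

    bundle_name: str
    streamlines: list
    point_in_lesion: list
    lesioned_indices: np.ndarray
    bundle_voxels: set
    lesion_voxels: set

    @property
    def n_lesioned(self) -> int:
        return len(self.lesioned_indices)


def split_by_lesion(
    bundle: Bundle, lesion_mask: np.ndarray, grid: VoxelGrid, step: float | None = None
) -> LesionInteraction:
    """Flag each streamline lesioned iff any of its points maps to a lesion voxel."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    step = default_step(grid) if step is None else step
    resampled = [_resample_polyline(s, step) for s in bundle.streamlines]
    flags = []
    voxels: set = set()
    lesioned: set = set()
    for points in resampled:
        idx = grid.nearest_voxel(points)
        ok = grid.in_bounds(idx)
        inles = np.zeros(len(points), dtype=bool)
        inles[ok] = lesion_mask[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        flags.append(inles)
        voxels.update(map(tuple, idx[ok]))
        lesioned.update(map(tuple, idx[ok][inles[ok]]))
    lesioned_idx = np.array(
        [i for i, f in enumerate(flags) if f.any()], dtype=int
    )
    return LesionInteraction(
        bundle_name=bundle.name,
        streamlines=resampled,
        point_in_lesion=flags,
        lesioned_indices=lesioned_idx,
        bundle_voxels=voxels,
        lesion_voxels=lesioned,
    )


def _sample_map(points: np.ndarray, scalar_map: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    idx = grid.nearest_voxel(points)
    ok = grid.in_bounds(idx)
    vals = np.full(len(points), np.nan)
    vals[ok] = scalar_map[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return vals


def tractometry(
    bundle: Bundle, scalar_map: np.ndarray, grid: VoxelGrid, step: float | None = None
) -> float:
    """Point-weighted mean of a scalar map over all streamline points.

    NaN map values and out-of-grid points are excluded; an all-NaN sample set
    raises.
    """
    scalar_map = np.asarray(scalar_map, dtype=float)
    if scalar_map.shape != grid.shape:
        raise ValueError("scalar map is not on the sampling grid")
    step = default_step(grid) if step is None else step
    samples = np.concatenate(
        [_sample_map(_resample_polyline(s, step), scalar_map, grid) for s in bundle.streamlines]
    )
    good = np.isfinite(samples)
    if not good.any():
        raise ValueError(f"all samples NaN for bundle {bundle.name!r}")
    return float(samples[good].mean())


def lesionometry(
    interaction: LesionInteraction,
    scalar_map: np.ndarray,
    grid: VoxelGrid,
    mode: str = "portion",
) -> float:
    """Mean map value over lesion-affected streamlines.

    mode="portion" samples only points lying inside lesion voxels;
    mode="full" samples the entire length of every lesioned streamline.
    Returns NaN (missing, never 0) when no streamline is lesioned.
    """
    if mode not in ("portion", "full"):
        raise ValueError(f"unknown lesionometry mode {mode!r}")
    scalar_map = np.asarray(scalar_map, dtype=float)
    if interaction.n_lesioned == 0:
        return float("nan")
    chunks = []
    for i in interaction.lesioned_indices:
        points = interaction.streamlines[i]
        if mode == "portion":
            points = points[interaction.point_in_lesion[i]]
        chunks.append(_sample_map(points, scalar_map, grid))
    samples = np.concatenate(chunks)
    good = np.isfinite(samples)
    if not good.any():
        raise ValueError("all lesionometry samples NaN")
    return float(samples[good].mean())


def average_hemispheres(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce paired left/right bundle columns to single (L+R)/2 measures.

    Columns are named ``"<bundle>|<measure>"``; a bundle named ``x_left``
    must have an ``x_right`` twin (and vice versa) or the pairing fails.
    Commissural bundles and global measures pass through unchanged. A missing
    value on either side leaves the average missing.
    """
    out = {}
    done = set()
    for col in table.columns:
        if col in done:
            continue
        if "|" not in col:
            out[col] = table[col]
            continue
        bundle, measure = col.split("|", 1)
        if bundle.endswith("_left") or bundle.endswith("_right"):
            base = bundle.rsplit("_", 1)[0]
            lcol, rcol = f"{base}_left|{measure}", f"{base}_right|{measure}"
            if lcol not in table.columns or rcol not in table.columns:
                raise ValueError(f"unpaired hemisphere column {col!r}")
            out[f"{base}|{measure}"] = (table[lcol] + table[rcol]) / 2.0
            done.update((lcol, rcol))
        else:
            out[col] = table[col]
    return pd.DataFrame(out, index=table.index)
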