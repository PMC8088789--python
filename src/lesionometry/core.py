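"""Core geometric containers shared across the package.

A :class:`VoxelGrid` carries the image geometry (shape + affine) that masks,
scalar maps and streamlines must agree on; a :class:`Bundle` is a named set of
streamlines in world millimetres (TCK convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "Bundle"]


@dataclass(frozen=True)
class VoxelGrid:
    """Image geometry: array shape and a voxel-index -> world-mm affine.

    Voxel ``(i, j, k)`` occupies the half-open world region mapping to the
    index cube ``[i - 0.5, i + 0.5) x ...``; a world point belongs to the
    voxel its continuous index rounds to.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4), must be invertible

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")

    @classmethod
    def isotropic(cls, shape, voxel_size: float) -> "VoxelGrid":
        """Axis-aligned grid with isotropic voxels; voxel (0,0,0) centred at the origin."""
        aff = np.eye(4)
        aff[:3, :3] *= float(voxel_size)
        return cls(tuple(shape), aff)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to continuous voxel indices."""
        points = np.asarray(points, dtype=float)
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=float)
        return indices @ self.affine[:3, :3].T + self.affine[:3, 3]

    def nearest_voxel(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index containing each world point (nearest-centre rule)."""
        return np.rint(self.world_to_voxel(points)).astype(np.int64)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices)
        ok = np.ones(indices.shape[:-1], dtype=bool)
        for ax in range(3):
            ok &= (indices[..., ax] >= 0) & (indices[..., ax] < self.shape[ax])
        return ok

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape ``(*shape, 3)``."""
        ijk = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(ijk)

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class Bundle:
    """A named set of streamlines (polylines in world mm)."""

    name: str
    streamlines: list = field(default_factory=list)
    side: str = "commissural"  # left | right | commissural

    def __post_init__(self) -> None:
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(
                    f"streamline {i} of bundle {self.name!r} must be (n>=2, 3)"
                )
            if not np.isfinite(arr).all():
                raise ValueError(
                    f"streamline {i} of bundle {self.name!r} has non-finite coordinates"
                )
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.streamlines)
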