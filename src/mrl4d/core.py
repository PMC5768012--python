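"""Shared volumetric containers: grids, structure masks, dose grids, deformation fields.

Conventions used throughout the package:

* world coordinates are in cm; axis order is ``(x, y, z)`` with
  x = left–right, y = anterior–posterior, z = cranial–caudal;
* voxel-center convention: voxel ``(i, j, k)`` sits at
  ``origin + (i, j, k) * spacing``; indices are 0-based;
* arrays are indexed ``[ix, iy, iz]``.

The respiratory cycle is discretised into exactly 8 amplitude-binned phases
labelled 0, 12.5, 25, 37.5, 50, 62.5, 75, 87.5 (percent of the cycle), with
0% = maximum inhale (the reference phase) and 50% = end exhale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Phase labels in percent of the breathing cycle, in storage order.
PHASE_LABELS: tuple[float, ...] = (0.0, 12.5, 25.0, 37.5, 50.0, 62.5, 75.0, 87.5)
N_PHASES = 8
#: Index of the reference phase (maximum inhale).
REFERENCE_PHASE = 0
#: Index of the end-exhale phase (label 50%).
EXHALE_PHASE = 4


class LatticeMismatchError(ValueError):
    """Two volumetric objects do not share the same grid."""


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D lattice: shape in voxels, spacing and origin in cm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.25, 0.25, 0.25)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive on all axes, got {self.spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal_cm(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (sparse meshgrid) world coordinates of all voxel centers."""
        return tuple(np.meshgrid(*(self.axis_coords(a) for a in range(3)),
                                 indexing="ij", sparse=True))

    @property
    def center_cm(self) -> np.ndarray:
        return np.array([self.origin[a] + self.spacing[a] * (self.shape[a] - 1) / 2.0
                         for a in range(3)])

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (no rounding)."""
        return (np.asarray(pts, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


def check_same_grid(*objs: Any) -> GridSpec:
    """Raise :class:`LatticeMismatchError` unless all objects share one grid."""
    grids = [o.grid for o in objs]
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise LatticeMismatchError(f"lattice mismatch: {g} vs {first}")
    return first


@dataclass
class StructureMask:
    """Named boolean mask on a :class:`GridSpec` (GTV, an OAR, or BODY)."""

    name: str
    voxels: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask {self.name!r} shape {self.voxels.shape} != grid shape {self.grid.shape}")

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def volume_cc(self) -> float:
        return float(self.voxels.sum()) * self.grid.voxel_volume_cc

    @property
    def centroid_cm(self) -> np.ndarray:
        """World-coordinate centroid of the mask voxels."""
        if self.is_empty:
            raise ValueError(f"mask {self.name!r} is empty")
        idx = np.argwhere(self.voxels)
        return self.grid.index_to_world(idx.mean(axis=0))


@dataclass
class DoseGrid:
    """Scalar absorbed-dose grid in Gy with provenance metadata."""

    values: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"dose shape {self.values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("dose contains negative values")


@dataclass
class DeformationField:
    """Displacement field (cm) from the reference phase to a source phase.

    Pull-back convention: the field maps reference-phase world coordinates
    ``x`` to the source phase's coordinates ``x + vectors[x]``, so that
    sampling a source-phase image at ``x + vectors[x]`` produces its
    representation on the reference anatomy.
    """

    vectors: np.ndarray  # shape grid.shape + (3,)
    grid: GridSpec
    source_phase: int = 0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError(
                f"field shape {self.vectors.shape} != grid shape {self.grid.shape} + (3,)")

    @classmethod
    def zero(cls, grid: GridSpec, source_phase: int = 0) -> "DeformationField":
        return cls(np.zeros(grid.shape + (3,)), grid, source_phase)
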