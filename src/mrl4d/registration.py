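"""Apply and compose deformation fields: contour propagation and dose warping.

All warps are pull-back (backward) resamples with trilinear interpolation:
the output value at reference-phase voxel ``x`` is the input sampled at
``x + v(x)``. Backward warping avoids the holes and overlaps of forward
splatting. Out-of-grid dose lookups return 0 Gy; masks are warped as float
indicators and re-thresholded at 0.5.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    DeformationField,
    DoseGrid,
    StructureMask,
    check_same_grid,
)

__all__ = ["propagate_mask", "warp_dose", "compose_fields", "dice"]


def _pullback_coords(field: DeformationField) -> list[np.ndarray]:
    """Fractional voxel indices of the displaced sample points."""
    grid = field.grid
    coords = []
    for a in range(3):
        shape = [1, 1, 1]
        shape[a] = grid.shape[a]
        base = np.arange(grid.shape[a], dtype=float).reshape(shape)
        coords.append(base + field.vectors[..., a] / grid.spacing[a])
    return coords


def _warp_values(values: np.ndarray, field: DeformationField, cval: float = 0.0,
                 mode: str = "constant") -> np.ndarray:
    return map_coordinates(values, _pullback_coords(field), order=1,
                           mode=mode, cval=cval)


def propagate_mask(mask: StructureMask, field: DeformationField) -> StructureMask:
    """Resample a structure mask through a deformation field (threshold 0.5)."""
    check_same_grid(mask, field)
    warped = _warp_values(mask.voxels.astype(np.float32), field)
    return StructureMask(mask.name, warped >= 0.5, mask.grid)


def warp_dose(dose: DoseGrid, field: DeformationField) -> DoseGrid:
    """Map a source-phase dose onto the reference phase."""
    check_same_grid(dose, field)
    warped = np.maximum(_warp_values(dose.values, field), 0.0)
    prov = dict(dose.provenance)
    prov["warped_from_phase"] = field.source_phase
    return DoseGrid(warped, dose.grid, prov)


def compose_fields(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """Composition ``v(x) = v_in(x) + v_out(x + v_in(x))``.

    Warping with the composed field is equivalent to warping with ``outer``
    first and then warping the result with ``inner`` — the cascade used to
    chain phase-to-phase registrations back to the reference phase.
    Composing with a zero field returns the other field (edge values are
    extrapolated as nearest-neighbour).
    """
    check_same_grid(outer, inner)
    coords = _pullback_coords(inner)
    vec = np.empty_like(inner.vectors)
    for a in range(3):
        vec[..., a] = inner.vectors[..., a] + map_coordinates(
            outer.vectors[..., a], coords, order=1, mode="nearest")
    return DeformationField(vec, inner.grid, outer.source_phase)


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; two empty masks count as 1.0."""
    check_same_grid(a, b)
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)
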