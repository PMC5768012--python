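"""Shared fixtures: small grids, sphere masks and compact phantoms.

Everything is generated at test time; grids are kept small (32–64 voxels per
axis at the native 0.25 cm spacing) except where a check is explicitly about
the full problem size.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrl4d.core import GridSpec, StructureMask
from mrl4d.phantom import OARSpec, PhantomEntry, default_grid, generate_phantom


def make_grid(n: int = 48, spacing: float = 0.25) -> GridSpec:
    return default_grid((n, n, n), spacing)


def sphere_mask(grid: GridSpec, center, radius: float, name: str = "S") -> StructureMask:
    x, y, z = grid.world_coords()
    vox = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius ** 2
    return StructureMask(name, np.broadcast_to(vox, grid.shape).copy(), grid)


@pytest.fixture(scope="session")
def grid48() -> GridSpec:
    return make_grid(48)


@pytest.fixture(scope="session")
def grid64() -> GridSpec:
    return make_grid(64)


def small_entry(amplitude_cm: float = 1.0, *, rom_eso: float = 0.5,
                gtv_cc: float = 8.0, lungs: bool = True) -> PhantomEntry:
    """Compact two-OAR patient that fits a 12 cm (48-voxel) grid."""
    oars = (
        OARSpec("ESO", d_inh_cm=1.0, rom_cm=rom_eso, azimuth_deg=150.0, radius_cm=0.5,
                length_cm=9.0),
        OARSpec("HRT", d_inh_cm=0.4, rom_cm=0.0, azimuth_deg=250.0, shape="ellipsoid",
                semi_axes_cm=(1.5, 1.5, 2.4)),
    )
    return PhantomEntry("toy", amplitude_cm, gtv_cc, oars, prescription_gy=50.0,
                        fractions=5, include_lungs=lungs)


@pytest.fixture(scope="session")
def toy_phantom(grid48):
    return generate_phantom(small_entry(1.0), grid=grid48)


@pytest.fixture(scope="session")
def static_phantom(grid48):
    return generate_phantom(small_entry(0.0, rom_eso=0.0), grid=grid48)
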