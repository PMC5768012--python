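"""Target volumes, beam geometry, MLC apertures and the virtual couch shift.

Two motion-management strategies are modelled:

* ``"itv"`` — the internal-target-volume approach: one fixed beam's-eye-view
  aperture per beam, conformed to the union of the GTV over all 8 breathing
  phases plus the setup margin;
* ``"4dmrl"`` — simulated MLC tumor tracking on an MRI-linac: the phase-0
  aperture conforms to the phase-0 PTV (GTV + margin) and is shifted on every
  other phase by the GTV centroid displacement via a virtual couch shift
  (VCS), i.e. a software translation of the aperture in the isocenter plane
  while the isocenter itself stays fixed (the MRI-linac has no couch motion).

Beams are isocentric, coplanar and static; the gantry rotates about the
cranial–caudal (z) axis, so MLC leaf rows stack along z and leaves travel
along the in-plane lateral axis. Machine presets: the MRI-linac has
SAD 143.5 cm and a projected leaf width of 0.72 cm at isocenter; a
conventional linac has SAD 100 cm and 0.5 cm leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .core import StructureMask, check_same_grid

__all__ = [
    "MACHINES",
    "Beam",
    "BeamConfig",
    "Aperture",
    "Plan",
    "expand_margin",
    "build_itv",
    "bev_aperture",
    "vcs_shift",
    "make_plan",
]

#: machine presets: (SAD cm, projected leaf width at isocenter cm)
MACHINES: dict[str, tuple[float, float]] = {
    "mrl": (143.5, 0.72),
    "conventional": (100.0, 0.5),
}


@dataclass(frozen=True)
class Beam:
    """One static coplanar beam (IEC-like gantry angle, isocentric)."""

    gantry_deg: float
    isocenter_cm: tuple[float, float, float]
    sad_cm: float = 143.5
    leaf_width_cm: float = 0.72

    def __post_init__(self) -> None:
        if self.sad_cm <= 0 or self.leaf_width_cm <= 0:
            raise ValueError("SAD and leaf width must be > 0")
        object.__setattr__(self, "isocenter_cm", tuple(float(c) for c in self.isocenter_cm))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from source toward isocenter (gantry 0 = +y)."""
        a = math.radians(self.gantry_deg)
        return np.array([math.sin(a), math.cos(a), 0.0])

    @property
    def u_hat(self) -> np.ndarray:
        """In-plane lateral axis (leaf-travel direction)."""
        a = math.radians(self.gantry_deg)
        return np.array([math.cos(a), -math.sin(a), 0.0])

    @property
    def v_hat(self) -> np.ndarray:
        """In-plane cranial–caudal axis (leaf-row stacking direction)."""
        return np.array([0.0, 0.0, 1.0])

    @property
    def source_cm(self) -> np.ndarray:
        return np.asarray(self.isocenter_cm) - self.sad_cm * self.axis


@dataclass(frozen=True)
class BeamConfig:
    """Beam arrangement: machine preset plus equispaced coplanar angles."""

    machine: str = "mrl"
    n_beams: int = 7
    angles_deg: tuple[float, ...] | None = None
    margin_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.machine not in MACHINES:
            raise ValueError(f"unknown machine {self.machine!r}; options: {list(MACHINES)}")
        if self.angles_deg is None:
            angles = tuple(360.0 * i / self.n_beams for i in range(self.n_beams))
            object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "n_beams", len(self.angles_deg))

    @property
    def sad_cm(self) -> float:
        return MACHINES[self.machine][0]

    @property
    def leaf_width_cm(self) -> float:
        return MACHINES[self.machine][1]

    def beams(self, isocenter_cm) -> list[Beam]:
        return [Beam(a, tuple(isocenter_cm), self.sad_cm, self.leaf_width_cm)
                for a in self.angles_deg]


@dataclass
class Aperture:
    """MLC opening in the isocenter plane, one interval per leaf row.

    Row ``k`` is centered at ``k * pitch_cm`` on the in-plane cranial–caudal
    axis (row index 0 at isocenter); ``openings[i] = (left, right)`` in cm,
    with a NaN pair for a closed row.
    """

    pitch_cm: float
    row_indices: np.ndarray
    openings: np.ndarray

    def __post_init__(self) -> None:
        self.row_indices = np.asarray(self.row_indices, dtype=int)
        self.openings = np.asarray(self.openings, dtype=float).reshape(-1, 2)
        if self.pitch_cm <= 0:
            raise ValueError("leaf pitch must be > 0")
        if self.openings.shape[0] != self.row_indices.size:
            raise ValueError("one opening interval per row required")
        op = self.open_rows
        if np.any(self.openings[op, 0] > self.openings[op, 1]):
            raise ValueError("open rows must satisfy left <= right")

    @property
    def open_rows(self) -> np.ndarray:
        return ~np.isnan(self.openings).any(axis=1)

    @property
    def is_empty(self) -> bool:
        return not bool(self.open_rows.any())

    @property
    def row_centers_cm(self) -> np.ndarray:
        return self.row_indices * self.pitch_cm

    @property
    def area_cm2(self) -> float:
        op = self.open_rows
        widths = self.openings[op, 1] - self.openings[op, 0]
        return float(widths.sum() * self.pitch_cm)

    @property
    def centroid_cm(self) -> np.ndarray:
        """Area-weighted (u, v) centroid of the opening."""
        op = self.open_rows
        if not op.any():
            raise ValueError("empty aperture has no centroid")
        w = self.openings[op, 1] - self.openings[op, 0]
        u = self.openings[op].mean(axis=1)
        v = self.row_centers_cm[op]
        return np.array([np.average(u, weights=w), np.average(v, weights=w)])


@dataclass
class Plan:
    """Beam set plus apertures: one fixed set (ITV) or 8 per-phase sets (tracked)."""

    strategy: str
    beams: list[Beam]
    apertures: list[list[Aperture]]  # per beam: length 1 (itv) or 8 (4dmrl)
    prescription_gy: float
    fractions: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = 8 if self.strategy == "4dmrl" else 1
        for per_beam in self.apertures:
            if len(per_beam) != n:
                raise ValueError(
                    f"{self.strategy} plan needs {n} aperture(s) per beam, got {len(per_beam)}")
        isos = {b.isocenter_cm for b in self.beams}
        if len(isos) != 1:
            raise ValueError("all beams must share one isocenter")

    def aperture(self, beam_idx: int, phase: int) -> Aperture:
        per_beam = self.apertures[beam_idx]
        return per_beam[phase] if len(per_beam) > 1 else per_beam[0]


# ---------------------------------------------------------------------------
# target volumes

#: Mean depth of a mask's outermost voxel centers below the continuous
#: surface, in voxel units (measured on analytically voxelized spheres).
#: The EDT measures distances to voxel centers, so isotropic dilation
#: thresholds add this depth to reach the true surface without bias.
_EDT_SURFACE_BIAS_VOXELS = 0.29


def expand_margin(mask: StructureMask, margin_cm: float) -> StructureMask:
    """Isotropic Euclidean (distance-transform) dilation by ``margin_cm``."""
    if margin_cm < 0:
        raise ValueError("margin must be >= 0")
    if margin_cm == 0:
        return StructureMask(mask.name, mask.voxels.copy(), mask.grid)
    d = distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing)
    reach = margin_cm + _EDT_SURFACE_BIAS_VOXELS * float(np.mean(mask.grid.spacing))
    return StructureMask(mask.name, mask.voxels | (d <= reach), mask.grid)


def build_itv(gtv_masks: list[StructureMask], margin_cm: float) -> StructureMask:
    """Union of the GTV over all phases, expanded isotropically by the margin."""
    grid = check_same_grid(*gtv_masks)
    union = np.zeros(grid.shape, dtype=bool)
    for m in gtv_masks:
        if m.is_empty:
            raise ValueError("cannot build an ITV from an empty GTV mask")
        union |= m.voxels
    return expand_margin(StructureMask("ITV", union, grid), margin_cm)


# ---------------------------------------------------------------------------
# apertures

def bev_aperture(target: StructureMask, beam: Beam) -> Aperture:
    """Conform an MLC aperture to the target in the beam's-eye view.

    Every target voxel center is ray-projected from the point source onto the
    isocenter plane (perpendicular to the beam axis); per leaf row, the
    opening is the [min, max] lateral extent of the projected points.
    """
    if target.is_empty:
        raise ValueError("cannot build an aperture for an empty target")
    pts = target.grid.index_to_world(np.argwhere(target.voxels))
    rel = pts - beam.source_cm
    s_axial = rel @ beam.axis
    scale = beam.sad_cm / s_axial
    u = (rel @ beam.u_hat) * scale
    v = (rel @ beam.v_hat) * scale
    pitch = beam.leaf_width_cm
    rows = np.floor(v / pitch + 0.5).astype(int)
    kmin, kmax = int(rows.min()), int(rows.max())
    idx = np.arange(kmin, kmax + 1)
    openings = np.full((idx.size, 2), np.nan)
    for j, k in enumerate(idx):
        sel = rows == k
        if sel.any():
            openings[j] = (u[sel].min(), u[sel].max())
    return Aperture(pitch, idx, openings)


def vcs_shift(aperture: Aperture, displacement_cm, beam: Beam) -> Aperture:
    """Virtual couch shift: translate the aperture by a target displacement.

    The 3-vector displacement is projected into the isocenter plane; leaf
    openings shift laterally by the u-component and rows are re-quantized to
    the leaf grid for the v-component (round to nearest row, ties craniad).
    The beam isocenter is unchanged — only the aperture moves.
    """
    d = np.asarray(displacement_cm, dtype=float)
    if d.shape != (3,) or not np.all(np.isfinite(d)):
        raise ValueError("displacement must be a finite 3-vector")
    du = float(d @ beam.u_hat)
    dv = float(d @ beam.v_hat)
    pitch = aperture.pitch_cm
    shifted: dict[int, list[float]] = {}
    for k, (lo, hi) in zip(aperture.row_indices, aperture.openings):
        if np.isnan(lo):
            continue
        new_k = int(np.floor((k * pitch + dv) / pitch + 0.5))
        iv = shifted.setdefault(new_k, [np.inf, -np.inf])
        iv[0] = min(iv[0], lo + du)
        iv[1] = max(iv[1], hi + du)
    if not shifted:
        return Aperture(pitch, aperture.row_indices.copy(), np.full_like(aperture.openings, np.nan))
    kmin, kmax = min(shifted), max(shifted)
    idx = np.arange(kmin, kmax + 1)
    openings = np.full((idx.size, 2), np.nan)
    for j, k in enumerate(idx):
        if k in shifted:
            openings[j] = shifted[k]
    return Aperture(pitch, idx, openings)


# ---------------------------------------------------------------------------
# plans

def make_plan(phantom, strategy: str, beam_config: BeamConfig,
              prescription_gy: float, fractions: int,
              gtv_masks: list[StructureMask] | None = None) -> Plan:
    """Build an ITV or tracked (4D-MRL) plan for a phantom.

    ITV: one fixed aperture per beam conformed to the ITV (phase-union GTV +
    margin), isocenter at the ITV centroid. Tracked: the phase-0 aperture
    conforms to the phase-0 PTV (GTV + margin); every other phase's aperture
    is the phase-0 one shifted by the GTV centroid displacement via VCS,
    around a constant isocenter at the phase-0 GTV centroid.

    ``gtv_masks`` overrides the per-phase target contours (e.g. contours
    propagated from the reference phase instead of the generator's own).
    """
    strategy = strategy.lower()
    if strategy not in ("itv", "4dmrl"):
        raise ValueError(f"unknown strategy {strategy!r}; use 'itv' or '4dmrl'")
    margin = beam_config.margin_cm
    gtvs = gtv_masks if gtv_masks is not None else [phantom.gtv(p) for p in range(8)]
    if len(gtvs) != 8:
        raise ValueError("need one GTV mask per phase")
    if strategy == "itv":
        target = build_itv(gtvs, margin)
        beams = beam_config.beams(target.centroid_cm)
        apertures = [[bev_aperture(target, b)] for b in beams]
        meta = {"target": "ITV", "target_volume_cc": target.volume_cc}
    else:
        ptv0 = expand_margin(gtvs[0], margin)
        c0 = gtvs[0].centroid_cm
        beams = beam_config.beams(c0)
        apertures = []
        for b in beams:
            ap0 = bev_aperture(ptv0, b)
            per_phase = [ap0 if p == 0 else vcs_shift(ap0, gtvs[p].centroid_cm - c0, b)
                         for p in range(8)]
            apertures.append(per_phase)
        meta = {"target": "PTV0", "target_volume_cc": ptv0.volume_cc}
    return Plan(strategy, beams, apertures, float(prescription_gy), int(fractions), meta)
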