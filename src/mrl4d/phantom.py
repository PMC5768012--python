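"""Synthetic 4D breathing phantoms: a desk-scale stand-in for patient 4D-CTs.

Each phantom is an 8-phase amplitude-binned image set: per phase a density
grid (g/cc) plus structure masks for the tumor (GTV), organs at risk and the
BODY outline. Geometry uses deliberately minimal primitives — the tumor is a
sphere, tubular organs (esophagus, trachea, spinal canal, great vessels) are
finite cylinders along the cranial–caudal axis, the heart is an ellipsoid,
the lungs are a pair of lateral ellipsoids and BODY is an elliptic cylinder.
These shapes are enough to realize any requested tumor motion amplitude,
GTV volume, OAR-to-target proximity (``d_inh``, may be negative for
overlapping organs) and relative organ motion (ROM).

Motion model: every structure follows its own rigid trajectory over the
8 phases. The tumor moves along a configurable axis (cranial–caudal by
default) reaching its full amplitude at end exhale (phase 50%); an OAR with
``rom_cm > 0`` drifts laterally toward the tumor, reaching ``d_inh - rom``
at end exhale. Phase 0 (maximum inhale) is the reference: every trajectory
starts at zero there.

Because the deformations are constructed, not estimated, the module can also
emit exact ("ground truth") deformation fields between any phase and the
reference phase — the stand-in for a deformable image registration engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .core import (
    EXHALE_PHASE,
    N_PHASES,
    PHASE_LABELS,
    DeformationField,
    GridSpec,
    StructureMask,
)
from .breathing import BreathingTrace

__all__ = [
    "OARSpec",
    "PhantomEntry",
    "MotionSpec",
    "PhantomPhase",
    "Phantom4D",
    "PhantomGeometryError",
    "generate_phantom",
    "ground_truth_field",
    "ground_truth_field_between",
    "generate_breathing_trace",
]

#: Fraction of the full exhale displacement reached at each phase
#: (0% … 87.5%); end exhale (50%) is the full displacement.
PHASE_FRACTIONS: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25)

DENSITY_AIR = 0.0012
DENSITY_LUNG = 0.26
DENSITY_SOFT = 1.0
DENSITY_BONE = 1.3


class PhantomGeometryError(ValueError):
    """A structure does not fit the grid or the BODY outline."""


@dataclass(frozen=True)
class OARSpec:
    """Placement request for one organ at risk.

    ``d_inh_cm`` is the signed surface distance from the GTV at maximum
    inhale (negative = overlap depth), ``rom_cm`` the relative organ motion:
    the OAR drifts toward the tumor so that the surface distance at end
    exhale is ``d_inh - rom``. ``azimuth_deg`` places the organ in the
    axial plane (0 deg = +x, 90 deg = +y) relative to the tumor.
    """

    name: str
    d_inh_cm: float
    rom_cm: float = 0.0
    azimuth_deg: float = 0.0
    shape: str = "tube"  # "tube" or "ellipsoid"
    radius_cm: float = 0.5
    length_cm: float = 12.0
    semi_axes_cm: tuple[float, float, float] = (2.8, 2.8, 5.0)
    density: float = DENSITY_SOFT

    def __post_init__(self) -> None:
        if self.shape not in ("tube", "ellipsoid"):
            raise ValueError(f"unknown OAR shape {self.shape!r}")
        if self.rom_cm < 0:
            raise ValueError("rom_cm must be >= 0")
        object.__setattr__(self, "semi_axes_cm",
                           tuple(float(s) for s in self.semi_axes_cm))


@dataclass(frozen=True)
class PhantomEntry:
    """Parameters of one cohort member (one synthetic patient)."""

    patient_id: str
    tumor_amplitude_cm: float
    gtv_volume_cc: float
    oars: tuple[OARSpec, ...] = ()
    prescription_gy: float = 50.0
    fractions: int = 5
    motion_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    breathing_period_s: float = 5.0
    include_lungs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_amplitude_cm < 0:
            raise ValueError("tumor amplitude must be >= 0")
        if self.gtv_volume_cc <= 0:
            raise ValueError("GTV volume must be > 0")
        axis = np.asarray(self.motion_axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("motion_axis must be non-zero")
        object.__setattr__(self, "motion_axis", tuple(float(a) for a in axis / n))

    @property
    def gtv_radius_cm(self) -> float:
        return (3.0 * self.gtv_volume_cc / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class MotionSpec:
    """Per-structure rigid trajectories: displacement (cm) per phase, zero at phase 0."""

    trajectories: dict[str, np.ndarray]  # name -> (8, 3)

    def __post_init__(self) -> None:
        for name, traj in self.trajectories.items():
            traj = np.asarray(traj, dtype=float)
            if traj.shape != (N_PHASES, 3):
                raise ValueError(f"trajectory of {name!r} must be (8, 3)")
            if np.any(traj[0] != 0):
                raise ValueError(f"trajectory of {name!r} must be zero at phase 0")
            self.trajectories[name] = traj

    @property
    def tumor_amplitude_cm(self) -> float:
        """Vector norm of the GTV displacement between phase 0% and phase 50%."""
        return float(np.linalg.norm(self.trajectories["GTV"][EXHALE_PHASE]))

    def displacement(self, name: str, phase: int) -> np.ndarray:
        return self.trajectories[name][phase]


@dataclass
class PhantomPhase:
    """One breathing phase: density grid (g/cc) and structure masks."""

    density: np.ndarray
    masks: dict[str, StructureMask]


@dataclass
class Phantom4D:
    """8-phase synthetic phantom with known motion and exact deformations."""

    grid: GridSpec
    phases: list[PhantomPhase]
    motion: MotionSpec
    entry: PhantomEntry | None = None
    _selection_dist: dict = field(default_factory=dict, repr=False)
    _field_cache: dict = field(default_factory=dict, repr=False)
    _gtv_envelope: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.phases) != N_PHASES:
            raise ValueError(f"phantom must have exactly {N_PHASES} phases")
        for ph in self.phases:
            if np.any(ph.density <= 0):
                raise ValueError("densities must be > 0 everywhere")

    def mask(self, name: str, phase: int) -> StructureMask:
        return self.phases[phase].masks[name]

    def gtv(self, phase: int) -> StructureMask:
        return self.mask("GTV", phase)

    @property
    def structure_names(self) -> list[str]:
        return list(self.phases[0].masks.keys())


# ---------------------------------------------------------------------------
# geometry primitives (boolean masks on a GridSpec)

#: 2x2x2 sub-voxel sample offsets (in voxel units) for anti-aliased voxelization.
_SUBOFFSETS = tuple((sx, sy, sz) for sx in (-0.25, 0.25)
                    for sy in (-0.25, 0.25) for sz in (-0.25, 0.25))


def _supersampled(grid: GridSpec, indicator) -> np.ndarray:
    """Voxelize a continuous indicator by majority vote over 8 sub-points.

    Includes a voxel when at least half of its sub-samples lie inside the
    shape, which keeps mask volumes stable (< a few %) under sub-voxel rigid
    motion — plain center-inclusion of thin structures can swing by 20%.
    """
    x, y, z = grid.world_coords()
    sp = grid.spacing
    votes = np.zeros(grid.shape, dtype=np.int8)
    for sx, sy, sz in _SUBOFFSETS:
        votes += indicator(x + sx * sp[0], y + sy * sp[1], z + sz * sp[2])
    return votes >= 4


def _sphere(grid: GridSpec, center, radius: float) -> np.ndarray:
    return _supersampled(grid, lambda x, y, z: (
        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        <= radius ** 2))


def _ellipsoid(grid: GridSpec, center, semi, u_dir=None) -> np.ndarray:
    """Ellipsoid; if ``u_dir`` is given, the first semi-axis lies along that
    in-plane unit vector (the third axis stays cranial–caudal)."""
    def inside(x, y, z):
        dx, dy, dz = x - center[0], y - center[1], z - center[2]
        if u_dir is None:
            u, w = dx, dy
        else:
            u = dx * u_dir[0] + dy * u_dir[1]
            w = -dx * u_dir[1] + dy * u_dir[0]
        return (u / semi[0]) ** 2 + (w / semi[1]) ** 2 + (dz / semi[2]) ** 2 <= 1.0

    return _supersampled(grid, inside)


def _lateral_votes(grid: GridSpec, inside_xy, n_sub: int = 4) -> np.ndarray:
    """Anti-aliased 2-D cross-section: majority vote over n_sub^2 sub-points."""
    x = grid.axis_coords(0)[:, None]
    y = grid.axis_coords(1)[None, :]
    offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    votes = np.zeros((grid.shape[0], grid.shape[1]), dtype=np.int16)
    for ox in offs:
        for oy in offs:
            votes += inside_xy(x + ox * grid.spacing[0], y + oy * grid.spacing[1])
    return votes >= (n_sub * n_sub) // 2


def _tube(grid: GridSpec, center, radius: float, length: float) -> np.ndarray:
    lat = _lateral_votes(grid, lambda x, y: (
        (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius ** 2))
    z = grid.axis_coords(2)[None, None, :]
    return lat[..., None] & np.broadcast_to(np.abs(z - center[2]) <= length / 2.0,
                                            grid.shape)


def _elliptic_cylinder(grid: GridSpec, center_xy, semi_xy) -> np.ndarray:
    lat = _lateral_votes(grid, lambda x, y: (
        ((x - center_xy[0]) / semi_xy[0]) ** 2
        + ((y - center_xy[1]) / semi_xy[1]) ** 2 <= 1.0))
    return np.repeat(lat[..., None], grid.shape[2], axis=2)


def _azimuth_unit(azimuth_deg: float) -> np.ndarray:
    a = math.radians(azimuth_deg)
    return np.array([math.cos(a), math.sin(a), 0.0])


# ---------------------------------------------------------------------------
# phantom generation

def default_grid(shape: tuple[int, int, int] = (96, 96, 96),
                 spacing_cm: float = 0.25) -> GridSpec:
    """Grid centered on the world origin (dose-grid resolution 0.25 cm)."""
    sp = (spacing_cm,) * 3
    origin = tuple(-(s - 1) / 2.0 * spacing_cm for s in shape)
    return GridSpec(shape, sp, origin)


def _oar_surface_offset(oar: OARSpec) -> float:
    """Distance from the OAR center to its surface along the tumor direction."""
    return oar.radius_cm if oar.shape == "tube" else oar.semi_axes_cm[0]


def generate_phantom(entry: PhantomEntry, grid: GridSpec | None = None,
                     density_noise_sd: float = 0.0) -> Phantom4D:
    """Build the 8-phase phantom requested by a cohort entry.

    The generator is a pure function of ``(entry, grid, density_noise_sd)``;
    the entry's ``seed`` drives the optional static density texture, so the
    same entry always yields bit-identical output.
    """
    if grid is None:
        grid = default_grid()
    half = np.array([(s - 1) / 2.0 * sp for s, sp in zip(grid.shape, grid.spacing)])
    center = grid.center_cm
    axis = np.asarray(entry.motion_axis)
    r_g = entry.gtv_radius_cm

    # phase-0 tumor center: offset so the motion straddles the grid center
    gtv0 = center - axis * entry.tumor_amplitude_cm / 2.0

    traj: dict[str, np.ndarray] = {}
    traj["GTV"] = np.outer(PHASE_FRACTIONS, axis * entry.tumor_amplitude_cm)
    oar_centers: dict[str, np.ndarray] = {}
    for oar in entry.oars:
        u = _azimuth_unit(oar.azimuth_deg)
        dist = oar.d_inh_cm + r_g + _oar_surface_offset(oar)
        oar_centers[oar.name] = gtv0 + u * dist
        traj[oar.name] = np.outer(PHASE_FRACTIONS, -u * oar.rom_cm)

    body_semi = (half[0] - 3 * grid.spacing[0], half[1] - 3 * grid.spacing[1])
    body = _elliptic_cylinder(grid, center[:2], body_semi)

    lung_masks_static = None
    if entry.include_lungs:
        lung_dx = 0.45 * body_semi[0]
        semi_x = 0.35 * body_semi[0]
        # keep the lateral ellipsoids inside the BODY ellipse cross-section
        frac = (lung_dx + semi_x) / body_semi[0]
        semi_y = (body_semi[1] - 0.3) * math.sqrt(max(1.0 - frac ** 2, 0.05))
        semi = (semi_x, min(7.0, semi_y), min(7.0, half[2] - 0.5))
        left = _ellipsoid(grid, center + np.array([-lung_dx, 0, 0]), semi)
        right = _ellipsoid(grid, center + np.array([lung_dx, 0, 0]), semi)
        lung_masks_static = left | right
        traj["LNG"] = np.zeros((N_PHASES, 3))

    rng = np.random.default_rng(entry.seed)
    texture = rng.normal(0.0, density_noise_sd, grid.shape) if density_noise_sd > 0 else None

    z_half = half[2]
    phases: list[PhantomPhase] = []
    for p in range(N_PHASES):
        masks: dict[str, StructureMask] = {}
        masks["BODY"] = StructureMask("BODY", body, grid)

        gtv_c = gtv0 + traj["GTV"][p]
        gtv = _sphere(grid, gtv_c, r_g)
        masks["GTV"] = StructureMask("GTV", gtv, grid)

        occupied = gtv.copy()
        for oar in entry.oars:
            c = oar_centers[oar.name] + traj[oar.name][p]
            if oar.shape == "tube":
                length = min(oar.length_cm, 2 * z_half - 1.0)
                m = _tube(grid, np.array([c[0], c[1], gtv0[2]]), oar.radius_cm, length)
            else:
                u = _azimuth_unit(oar.azimuth_deg)
                m = _ellipsoid(grid, c, oar.semi_axes_cm, u_dir=u)
            masks[oar.name] = StructureMask(oar.name, m, grid)
            occupied |= m

        if lung_masks_static is not None:
            masks["LNG"] = StructureMask("LNG", lung_masks_static & ~occupied, grid)

        _check_geometry(masks, p)

        density = np.full(grid.shape, DENSITY_AIR)
        density[body] = DENSITY_SOFT
        if "LNG" in masks:
            density[masks["LNG"].voxels] = DENSITY_LUNG
        for oar in entry.oars:
            density[masks[oar.name].voxels] = oar.density
        density[gtv] = DENSITY_SOFT
        if texture is not None:
            density = np.maximum(density + texture, DENSITY_AIR)
        phases.append(PhantomPhase(density, masks))

    return Phantom4D(grid, phases, MotionSpec(traj), entry)


def _check_geometry(masks: dict[str, StructureMask], phase: int) -> None:
    label = PHASE_LABELS[phase]
    body = masks["BODY"].voxels
    for name, mask in masks.items():
        if name == "BODY":
            continue
        v = mask.voxels
        if not v.any():
            raise PhantomGeometryError(
                f"structure {name} leaves grid at phase {label}% (empty mask)")
        edge = (v[0].any() or v[-1].any() or v[:, 0].any() or v[:, -1].any()
                or v[:, :, 0].any() or v[:, :, -1].any())
        if edge:
            raise PhantomGeometryError(f"structure {name} leaves grid at phase {label}%")
        if np.any(v & ~body):
            raise PhantomGeometryError(f"structure {name} leaves BODY at phase {label}%")


# ---------------------------------------------------------------------------
# ground-truth deformation fields

def _selection_distances(phantom: Phantom4D) -> dict[str, np.ndarray]:
    """Distance (cm) to each structure's territory in the reference frame.

    The tumor's territory is its motion envelope (union of the GTV over all
    phases), so every voxel the tumor sweeps follows the tumor's rigid
    displacement exactly; an OAR's territory is its reference-phase mask
    minus the tumor envelope — the tumor wins contested voxels, which keeps
    the propagated GTV exact even when an organ overlaps the target.
    """
    if phantom._selection_dist:
        return phantom._selection_dist
    grid = phantom.grid
    names = [n for n in phantom.structure_names if n not in ("BODY", "LNG")]
    gtv_env = np.zeros(grid.shape, dtype=bool)
    for p in range(N_PHASES):
        gtv_env |= phantom.gtv(p).voxels
    phantom._gtv_envelope = gtv_env
    out: dict[str, np.ndarray] = {}
    for name in names:
        if name == "GTV":
            territory = gtv_env
        else:
            territory = phantom.mask(name, 0).voxels & ~gtv_env
            if not territory.any():
                territory = phantom.mask(name, 0).voxels
        out[name] = distance_transform_edt(~territory, sampling=grid.spacing)
    phantom._selection_dist = out
    return out


def _blended_field(phantom: Phantom4D, displacements: dict[str, np.ndarray],
                   sigma_cm: float, sigma_select_cm: float) -> np.ndarray:
    """Blend rigid per-structure displacements into one smooth field.

    Nearest-structure softmax selection (scale ``sigma_select_cm``) decides
    *which* structure's displacement a voxel follows; a wider Gaussian
    envelope (scale ``sigma_cm``) fades the displacement into the static
    background. Inside the tumor's motion envelope the field is exactly the
    tumor's rigid displacement (the tumor wins contested voxels outright);
    inside an OAR's uncontested reference-phase mask it is exactly that
    organ's displacement.
    """
    dists = _selection_distances(phantom)
    names = list(dists.keys())
    logw = np.stack([-dists[n] ** 2 / (2.0 * sigma_select_cm ** 2) for n in names])
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=0, keepdims=True)
    dmin = np.minimum.reduce([dists[n] for n in names])
    envelope = np.exp(-dmin ** 2 / (2.0 * sigma_cm ** 2))
    out = np.zeros(phantom.grid.shape + (3,))
    for i, name in enumerate(names):
        d = displacements.get(name)
        if d is None or not np.any(d):
            continue
        out += (w[i] * envelope)[..., None] * d
    d_gtv = displacements.get("GTV")
    if d_gtv is not None:
        out[phantom._gtv_envelope] = d_gtv
    return out


def ground_truth_field_between(phantom: Phantom4D, from_phase: int, to_phase: int,
                               sigma_cm: float = 2.0,
                               sigma_select_cm: float = 0.4) -> DeformationField:
    """Exact field mapping phase ``from_phase`` coordinates to ``to_phase``.

    Pull-back convention: warping a ``to_phase`` image with this field
    produces its representation on the ``from_phase`` anatomy.
    """
    for p in (from_phase, to_phase):
        if not 0 <= p < N_PHASES:
            raise ValueError(f"phase index {p} out of range 0..{N_PHASES - 1}")
    key = (from_phase, to_phase, sigma_cm, sigma_select_cm)
    if key in phantom._field_cache:
        return phantom._field_cache[key]
    if from_phase == to_phase:
        fld = DeformationField.zero(phantom.grid, to_phase)
    else:
        disp = {name: phantom.motion.displacement(name, to_phase)
                - phantom.motion.displacement(name, from_phase)
                for name in phantom.motion.trajectories}
        fld = DeformationField(
            _blended_field(phantom, disp, sigma_cm, sigma_select_cm),
            phantom.grid, to_phase)
    phantom._field_cache[key] = fld
    return fld


def ground_truth_field(phantom: Phantom4D, phase: int, sigma_cm: float = 2.0,
                       sigma_select_cm: float = 0.4) -> DeformationField:
    """Field from the reference phase (0%, maximum inhale) to ``phase``."""
    return ground_truth_field_between(phantom, 0, phase, sigma_cm, sigma_select_cm)


# ---------------------------------------------------------------------------
# breathing-trace generator

def generate_breathing_trace(period_s: float = 5.0, amplitude: float = 1.0,
                             exponent_n: int = 2, variability: float = 0.0,
                             duration_s: float = 60.0, sample_rate_hz: float = 25.0,
                             seed: int | None = 0) -> BreathingTrace:
    """Synthetic bellows-like signal: ``a(t) = A_i * cos^(2n)(pi t_i / T_i)``.

    Each cycle ``i`` draws its period and amplitude from normal distributions
    centered on the nominal values with relative standard deviation
    ``variability`` (0 gives an exactly periodic trace). The signal peaks at
    maximum inhale and dwells near end exhale, as bellows pressure traces do.
    """
    if period_s <= 0:
        raise ValueError("period must be > 0")
    if sample_rate_hz < 10:
        raise ValueError("sample rate must be >= 10 Hz")
    if duration_s < 2 * period_s:
        raise ValueError("duration must cover at least 2 periods "
                         "(period detection is impossible otherwise)")
    rng = np.random.default_rng(seed)
    starts = [0.0]
    periods = []
    amps = []
    while starts[-1] < duration_s:
        t_i = period_s * float(np.clip(1.0 + variability * rng.standard_normal(), 0.3, 3.0))
        a_i = amplitude * float(np.clip(1.0 + variability * rng.standard_normal(), 0.1, None))
        periods.append(t_i)
        amps.append(a_i)
        starts.append(starts[-1] + t_i)
    times = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    cycle = np.searchsorted(np.asarray(starts), times, side="right") - 1
    t_local = times - np.asarray(starts)[cycle]
    per = np.asarray(periods)[cycle]
    amp = np.asarray(amps)[cycle]
    values = amp * np.cos(np.pi * t_local / per) ** (2 * int(exponent_n))
    return BreathingTrace(times, values)
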