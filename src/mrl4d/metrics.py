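"""Plan evaluation: DVHs, TG-101 SBRT limits, GTV–OAR distances, ROM, sparing.

Distances are Euclidean distance-transform based and reported in cm. The
signed minimum GTV–OAR distance is positive for disjoint structures (surface
to surface) and negative when they overlap, with magnitude equal to the
deepest penetration of one structure into the other — so an organ that moves
into the target volume gets a negative proximity value.

The relative organ motion of an OAR is ``ROM = |d_exh - d_inh|``: the change
in minimum GTV–OAR distance between end exhale (phase 50%) and maximum
inhale (phase 0%).

Dose sparing of tracking for one OAR is
``(Dmean_ITV - Dmean_tracked) / prescription`` (dimensionless); the sparing
regression fits sparing against ROM by ordinary least squares with a
two-sided t-test on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import distance_transform_edt

from .core import DoseGrid, StructureMask, check_same_grid

__all__ = [
    "DVHCurve",
    "ROMResult",
    "SparingRecord",
    "TG101_LIMITS",
    "dvh",
    "tg101_metrics",
    "signed_min_distance",
    "rom",
    "sparing_regression",
    "proximity_profile",
    "irradiated_volume_reduction",
]


@dataclass
class DVHCurve:
    """Cumulative dose–volume histogram: volume (cc) at or above each dose edge."""

    edges_gy: np.ndarray
    volume_cc: np.ndarray

    def __post_init__(self) -> None:
        self.edges_gy = np.asarray(self.edges_gy, dtype=float)
        self.volume_cc = np.asarray(self.volume_cc, dtype=float)
        if self.edges_gy.shape != self.volume_cc.shape:
            raise ValueError("edges and volumes must align")
        if np.any(np.diff(self.volume_cc) > 1e-9):
            raise ValueError("cumulative DVH must be non-increasing")

    def v_at(self, dose_gy: float) -> float:
        """Volume (cc) receiving at least ``dose_gy``.

        Queries between bin edges round up to the next edge, so a threshold
        just above a dose level correctly excludes that level.
        """
        i = int(np.searchsorted(self.edges_gy, dose_gy, side="left"))
        if i >= self.edges_gy.size:
            return 0.0
        return float(self.volume_cc[i])


@dataclass(frozen=True)
class ROMResult:
    """Signed GTV–OAR distances at inhale/exhale and the relative organ motion."""

    d_inh_cm: float
    d_exh_cm: float

    @property
    def rom_cm(self) -> float:
        return abs(self.d_exh_cm - self.d_inh_cm)


@dataclass(frozen=True)
class SparingRecord:
    """One OAR's tracking benefit with its motion/proximity covariates."""

    oar: str
    patient_id: str
    rom_cm: float
    d_inh_cm: float
    sparing: float  # (Dmean_ITV - Dmean_tracked) / prescription
    mean_dose_itv_gy: float = float("nan")
    mean_dose_tracked_gy: float = float("nan")


#: AAPM TG-101 style SBRT limits used for the pass/fail report:
#: {organ: [(metric, threshold_gy_or_None, limit_cc_or_gy)]} where metric is
#: "Vx" (volume in cc at or above x Gy, limit in cc) or "Dmax" (Gy).
TG101_LIMITS: dict[str, list[tuple[str, float | None, float]]] = {
    "ESO": [("V19.5Gy", 19.5, 5.0), ("Dmax", None, 35.0)],
    "HRT": [("V32Gy", 32.0, 15.0), ("Dmax", None, 38.0)],
    "LNG": [("V12.5Gy", 12.5, 1500.0), ("V13.5Gy", 13.5, 1000.0)],
    "SC": [("V23Gy", 23.0, 0.35), ("Dmax", None, 30.0)],
    "GRT": [("V47Gy", 47.0, 10.0), ("Dmax", None, 53.0)],
    "TRA": [("V16.5Gy", 16.5, 4.0), ("Dmax", None, 40.0)],
}


def dvh(dose: DoseGrid, mask: StructureMask, bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative at-or-above DVH of a structure on uniform dose bins."""
    check_same_grid(dose, mask)
    if mask.is_empty:
        raise ValueError(f"cannot compute a DVH of empty mask {mask.name!r}")
    vals = dose.values[mask.voxels]
    vox = dose.grid.voxel_volume_cc
    n_bins = int(np.ceil(vals.max() / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    counts, _ = np.histogram(vals, bins=np.append(edges, np.inf))
    at_or_above = counts[::-1].cumsum()[::-1] * vox
    return DVHCurve(edges, at_or_above)


def tg101_metrics(dose: DoseGrid, masks: dict[str, StructureMask]) -> pd.DataFrame:
    """TG-101 style metric table: Vx (cc), Dmax, Dmean per OAR vs its limit.

    Organs missing from ``masks`` are flagged (``value`` NaN) and the rest are
    still computed. Dmax is the single-voxel maximum.
    """
    vox = dose.grid.voxel_volume_cc
    rows = []
    for organ, limits in TG101_LIMITS.items():
        mask = masks.get(organ)
        present = mask is not None and not mask.is_empty
        vals = dose.values[mask.voxels] if present else None
        for metric, threshold, limit in limits:
            if not present:
                rows.append((organ, metric, np.nan, limit, False, True))
                continue
            if metric == "Dmax":
                value = float(vals.max())
            else:
                value = float((vals >= threshold).sum()) * vox
            rows.append((organ, metric, value, limit, bool(value < limit), False))
        if present:
            rows.append((organ, "Dmean", float(vals.mean()), np.nan, True, False))
    return pd.DataFrame(rows, columns=["oar", "metric", "value", "limit", "passed", "missing"])


def signed_min_distance(a: StructureMask, b: StructureMask) -> float:
    """Signed minimum distance (cm) between two structures.

    Disjoint: the minimum Euclidean distance between the voxel sets (> 0).
    Overlapping: negative, magnitude = deepest penetration of either
    structure into the other (max over the intersection of the distance to
    the penetrated structure's boundary).
    """
    check_same_grid(a, b)
    if a.is_empty or b.is_empty:
        raise ValueError("signed distance of an empty mask is undefined")
    spacing = a.grid.spacing
    inter = a.voxels & b.voxels
    if not inter.any():
        d_to_a = distance_transform_edt(~a.voxels, sampling=spacing)
        return float(d_to_a[b.voxels].min())
    depth_a = distance_transform_edt(a.voxels, sampling=spacing)
    depth_b = distance_transform_edt(b.voxels, sampling=spacing)
    return -float(max(depth_a[inter].max(), depth_b[inter].max()))


def rom(gtv_phase0: StructureMask, gtv_phase50: StructureMask,
        oar_phase0: StructureMask, oar_phase50: StructureMask) -> ROMResult:
    """Relative organ motion from the inhale- and exhale-phase mask pairs."""
    return ROMResult(
        d_inh_cm=signed_min_distance(gtv_phase0, oar_phase0),
        d_exh_cm=signed_min_distance(gtv_phase50, oar_phase50),
    )


def sparing_regression(records: list[SparingRecord]) -> dict:
    """OLS of sparing on ROM with a two-sided t-test on the slope."""
    if len(records) < 3:
        raise ValueError("need at least 3 sparing records for a regression")
    x = np.array([r.rom_cm for r in records])
    y = np.array([r.sparing for r in records])
    if np.ptp(x) == 0:
        raise ValueError("zero ROM variance; regression is degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "p_value": float(model.pvalues[1]),
        "slope_stderr": float(model.bse[1]),
        "r_squared": float(model.rsquared),
        "n": len(records),
    }


def proximity_profile(records: list[SparingRecord],
                      edges_cm: tuple[float, ...] = (0.0, 1.5, 2.0)) -> pd.DataFrame:
    """Mean sparing binned by OAR-to-target proximity ``d_inh``.

    Overlapping OARs (``d_inh < 0``) get their own bin; the last bin is
    open-ended. Empty bins are absent from the result, not reported as zero.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    bounds = [-np.inf, *edges_cm, np.inf]
    labels = ["overlap"] + [f"[{a:g}, {b:g})" for a, b in zip(edges_cm[:-1], edges_cm[1:])] \
        + [f">= {edges_cm[-1]:g}"]
    rows = []
    for lo, hi, label in zip(bounds[:-1], bounds[1:], labels):
        sel = [r for r in records if lo <= r.d_inh_cm < hi]
        if sel:
            rows.append((label, lo, hi, np.mean([r.sparing for r in sel]), len(sel)))
    return pd.DataFrame(rows, columns=["bin", "lo_cm", "hi_cm", "mean_sparing", "n"])


def irradiated_volume_reduction(itv_dose: DoseGrid, tracked_dose: DoseGrid,
                                body: StructureMask, prescription_gy: float,
                                threshold_fraction: float = 0.5) -> float:
    """Percent reduction of the BODY volume receiving >= a prescription fraction."""
    check_same_grid(itv_dose, tracked_dose, body)
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    level = threshold_fraction * prescription_gy
    vox = body.grid.voxel_volume_cc
    v_itv = float((itv_dose.values[body.voxels] >= level).sum()) * vox
    v_trk = float((tracked_dose.values[body.voxels] >= level).sum()) * vox
    if v_itv == 0:
        raise ValueError("ITV irradiated volume is zero at this threshold")
    return 100.0 * (v_itv - v_trk) / v_itv
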