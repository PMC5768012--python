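"""File formats: NIfTI volumes, CSV traces/PDFs/tables, JSON plans and configs.

Volumes (densities, masks, doses, displacement fields) are NIfTI with a
diagonal affine built from the grid spacing and origin (world units cm,
axis order x, y, z). Breathing traces are 2-column CSV (time_s, amplitude);
phase PDFs are 8-value CSV/JSON keyed by phase label; plans and cohort
reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .breathing import BreathingTrace, PhasePDF
from .core import PHASE_LABELS, DeformationField, DoseGrid, GridSpec
from .phantom import OARSpec, Phantom4D, PhantomEntry
from .planning import Aperture, Beam, Plan

__all__ = [
    "grid_affine",
    "save_volume",
    "load_volume",
    "save_trace",
    "load_trace",
    "save_pdf",
    "load_pdf",
    "save_plan",
    "load_plan",
    "save_phantom",
    "load_cohort_config",
]


def grid_affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def save_volume(path, values: np.ndarray, grid: GridSpec) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid_affine(grid))
    img.header.set_xyzt_units("mm")  # nominal; world units are cm throughout
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj)
    return data, GridSpec(data.shape[:3], spacing, origin)


def save_trace(path, trace: BreathingTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "amplitude": trace.amplitudes}).to_csv(
        path, index=False)


def load_trace(path) -> BreathingTrace:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace CSV needs 2 columns: time_s, amplitude")
    return BreathingTrace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def save_pdf(path, pdf: PhasePDF) -> None:
    path = Path(path)
    payload = {str(k): v for k, v in pdf.as_dict().items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        pd.DataFrame({"phase_pct": PHASE_LABELS, "weight": pdf.weights}).to_csv(
            path, index=False)


def load_pdf(path) -> PhasePDF:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return PhasePDF(np.array([payload[str(k)] for k in PHASE_LABELS]))
    df = pd.read_csv(path)
    return PhasePDF(df["weight"].to_numpy())


def _aperture_dict(ap: Aperture) -> dict:
    return {
        "pitch_cm": ap.pitch_cm,
        "rows": [{"index": int(k), "open": None if np.isnan(lo) else [float(lo), float(hi)]}
                 for k, (lo, hi) in zip(ap.row_indices, ap.openings)],
    }


def _aperture_from_dict(d: dict) -> Aperture:
    idx = [r["index"] for r in d["rows"]]
    openings = [(r["open"] if r["open"] is not None else [np.nan, np.nan])
                for r in d["rows"]]
    return Aperture(d["pitch_cm"], np.array(idx), np.array(openings))


def save_plan(path, plan: Plan) -> None:
    payload = {
        "strategy": plan.strategy,
        "prescription_gy": plan.prescription_gy,
        "fractions": plan.fractions,
        "meta": plan.meta,
        "beams": [{"gantry_deg": b.gantry_deg, "isocenter_cm": list(b.isocenter_cm),
                   "sad_cm": b.sad_cm, "leaf_width_cm": b.leaf_width_cm}
                  for b in plan.beams],
        "apertures": [[_aperture_dict(a) for a in per_beam] for per_beam in plan.apertures],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_plan(path) -> Plan:
    d = json.loads(Path(path).read_text())
    beams = [Beam(b["gantry_deg"], tuple(b["isocenter_cm"]), b["sad_cm"], b["leaf_width_cm"])
             for b in d["beams"]]
    apertures = [[_aperture_from_dict(a) for a in per_beam] for per_beam in d["apertures"]]
    return Plan(d["strategy"], beams, apertures, d["prescription_gy"], d["fractions"],
                d.get("meta", {}))


def save_phantom(outdir, phantom: Phantom4D) -> None:
    """One NIfTI per phase per channel (density + each mask) plus motion JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p, phase in enumerate(phantom.phases):
        save_volume(outdir / f"phase{p}_density.nii.gz", phase.density, phantom.grid)
        for name, mask in phase.masks.items():
            save_volume(outdir / f"phase{p}_mask_{name}.nii.gz",
                        mask.voxels.astype(np.uint8), phantom.grid)
    meta = {
        "phase_labels_pct": list(PHASE_LABELS),
        "trajectories_cm": {k: v.tolist() for k, v in phantom.motion.trajectories.items()},
        "grid": {"shape": list(phantom.grid.shape), "spacing_cm": list(phantom.grid.spacing),
                 "origin_cm": list(phantom.grid.origin)},
    }
    if phantom.entry is not None:
        meta["entry"] = _entry_dict(phantom.entry)
    (outdir / "phantom.json").write_text(json.dumps(meta, indent=2))


def save_field(path, field: DeformationField) -> None:
    save_volume(path, field.vectors, field.grid)


def save_dose(path, dose: DoseGrid) -> None:
    save_volume(path, dose.values, dose.grid)


def load_dose(path) -> DoseGrid:
    values, grid = load_volume(path)
    return DoseGrid(values, grid)


def _entry_dict(entry: PhantomEntry) -> dict:
    d = dataclasses.asdict(entry)
    d["oars"] = [dataclasses.asdict(o) for o in entry.oars]
    return d


def entry_from_dict(d: dict) -> PhantomEntry:
    d = dict(d)
    oars = tuple(OARSpec(**o) for o in d.pop("oars", []))
    return PhantomEntry(oars=oars, **d)


def load_cohort_config(path) -> list[PhantomEntry]:
    """Cohort description from YAML/JSON: a list of phantom entries."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    entries = data["cohort"] if isinstance(data, dict) else data
    return [entry_from_dict(e) for e in entries]
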