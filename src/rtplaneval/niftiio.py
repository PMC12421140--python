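"""NIfTI + JSON-manifest persistence for synthetic cohorts.

Layout of a cohort directory::

    <out_dir>/
      manifest.json
      cases/<case_id>/<case_id>_<roi>_<auto|manual>.nii.gz   (uint8 masks)
      cases/<case_id>/<case_id>_dose_<auto|manual>.nii.gz    (float32 Gy)

Masks are written as uint8 0/1, dose grids as float32, both with a diagonal
mm affine built from the grid spacing and origin.  The manifest records the
grid metadata, prescription, scenario and relative file paths per case, and
is the single source of case ordering for downstream stages.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, ValidationError
from .grid import PRESCRIPTIONS, PlanCase, StructureSet, VoxelGrid

MANIFEST_NAME = "manifest.json"


def _save(path: Path, data: np.ndarray, grid: VoxelGrid, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), grid.affine())
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def _load(path: Path, grid: VoxelGrid, case_id: str, what: str) -> np.ndarray:
    if not path.exists():
        raise ValidationError(f"case {case_id}: missing file for {what}: {path}")
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.shape != grid.shape:
        raise GridMismatchError(
            f"case {case_id}: {what} has shape {arr.shape}, manifest grid {grid.shape}"
        )
    return arr


def write_case(case: PlanCase, cases_dir: Path) -> dict:
    """Write one case's volumes; return its manifest entry."""
    d = cases_dir / case.case_id
    d.mkdir(parents=True, exist_ok=True)
    grid = case.grid
    files: dict[str, str] = {}
    for plan, sset in (("auto", case.auto_structures), ("manual", case.manual_structures)):
        for roi, mask in sset.masks.items():
            name = f"{case.case_id}_{roi}_{plan}.nii.gz"
            _save(d / name, mask, grid, np.uint8)
            files[f"{roi}_{plan}"] = f"cases/{case.case_id}/{name}"
    for plan, dose in (("auto", case.auto_dose), ("manual", case.manual_dose)):
        name = f"{case.case_id}_dose_{plan}.nii.gz"
        _save(d / name, dose, grid, np.float32)
        files[f"dose_{plan}"] = f"cases/{case.case_id}/{name}"
    return {
        "case_id": case.case_id,
        "prescription": case.prescription.label,
        "total_dose_gy": case.prescription.total_dose_gy,
        "fractions": case.prescription.fractions,
        "scenario": case.scenario,
        "files": files,
    }


def write_manifest(out_dir: Path, entries: list[dict], grid: VoxelGrid,
                   extra: dict | None = None) -> Path:
    manifest = {
        "grid": {
            "shape": list(grid.shape),
            "spacing_mm": list(grid.spacing),
            "origin_mm": list(grid.origin),
        },
        "n_cases": len(entries),
        "cases": entries,
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_manifest(cohort_dir: Path) -> dict:
    path = Path(cohort_dir) / MANIFEST_NAME
    if not path.exists():
        raise ValidationError(f"no {MANIFEST_NAME} in {cohort_dir}")
    return json.loads(path.read_text())


def manifest_grid(manifest: dict) -> VoxelGrid:
    g = manifest["grid"]
    return VoxelGrid(tuple(g["shape"]), tuple(g["spacing_mm"]), tuple(g["origin_mm"]))


def load_case(cohort_dir: Path, entry: dict, grid: VoxelGrid) -> PlanCase:
    """Reassemble one case from its manifest entry."""
    cohort_dir = Path(cohort_dir)
    cid = entry["case_id"]
    files = entry["files"]
    sets = {}
    for plan in ("auto", "manual"):
        masks = {}
        for key, rel in files.items():
            if key.endswith(f"_{plan}") and not key.startswith("dose_"):
                roi = key[: -len(f"_{plan}")]
                masks[roi] = _load(cohort_dir / rel, grid, cid, key).astype(bool)
        sets[plan] = StructureSet(grid=grid, masks=masks)
        sets[plan].validate()
    doses = {
        plan: _load(cohort_dir / files[f"dose_{plan}"], grid, cid, f"dose_{plan}")
        for plan in ("auto", "manual")
    }
    label = entry["prescription"]
    rx = PRESCRIPTIONS.get(label)
    if rx is None or rx.total_dose_gy != entry.get("total_dose_gy", rx.total_dose_gy):
        from .grid import Prescription

        rx = Prescription(entry["total_dose_gy"], entry["fractions"])
    return PlanCase(
        case_id=cid,
        prescription=rx,
        auto_structures=sets["auto"],
        manual_structures=sets["manual"],
        auto_dose=doses["auto"],
        manual_dose=doses["manual"],
        scenario=entry.get("scenario", "typical"),
    )


def iter_cases(cohort_dir: Path):
    """Yield PlanCases in manifest order (never filesystem order)."""
    manifest = read_manifest(cohort_dir)
    grid = manifest_grid(manifest)
    for entry in manifest["cases"]:
        yield load_case(cohort_dir, entry, grid)
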