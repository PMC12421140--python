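"""End-to-end orchestration: generate -> per-case metrics -> study report.

The cohort table carries, per case, the PTV contour-agreement metrics, the
dose metrics of both plans, and their differences (auto - manual).  PTV
dose metrics for BOTH plans are evaluated on one common reference PTV
(default: the automated one) so that paired differences measure the effect
of the contour edit on the delivered dose rather than each plan's
self-consistency; the reference is configurable (``ptv_reference``).
Prescription-normalised differences ΔDmax/Rx and ΔD95/Rx feed the
Tukey-fence acceptability analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_case
from .dose import DoseMetrics, summarize_case_dose
from .errors import ValidationError
from .geometry import summarize_case_geometry
from .grid import PlanCase
from .niftiio import iter_cases, write_case, write_manifest
from .stats import run_study

log = logging.getLogger("rtplaneval")

__all__ = ["case_row", "compute_cohort_metrics", "run_all", "write_table"]

_DELTA_STEMS = ("ci", "hi", "dmean", "dmax", "dmin", "d95")


def case_row(
    case: PlanCase,
    ptv_reference: str = "auto",
    vri_within_ptv: bool = False,
) -> dict:
    """One complete cohort-table row for a case."""
    geo = summarize_case_geometry(case)
    rx = case.prescription.total_dose_gy
    row: dict = {
        "case_id": case.case_id,
        "prescription": case.prescription.label,
        "rx_gy": rx,
        "scenario": case.scenario,
        "hd_mm": geo.hd_mm,
        "mda_mm": geo.mda_mm,
        "dsc": geo.dsc,
        "ji": geo.ji,
        "ptv_vol_auto_cc": geo.vol_auto_cc,
        "ptv_vol_manual_cc": geo.vol_manual_cc,
    }
    for oar in ("bladder", "small_bowel", "rectum"):
        row[f"auto_overlap_{oar}_cc"] = geo.overlap_auto_cc[oar]
        row[f"manual_overlap_{oar}_cc"] = geo.overlap_manual_cc[oar]
    metrics: dict[str, DoseMetrics] = {}
    for plan in ("auto", "manual"):
        m = summarize_case_dose(
            case, plan, ptv_reference=ptv_reference, vri_within_ptv=vri_within_ptv
        )
        metrics[plan] = m
        for name in DoseMetrics.PTV_METRICS + DoseMetrics.OAR_METRICS:
            row[f"{plan}_{name}"] = getattr(m, name)
    for stem in _DELTA_STEMS:
        row[f"delta_{stem}"] = getattr(metrics["auto"], stem) - getattr(
            metrics["manual"], stem
        )
    row["delta_dmax_over_rx"] = row["delta_dmax"] / rx
    row["delta_d95_over_rx"] = row["delta_d95"] / rx
    return row


def compute_cohort_metrics(
    cases,
    ptv_reference: str = "auto",
    vri_within_ptv: bool = False,
) -> pd.DataFrame:
    """Cohort table from an iterable of PlanCases or a cohort directory.

    Row order follows the input order — for a directory, the manifest
    order, never the filesystem listing.
    """
    if isinstance(cases, (str, Path)):
        cases = iter_cases(Path(cases))
    rows = []
    for case in cases:
        log.debug("metrics: %s", case.case_id)
        rows.append(case_row(case, ptv_reference, vri_within_ptv))
    if not rows:
        raise ValidationError("no cases to tabulate")
    return pd.DataFrame(rows)


def write_table(table: pd.DataFrame, path: Path) -> None:
    """CSV with 6-significant-digit floats (the package's on-disk precision)."""
    table.to_csv(path, index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    config: CohortConfig,
    out_dir,
    *,
    write_volumes: bool = True,
    ptv_reference: str = "auto",
    vri_within_ptv: bool = False,
    alpha: float = 0.05,
    iqr_k: float = 1.5,
    quartile_method: str = "linear",
    flag_combine: str = "union",
    per_prescription_fences: bool = False,
) -> tuple[dict, dict]:
    """Generate the cohort, tabulate metrics, run the study; persist all.

    Writes ``cases/`` NIfTI volumes (unless ``write_volumes=False``),
    ``metrics.csv``, ``report.json`` and ``manifest.json`` under
    ``out_dir``; returns (report, manifest).  Deterministic: one config
    yields byte-identical CSV/JSON on every run.
    """
    config.validate()
    if config.n_cases < 1:
        raise ValidationError("run_all requires a config with n_cases >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid()
    entries = []
    rows = []
    t0 = time.time()
    for i in range(config.n_cases):
        case = generate_case(config, i)
        log.info("generated %s (%s, %s)", case.case_id, case.prescription.label,
                 case.scenario)
        if write_volumes:
            entries.append(write_case(case, out / "cases"))
        else:
            entries.append({
                "case_id": case.case_id,
                "prescription": case.prescription.label,
                "total_dose_gy": case.prescription.total_dose_gy,
                "fractions": case.prescription.fractions,
                "scenario": case.scenario,
                "files": {},
            })
        rows.append(case_row(case, ptv_reference, vri_within_ptv))
    table = pd.DataFrame(rows)
    csv_path = out / "metrics.csv"
    write_table(table, csv_path)

    report = run_study(
        table,
        alpha=alpha,
        iqr_k=iqr_k,
        quartile_method=quartile_method,
        flag_combine=flag_combine,
        per_prescription_fences=per_prescription_fences,
    )
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2) + "\n")

    manifest_path = write_manifest(
        out, entries, grid,
        extra={
            "package_version": __version__,
            "config": config.to_dict(),
            "options": {
                "ptv_reference": ptv_reference,
                "vri_within_ptv": vri_within_ptv,
                "alpha": alpha,
                "iqr_k": iqr_k,
                "quartile_method": quartile_method,
                "flag_combine": flag_combine,
                "per_prescription_fences": per_prescription_fences,
            },
            "outputs": {
                "metrics_csv": {"path": "metrics.csv", "sha256": _sha256(csv_path)},
                "report_json": {"path": "report.json", "sha256": _sha256(report_path)},
            },
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        },
    )
    manifest = json.loads(manifest_path.read_text())
    return report, manifest
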