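"""DVH-based dosimetric metrics and prescription constraint checks.

Dx (D95, D50, D2, D98, ...) is the minimum dose received by the hottest x%
of a structure's volume.  It is computed from the exact sorted voxel doses
with linear interpolation at fractional ranks (rank 1 + (n-1)p on the
sorted values) — no histogram binning, so an independent sort-based oracle
can match it exactly.  Dmax/Dmin are raw voxel extrema, with no 0.03-cc
smoothing.

HI = (D2 - D98) / D50.
CI = Vri / Vptv, where Vri is by default the absolute volume of the WHOLE
grid that reaches the prescription dose ("absolute volume" reading); a
PTV-restricted variant is available via ``vri_within_ptv=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError, InvalidConfigError, UndefinedMetricError
from .grid import PlanCase, Prescription, StructureSet, VoxelGrid

__all__ = [
    "dose_at_volume",
    "homogeneity_index",
    "conformity_index",
    "DoseMetrics",
    "summarize_case_dose",
    "ConstraintReport",
    "check_constraints",
    "CONSTRAINT_LIMITS",
]


def _masked_doses(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dose.shape != mask.shape:
        raise InvalidConfigError(f"dose shape {dose.shape} != mask shape {mask.shape}")
    vals = dose[mask]
    if vals.size == 0:
        raise EmptyMaskError("dose metric requested for an empty structure")
    return vals


def dose_at_volume(dose: np.ndarray, mask: np.ndarray, x_percent: float) -> float:
    """Dx: minimum dose (Gy) received by the hottest ``x_percent``% of the
    structure.

    Monotone non-increasing in ``x_percent``; ``x_percent=100`` is Dmin.
    """
    if not (0.0 < x_percent <= 100.0):
        raise InvalidConfigError(f"x_percent must be in (0, 100], got {x_percent}")
    vals = _masked_doses(dose, mask)
    # Hottest x% <-> (100 - x)th percentile of the dose distribution.
    return float(np.quantile(vals, (100.0 - x_percent) / 100.0, method="linear"))


def homogeneity_index(dose: np.ndarray, mask: np.ndarray) -> float:
    """HI = (D2 - D98) / D50; 0 for a perfectly uniform target dose."""
    d2 = dose_at_volume(dose, mask, 2.0)
    d98 = dose_at_volume(dose, mask, 98.0)
    d50 = dose_at_volume(dose, mask, 50.0)
    if d50 <= 0:
        raise UndefinedMetricError("HI undefined: D50 is zero")
    return (d2 - d98) / d50


def conformity_index(
    dose: np.ndarray,
    ptv_mask: np.ndarray,
    prescription: Prescription,
    grid: VoxelGrid,
    *,
    vri_within_ptv: bool = False,
) -> float:
    """CI = Vri / Vptv.

    Vri = volume reaching the prescription dose (over the whole grid by
    default; restricted to the PTV when ``vri_within_ptv`` — the coverage-
    ratio variant, which is bounded by 1).
    """
    ptv_mask = grid.check_mask(ptv_mask, "ptv")
    n_ptv = int(np.count_nonzero(ptv_mask))
    if n_ptv == 0:
        raise EmptyMaskError("conformity index requested for an empty PTV")
    dose = np.asarray(dose, dtype=float)
    reached = dose >= prescription.total_dose_gy
    if vri_within_ptv:
        reached = reached & ptv_mask
    return int(np.count_nonzero(reached)) / n_ptv


@dataclass(frozen=True)
class DoseMetrics:
    """PTV and OAR dose statistics for one plan of one case (all Gy except
    the dimensionless hi/ci)."""

    dmean: float
    dmax: float
    dmin: float
    d95: float
    d2: float
    d98: float
    d50: float
    hi: float
    ci: float
    bladder_dmean: float
    femoral_head_l_dmean: float
    femoral_head_r_dmean: float
    small_bowel_dmax: float

    PTV_METRICS = ("dmean", "dmax", "dmin", "d95", "d2", "d98", "d50", "hi", "ci")
    OAR_METRICS = (
        "bladder_dmean",
        "femoral_head_l_dmean",
        "femoral_head_r_dmean",
        "small_bowel_dmax",
    )


def summarize_case_dose(
    case: PlanCase,
    plan: str,
    *,
    ptv_reference: str = "own",
    vri_within_ptv: bool = False,
) -> DoseMetrics:
    """All Table-style dose metrics for one plan ("auto" or "manual").

    ``ptv_reference`` selects the PTV mask the PTV metrics are evaluated
    against: "own" (the plan's own PTV), or "auto"/"manual" to score both
    plans on a common reference target — the convention the cohort deltas
    use, so that dose-metric differences reflect contour differences rather
    than each plan being judged only on the region it already targets.
    OAR metrics always use the plan's own structure set.
    """
    if plan not in ("auto", "manual"):
        raise InvalidConfigError(f"plan must be 'auto' or 'manual', got {plan!r}")
    if ptv_reference not in ("own", "auto", "manual"):
        raise InvalidConfigError(f"bad ptv_reference {ptv_reference!r}")
    dose = case.auto_dose if plan == "auto" else case.manual_dose
    own: StructureSet = case.auto_structures if plan == "auto" else case.manual_structures
    ref_name = plan if ptv_reference == "own" else ptv_reference
    ref_set = case.auto_structures if ref_name == "auto" else case.manual_structures
    ptv = ref_set["ptv"]

    vals = _masked_doses(dose, ptv)
    d2 = dose_at_volume(dose, ptv, 2.0)
    d98 = dose_at_volume(dose, ptv, 98.0)
    d50 = dose_at_volume(dose, ptv, 50.0)
    return DoseMetrics(
        dmean=float(vals.mean()),
        dmax=float(vals.max()),
        dmin=float(vals.min()),
        d95=dose_at_volume(dose, ptv, 95.0),
        d2=d2,
        d98=d98,
        d50=d50,
        hi=homogeneity_index(dose, ptv),
        ci=conformity_index(
            dose, ptv, case.prescription, case.grid, vri_within_ptv=vri_within_ptv
        ),
        bladder_dmean=float(_masked_doses(dose, own["bladder"]).mean()),
        femoral_head_l_dmean=float(_masked_doses(dose, own["femoral_head_l"]).mean()),
        femoral_head_r_dmean=float(_masked_doses(dose, own["femoral_head_r"]).mean()),
        small_bowel_dmax=float(_masked_doses(dose, own["small_bowel"]).max()),
    )


#: Per-schedule dose limits (strict '<' comparisons).  The small bowel has
#: no limit in either schedule and is report-only.
CONSTRAINT_LIMITS: dict[str, dict[str, tuple[str, float]]] = {
    "50Gy/25F": {
        "ptv": ("dmax", 52.5),
        "bladder": ("dmean", 40.0),
        "femoral_head_l": ("dmean", 18.0),
        "femoral_head_r": ("dmean", 18.0),
    },
    "25Gy/5F": {
        "ptv": ("dmax", 26.5),
        "bladder": ("dmean", 12.0),
        "femoral_head_l": ("dmean", 9.0),
        "femoral_head_r": ("dmean", 9.0),
    },
}


@dataclass(frozen=True)
class ConstraintReport:
    """Pass/fail of one plan's metrics against its schedule's dose limits."""

    prescription_label: str
    checks: dict[str, dict] = field(default_factory=dict)
    known_schedule: bool = True

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks.values())

    @property
    def violations(self) -> list[str]:
        return [k for k, c in self.checks.items() if not c["passed"]]


def check_constraints(metrics: DoseMetrics, prescription: Prescription) -> ConstraintReport:
    """Check a plan's metrics against the schedule's limits (strict '<').

    margin = limit - value (Gy); positive margin means the constraint is
    met with room to spare.  Unknown schedules get an empty, flagged report.
    """
    label = prescription.label
    limits = CONSTRAINT_LIMITS.get(label)
    if limits is None:
        return ConstraintReport(prescription_label=label, checks={}, known_schedule=False)
    checks = {}
    for roi, (which, limit) in limits.items():
        value = getattr(metrics, "dmax" if roi == "ptv" and which == "dmax" else f"{roi}_{which}")
        checks[f"{roi}_{which}"] = {
            "roi": roi,
            "metric": which,
            "limit_gy": limit,
            "value_gy": float(value),
            "margin_gy": float(limit - value),
            "passed": bool(value < limit),
        }
    return ConstraintReport(prescription_label=label, checks=checks)
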