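"""Cohort-level statistics: rank correlation, paired tests, Tukey-fence
outlier flagging and the clinical-acceptability rate.

The workflow mirrors a plan-QA study: Shapiro-Wilk normality is reported as
an advisory gate, Spearman rank correlation relates contour-agreement
metrics to paired dose-metric differences, paired t-tests compare OAR doses
and volumes between automated and manual plans, and plans whose
prescription-normalised ΔDmax or ΔD95 fall strictly outside the Tukey
fences [Q1 - k·IQR, Q3 + k·IQR] (k = 1.5) are flagged as requiring manual
intervention; the acceptability rate is the unflagged percentage.

No multiple-testing correction is applied (one alpha = 0.05 per test);
this matches the single-comparison-at-a-time reporting style of clinical
QA audits and is recorded in the report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateTestError,
    InsufficientDataError,
    UndefinedMetricError,
    ValidationError,
)

__all__ = [
    "spearman",
    "paired_t",
    "PairedTestResult",
    "iqr_flags",
    "OutlierEntry",
    "acceptability",
    "run_study",
    "GEOMETRIC_METRICS",
    "DELTA_METRICS",
]

#: Geometric metrics entering the correlation matrix (rows).
GEOMETRIC_METRICS = ("hd_mm", "mda_mm", "dsc", "ji")
#: PTV dose-metric deltas entering the correlation matrix (columns).
DELTA_METRICS = ("delta_ci", "delta_hi", "delta_dmean", "delta_dmax",
                 "delta_dmin", "delta_d95")
#: Normalised deltas the acceptability analysis fences.
FENCED_METRICS = ("delta_dmax_over_rx", "delta_d95_over_rx")

#: Paired comparisons reported (column stems; auto_/manual_ prefixed pairs).
PAIRED_COMPARISONS = (
    "bladder_dmean",
    "femoral_head_l_dmean",
    "femoral_head_r_dmean",
    "small_bowel_dmax",
    "ptv_vol_cc",
    "overlap_bladder_cc",
    "overlap_small_bowel_cc",
    "overlap_rectum_cc",
)


def spearman(xs, ys) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, two-sided p) where p uses the t-approximation with n - 2
    degrees of freedom.  Errors on constant input (undefined correlation).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValidationError("spearman requires two equal-length 1-D vectors")
    if len(xs) < 3:
        raise InsufficientDataError("spearman requires n >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedMetricError("spearman undefined for a constant vector")
    res = sps.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PairedTestResult:
    metric: str
    n: int
    mean_auto: float
    mean_manual: float
    mean_diff: float
    t: float
    p: float
    shapiro_p: float

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n": self.n,
            "mean_auto": self.mean_auto,
            "mean_manual": self.mean_manual,
            "mean_diff": self.mean_diff,
            "t": self.t,
            "p": self.p,
            "shapiro_p": self.shapiro_p,
        }


def paired_t(a, b, metric: str = "") -> PairedTestResult:
    """Two-tailed paired t-test of a vs b (differences a - b).

    Shapiro-Wilk p on the differences is reported alongside as an advisory
    normality gate; the t-test is computed regardless.  Errors when the
    differences have zero variance (t undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired_t requires two equal-length 1-D vectors")
    n = len(a)
    if n < 3:
        raise InsufficientDataError("paired_t requires n >= 3")
    d = a - b
    if np.ptp(d) == 0:
        raise DegenerateTestError("paired differences have zero variance")
    t, p = sps.ttest_rel(a, b)
    sw_p = float(sps.shapiro(d).pvalue)
    return PairedTestResult(
        metric=metric,
        n=n,
        mean_auto=float(a.mean()),
        mean_manual=float(b.mean()),
        mean_diff=float(d.mean()),
        t=float(t),
        p=float(p),
        shapiro_p=sw_p,
    )


_QUANTILE_METHODS = {"linear", "lower", "higher", "nearest", "midpoint"}


@dataclass(frozen=True)
class OutlierEntry:
    """Tukey-fence summary for one delta metric."""

    metric: str
    n: int
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    flagged: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n": self.n,
            "q1": self.q1,
            "q3": self.q3,
            "iqr": self.iqr,
            "lower_fence": self.lower_fence,
            "upper_fence": self.upper_fence,
            "n_flagged": len(self.flagged),
            "flagged_case_ids": list(self.flagged),
        }


def iqr_flags(
    values,
    ids=None,
    k: float = 1.5,
    metric: str = "",
    quartile_method: str = "linear",
) -> OutlierEntry:
    """Flag values strictly outside [Q1 - k·IQR, Q3 + k·IQR].

    Quartiles use linear interpolation between order statistics (rank
    1 + (n-1)p) by default; the convention is configurable because flags
    near a fence can depend on it.  Affine-equivariant: flags of
    a·x + b (a > 0) equal flags of x.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValidationError("iqr_flags requires a 1-D vector")
    n = len(values)
    if n < 4:
        raise InsufficientDataError(f"iqr_flags requires n >= 4, got {n}")
    if quartile_method not in _QUANTILE_METHODS:
        raise ValidationError(f"unknown quartile method {quartile_method!r}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = list(ids)
    if len(ids) != n:
        raise ValidationError("ids and values lengths differ")
    q1 = float(np.quantile(values, 0.25, method=quartile_method))
    q3 = float(np.quantile(values, 0.75, method=quartile_method))
    iqr = q3 - q1
    lo = q1 - k * iqr
    hi = q3 + k * iqr
    out = (values < lo) | (values > hi)
    return OutlierEntry(
        metric=metric,
        n=n,
        q1=q1,
        q3=q3,
        iqr=iqr,
        lower_fence=lo,
        upper_fence=hi,
        flagged=tuple(i for i, o in zip(ids, out) if o),
    )


def acceptability(flags_dmax, flags_d95, n_total: int,
                  combine: str = "union") -> float:
    """Clinical acceptability rate in percent (one decimal).

    A plan is unacceptable when flagged on ΔDmax/Rx or ΔD95/Rx ("union",
    the conservative default) or on both ("intersection").
    """
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    if combine not in ("union", "intersection"):
        raise ValidationError(f"combine must be 'union' or 'intersection', got {combine!r}")
    sa, sb = set(flags_dmax), set(flags_d95)
    flagged = sa | sb if combine == "union" else sa & sb
    return round(100.0 * (n_total - len(flagged)) / n_total, 1)


# --------------------------------------------------------------------------
# study report
# --------------------------------------------------------------------------

REPORT_VERSION = "1"

_REQUIRED_COLUMNS = (
    ["case_id", "prescription", "rx_gy", "scenario"]
    + list(GEOMETRIC_METRICS)
    + ["ptv_vol_auto_cc", "ptv_vol_manual_cc"]
    + [f"{s}_overlap_{o}_cc" for s in ("auto", "manual")
       for o in ("bladder", "small_bowel", "rectum")]
    + [f"{s}_{m}" for s in ("auto", "manual")
       for m in ("dmean", "dmax", "dmin", "d95", "d2", "d98", "d50", "hi", "ci",
                 "bladder_dmean", "femoral_head_l_dmean",
                 "femoral_head_r_dmean", "small_bowel_dmax")]
    + list(DELTA_METRICS) + list(FENCED_METRICS)
)


def validate_table(table: pd.DataFrame) -> None:
    """Completeness check: every required column present, no missing cells."""
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"cohort table missing columns: {missing_cols}")
    na = table[list(_REQUIRED_COLUMNS)].isna()
    if na.any().any():
        cells = [
            f"{table['case_id'].iloc[i] if 'case_id' in table else i}:{c}"
            for i, c in zip(*np.where(na.values))
        ]
        raise ValidationError(f"cohort table has missing cells: {cells[:20]}")


def _geometric_summary(table: pd.DataFrame) -> dict:
    out = {}
    for m in GEOMETRIC_METRICS:
        v = table[m].to_numpy(dtype=float)
        out[m] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    return out


def _safe_spearman(xs, ys):
    try:
        rho, p = spearman(xs, ys)
        return {"rho": rho, "p": p}
    except (UndefinedMetricError, InsufficientDataError):
        return {"rho": None, "p": None}


def _safe_paired(table, stem):
    a = table[f"auto_{stem}" if stem != "ptv_vol_cc" else "ptv_vol_auto_cc"]
    b = table[f"manual_{stem}" if stem != "ptv_vol_cc" else "ptv_vol_manual_cc"]
    if stem.startswith("overlap_"):
        a = table[f"auto_{stem}"]
        b = table[f"manual_{stem}"]
    try:
        return paired_t(a.to_numpy(float), b.to_numpy(float), metric=stem).to_dict()
    except (DegenerateTestError, InsufficientDataError) as exc:
        return {"metric": stem, "n": int(len(a)), "error": str(exc)}


def _prescription_summary(table: pd.DataFrame) -> dict:
    """Mean ± sd of the OAR metrics per prescription group and plan."""
    out = {}
    for label, sub in table.groupby("prescription", sort=True):
        entry = {"n": int(len(sub))}
        for stem in ("bladder_dmean", "femoral_head_l_dmean",
                     "femoral_head_r_dmean", "small_bowel_dmax"):
            for plan in ("auto", "manual"):
                v = sub[f"{plan}_{stem}"].to_numpy(float)
                entry[f"{plan}_{stem}"] = {
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                }
        out[label] = entry
    return out


def run_study(
    table: pd.DataFrame,
    alpha: float = 0.05,
    iqr_k: float = 1.5,
    quartile_method: str = "linear",
    flag_combine: str = "union",
    per_prescription_fences: bool = False,
) -> dict:
    """Full statistical stage on a complete cohort table.

    Returns a JSON-serialisable report with fixed key order: geometric
    distribution summaries, the Spearman matrix of geometric metrics vs PTV
    dose-metric deltas, paired t-tests (OAR doses, PTV volume, PTV∩OAR
    overlaps), Tukey-fence outlier reports on the prescription-normalised
    ΔDmax and ΔD95, and the acceptability rate.
    """
    validate_table(table)
    n = len(table)
    ids = table["case_id"].astype(str).tolist()

    corr = {}
    for g in GEOMETRIC_METRICS:
        corr[g] = {d: _safe_spearman(table[g].to_numpy(float),
                                     table[d].to_numpy(float))
                   for d in DELTA_METRICS}

    paired = {stem: _safe_paired(table, stem) for stem in PAIRED_COMPARISONS}

    outliers = {}
    flag_sets = {}
    for m in FENCED_METRICS:
        if per_prescription_fences:
            flagged = []
            entries = {}
            for label, sub in table.groupby("prescription", sort=True):
                if len(sub) < 4:
                    continue
                e = iqr_flags(sub[m].to_numpy(float),
                              sub["case_id"].astype(str).tolist(),
                              k=iqr_k, metric=m, quartile_method=quartile_method)
                entries[label] = e.to_dict()
                flagged.extend(e.flagged)
            outliers[m] = {"per_prescription": entries}
            flag_sets[m] = set(flagged)
        else:
            e = iqr_flags(table[m].to_numpy(float), ids, k=iqr_k, metric=m,
                          quartile_method=quartile_method)
            outliers[m] = e.to_dict()
            flag_sets[m] = set(e.flagged)

    sa, sb = flag_sets[FENCED_METRICS[0]], flag_sets[FENCED_METRICS[1]]
    combined = sorted(sa | sb) if flag_combine == "union" else sorted(sa & sb)
    rate = acceptability(sa, sb, n, combine=flag_combine)

    return {
        "report_version": REPORT_VERSION,
        "options": {
            "alpha": alpha,
            "iqr_k": iqr_k,
            "quartile_method": quartile_method,
            "flag_combine": flag_combine,
            "per_prescription_fences": per_prescription_fences,
            "multiple_testing_correction": "none",
        },
        "n_cases": n,
        "geometric_summary": _geometric_summary(table),
        "spearman": corr,
        "paired_tests": paired,
        "outliers": outliers,
        "acceptability": {
            "n_total": n,
            "n_flagged": len(combined),
            "flagged_case_ids": combined,
            "rate_percent": rate,
        },
        "prescription_summary": _prescription_summary(table),
    }
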