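"""Synthetic paired-plan cohort generator.

Emulates a pelvic radiotherapy QA cohort: for each case an "automated"
structure set is synthesised from parametric anatomy, a "manual" set is
derived from it by a contraction-biased stochastic contour edit (clinicians
predominantly contract auto-contours, most strongly near the rectum), and
an idealised dose distribution is computed for each set.  Scenarios model
the two failure modes seen in practice: superior-inferior truncation of the
target and one-sided lateral asymmetry.

Everything is a pure function of the configuration, including its master
seed: per-case substreams are derived as (seed, case_index, stage), so a
cohort is bit-reproducible and stable under changes of ``n_cases`` up to
truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import GenerationError, InvalidConfigError
from .grid import (
    PRESCRIPTIONS,
    REQUIRED_ROIS,
    PlanCase,
    Prescription,
    StructureSet,
    VoxelGrid,
)

__all__ = [
    "AnatomyParams",
    "PerturbParams",
    "DoseParams",
    "CohortConfig",
    "synthesize_anatomy",
    "perturb_to_manual",
    "synthesize_dose",
    "generate_cohort",
]

SCENARIOS = ("typical", "si_truncated", "asymmetric")

#: Prescription composition of the reference cohort (n = 117).
DEFAULT_ALLOCATION = {"25Gy/5F": 77, "50Gy/25F": 36, "other": 4}


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnatomyParams:
    """Parametric pelvic anatomy (all lengths mm, fractions dimensionless).

    The PTV is a superellipsoid elongated along SI (near-cylindrical with
    rounded caps); OARs are spheres/cylinders placed around it.  Per-case
    jitter scales semi-axes and shifts centres so volumes spread over a
    realistic range (~300-550 cm³ for the PTV by default).
    """

    ptv_semiaxes_mm: tuple[float, float, float] = (37.0, 34.0, 62.0)
    ptv_si_exponent: float = 6.0
    jitter_lo: float = 0.91
    jitter_hi: float = 1.09
    center_jitter_mm: float = 4.0
    bladder_radius_mm: float = 24.0
    femoral_radius_mm: float = 21.0
    rectum_radius_mm: float = 11.0
    small_bowel_radius_mm: float = 18.0


@dataclass(frozen=True)
class PerturbParams:
    """Contour-edit model parameters.

    The manual mask is the sub-level set ``sdf < f`` of the auto mask's
    signed distance, where f is a Gaussian-smoothed random displacement
    field (spatial correlation length ``smoothing_mm``) with mean
    ``bias_mm`` (< 0 = net contraction) and standard deviation
    ``amplitude_mm``, minus an extra contraction of up to
    ``rectum_contraction_mm`` that decays away from the rectum with length
    ``rectum_tau_mm``.

    Scenario extras: SI truncation removes whole axial slices from one end
    of the PTV, the extent drawn log-normally (median ``si_extent_mm``,
    log-sd ``si_extent_sigma``; sigma = 0 gives a fixed extent).  The
    asymmetric scenario adds a one-sided lateral contraction ramping to
    ``asym_depth_mm`` at the far lateral edge.
    """

    amplitude_mm: float = 1.5
    bias_mm: float = -0.5
    smoothing_mm: float = 10.0
    rectum_contraction_mm: float = 1.0
    rectum_tau_mm: float = 5.0
    si_extent_mm: float = 6.0
    si_extent_sigma: float = 0.7
    asym_depth_mm: float = 4.0
    perturb_oars: bool = False

    def validate(self) -> None:
        for name in ("amplitude_mm", "smoothing_mm", "rectum_contraction_mm",
                     "rectum_tau_mm", "si_extent_mm", "si_extent_sigma",
                     "asym_depth_mm"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DoseParams:
    """Idealised dose model.

    Inside the planned PTV the dose is the prescription; outside it falls
    off as exp(-d / penumbra_mm) in distance d from the PTV.  A Gaussian
    hot spot of relative amplitude ``hotspot_frac`` (placed at a seeded
    offset from the PTV centroid) and smooth Gaussian noise of standard
    deviation ``noise_sd_gy`` are added; the result is clipped to
    [0, dmax_cap_frac x prescription].
    """

    penumbra_mm: float = 8.0
    hotspot_frac: float = 0.02
    hotspot_width_frac: float = 0.35
    noise_sd_gy: float = 0.2
    noise_smoothing_mm: float = 5.0
    dmax_cap_frac: float = 1.10

    def validate(self) -> None:
        if self.penumbra_mm < 0:
            raise InvalidConfigError("penumbra_mm must be >= 0")
        if self.noise_sd_gy < 0:
            raise InvalidConfigError("noise_sd_gy must be >= 0")
        if self.hotspot_frac < 0 or self.hotspot_width_frac <= 0:
            raise InvalidConfigError("hot-spot parameters must be positive")
        if self.dmax_cap_frac < 1.0:
            raise InvalidConfigError("dmax_cap_frac must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines a cohort, including the master seed."""

    n_cases: int = 117
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 96)
    grid_spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    grid_origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    anatomy: AnatomyParams = field(default_factory=AnatomyParams)
    perturb: PerturbParams = field(default_factory=PerturbParams)
    dose: DoseParams = field(default_factory=DoseParams)
    p_si_truncated: float = 0.12
    p_asymmetric: float = 0.08
    allocation: dict[str, int] | None = None

    def validate(self) -> None:
        if self.n_cases < 0:
            raise InvalidConfigError(f"n_cases must be >= 0, got {self.n_cases}")
        for p in (self.p_si_truncated, self.p_asymmetric):
            if not (0.0 <= p <= 1.0):
                raise InvalidConfigError("scenario probabilities must lie in [0, 1]")
        if self.p_si_truncated + self.p_asymmetric > 1.0 + 1e-12:
            raise InvalidConfigError("scenario probabilities sum to more than 1")
        self.perturb.validate()
        self.dose.validate()
        if self.allocation is not None:
            unknown = set(self.allocation) - set(PRESCRIPTIONS)
            if unknown:
                raise InvalidConfigError(f"unknown prescription labels: {sorted(unknown)}")
            if any(v < 0 for v in self.allocation.values()):
                raise InvalidConfigError("allocation counts must be >= 0")
            if sum(self.allocation.values()) != self.n_cases:
                raise InvalidConfigError(
                    f"allocation counts sum to {sum(self.allocation.values())}, "
                    f"expected n_cases = {self.n_cases}"
                )

    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_shape, self.grid_spacing_mm, self.grid_origin_mm)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("grid_shape", "grid_spacing_mm", "grid_origin_mm"):
            d[key] = list(d[key])
        d["anatomy"]["ptv_semiaxes_mm"] = list(d["anatomy"]["ptv_semiaxes_mm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key, sub in (("anatomy", AnatomyParams), ("perturb", PerturbParams),
                         ("dose", DoseParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in d[key].items()})
        for key in ("grid_shape", "grid_spacing_mm", "grid_origin_mm"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# --------------------------------------------------------------------------
# anatomy
# --------------------------------------------------------------------------

def _coords_mm(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = grid.coordinate_axes()
    return (
        ax[0][:, None, None].astype(np.float32),
        ax[1][None, :, None].astype(np.float32),
        ax[2][None, None, :].astype(np.float32),
    )


def synthesize_anatomy(
    grid: VoxelGrid,
    seed,
    params: AnatomyParams | None = None,
) -> StructureSet:
    """Generate one patient's automated structure set on ``grid``.

    Deterministic in (grid, seed, params).  Raises
    :class:`~rtplaneval.errors.GenerationError` naming the first ROI that
    cannot be placed when the grid is too small.
    """
    params = params or AnatomyParams()
    rng = np.random.default_rng(seed)
    X, Y, Z = _coords_mm(grid)
    extent = np.array(grid.shape) * np.array(grid.spacing)
    center = np.asarray(grid.origin) + extent / 2.0

    jit = rng.uniform(params.jitter_lo, params.jitter_hi, size=3)
    cjit = rng.uniform(-params.center_jitter_mm, params.center_jitter_mm, size=3)
    # OAR jitters drawn unconditionally so the stream layout is fixed.
    oar_jit = rng.uniform(params.jitter_lo, params.jitter_hi, size=4)
    oar_cjit = rng.uniform(-params.center_jitter_mm, params.center_jitter_mm, size=(4, 3))

    a, b, c = np.array(params.ptv_semiaxes_mm) * jit
    cptv = center + np.array([0.0, 8.0, -10.0]) + cjit
    p = params.ptv_si_exponent
    ptv = (
        ((X - cptv[0]) / a) ** 2
        + ((Y - cptv[1]) / b) ** 2
        + np.abs((Z - cptv[2]) / c) ** p
    ) <= 1.0

    def sphere(cx, cy, cz, r):
        return ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) <= r * r

    cb = center + np.array([0.0, -42.0, 35.0]) + oar_cjit[0]
    bladder = sphere(*cb, params.bladder_radius_mm * oar_jit[0])

    rfem = params.femoral_radius_mm * oar_jit[1]
    cfl = center + np.array([-58.0, 2.0, -15.0]) + oar_cjit[1]
    cfr = center + np.array([58.0, 2.0, -15.0]) + oar_cjit[1] * np.array([-1, 1, 1])
    # Femoral heads are never part of the target; keep them disjoint from
    # the PTV even at extreme size/placement jitter.
    femoral_l = sphere(*cfl, rfem) & ~ptv
    femoral_r = sphere(*cfr, rfem) & ~ptv

    crec = center + np.array([0.0, 28.0, 0.0]) + oar_cjit[2]
    rrec = params.rectum_radius_mm * oar_jit[2]
    rectum = (
        ((X - crec[0]) ** 2 + (Y - crec[1]) ** 2 <= rrec * rrec)
        & (Z >= cptv[2] - c - 10.0)
        & (Z <= cptv[2] + c * 0.6)
    )

    csb = center + np.array([0.0, -10.0, 75.0]) + oar_cjit[3]
    rsb = params.small_bowel_radius_mm * oar_jit[3]
    small_bowel = (
        ((X - csb[0]) ** 2 + (Y - csb[1]) ** 2 <= rsb * rsb)
        & (np.abs(Z - csb[2]) <= 25.0)
    )

    masks = {
        "ptv": ptv,
        "bladder": bladder,
        "femoral_head_l": femoral_l,
        "femoral_head_r": femoral_r,
        "small_bowel": small_bowel,
        "rectum": rectum,
    }
    for roi in REQUIRED_ROIS:
        if not masks[roi].any():
            raise GenerationError(
                f"grid too small to place '{roi}' "
                f"(physical extent {tuple(np.round(extent, 1))} mm)"
            )
    if not (ptv & rectum).any():
        raise GenerationError("PTV and rectum do not overlap on this grid")
    return StructureSet(grid=grid, masks=masks)


# --------------------------------------------------------------------------
# contour perturbation
# --------------------------------------------------------------------------

def _centered_sdf(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Signed distance (mm) from voxel centres to the mask surface,
    negative inside.  Half-voxel corrected so that thresholding at 0
    reproduces the mask exactly."""
    spacing = grid.spacing
    half = float(min(spacing)) / 2.0
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    sdf = outside - inside
    return sdf - np.sign(sdf) * half


def _smooth_unit_field(rng: np.random.Generator, grid: VoxelGrid,
                       smoothing_mm: float) -> np.ndarray:
    """Zero-mean, unit-sd Gaussian random field with the given correlation
    length (mm)."""
    white = rng.standard_normal(grid.shape).astype(np.float32)
    if smoothing_mm > 0:
        sigma = [smoothing_mm / s for s in grid.spacing]
        fld = ndimage.gaussian_filter(white, sigma=sigma)
    else:
        fld = white
    sd = float(fld.std())
    if sd > 0:
        fld = (fld - fld.mean()) / sd
    return fld


def _perturb_mask(
    mask: np.ndarray,
    grid: VoxelGrid,
    rng: np.random.Generator,
    params: PerturbParams,
    extra_contraction_mm: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Level-set boundary edit: threshold the centred signed distance at a
    smooth random displacement field."""
    f = params.amplitude_mm * _smooth_unit_field(rng, grid, params.smoothing_mm)
    f = f + params.bias_mm - extra_contraction_mm
    if not np.any(f):  # all-zero displacement: exact identity
        return mask.copy()
    sdf = _centered_sdf(mask, grid)
    return sdf < f


def perturb_to_manual(
    auto: StructureSet,
    scenario: str,
    params: PerturbParams | None = None,
    seed=0,
) -> StructureSet:
    """Derive the physician-edited ("manual") structure set from the
    automated one.

    typical       smooth, contraction-biased boundary displacement of the
                  PTV, strongest at the PTV-rectum interface;
    si_truncated  additionally removes whole axial slices from one SI end
                  of the PTV;
    asymmetric    additionally contracts one lateral side.

    With all amplitudes zero the output equals the input exactly.  OAR
    masks are shared by reference unless ``params.perturb_oars``.
    """
    if scenario not in SCENARIOS:
        raise InvalidConfigError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    params = params or PerturbParams()
    params.validate()
    grid = auto.grid
    rng = np.random.default_rng(seed)
    ptv = auto["ptv"]

    extra = 0.0
    if params.rectum_contraction_mm > 0 and params.rectum_tau_mm > 0:
        d_rect = ndimage.distance_transform_edt(~auto["rectum"], sampling=grid.spacing)
        extra = params.rectum_contraction_mm * np.exp(
            -d_rect / params.rectum_tau_mm
        ).astype(np.float32)

    # Scenario draws happen unconditionally, in fixed order, so the random
    # stream layout does not depend on the scenario.
    trunc_u = rng.standard_normal()        # log-normal deviate for the extent
    trunc_superior = bool(rng.uniform() < 0.5)
    asym_left = bool(rng.uniform() < 0.5)

    if scenario == "asymmetric" and params.asym_depth_mm > 0:
        X = grid.coordinate_axes()[0][:, None, None]
        idx = np.argwhere(ptv)
        xs = grid.origin[0] + grid.spacing[0] * idx[:, 0]
        cx = xs.mean()
        halfwidth = max(np.abs(xs - cx).max(), grid.spacing[0])
        side = -1.0 if asym_left else 1.0
        ramp = np.maximum(0.0, side * (X - cx)) / halfwidth
        extra = extra + params.asym_depth_mm * ramp.astype(np.float32)

    manual_ptv = _perturb_mask(ptv, grid, rng, params, extra_contraction_mm=extra)
    if not manual_ptv.any():
        manual_ptv = ptv.copy()  # degenerate over-contraction: keep the target

    if scenario == "si_truncated":
        extent_mm = params.si_extent_mm
        if params.si_extent_sigma > 0 and extent_mm > 0:
            extent_mm = float(extent_mm * math.exp(params.si_extent_sigma * trunc_u))
        k = int(round(extent_mm / grid.spacing[2]))
        occupied = np.flatnonzero(manual_ptv.any(axis=(0, 1)))
        k = min(k, len(occupied) - 1)  # never empty the PTV
        if k > 0:
            cut = occupied[-k:] if trunc_superior else occupied[:k]
            manual_ptv = manual_ptv.copy()
            manual_ptv[:, :, cut] = False

    masks = {"ptv": manual_ptv}
    for roi in auto.masks:
        if roi == "ptv":
            continue
        if params.perturb_oars:
            masks[roi] = _perturb_mask(auto[roi], grid, rng, params)
            if not masks[roi].any():
                masks[roi] = auto[roi].copy()
        else:
            masks[roi] = auto[roi]
    return StructureSet(grid=grid, masks=masks)


# --------------------------------------------------------------------------
# dose synthesis
# --------------------------------------------------------------------------

def synthesize_dose(
    structures: StructureSet,
    prescription: Prescription,
    params: DoseParams | None = None,
    seed=0,
) -> np.ndarray:
    """Idealised dose grid (Gy, float32) for a plan targeting
    ``structures``' PTV.

    Deterministic in (structures, prescription, params, seed); calling with
    the same seed but a different PTV changes the dose only through the
    geometry (falloff distances, hot-spot placement), which is what lets
    paired auto/manual dose differences arise purely from contour edits.
    """
    params = params or DoseParams()
    params.validate()
    grid = structures.grid
    ptv = structures["ptv"]
    if not ptv.any():
        raise GenerationError("cannot synthesise dose for an empty PTV")
    rx = prescription.total_dose_gy
    rng = np.random.default_rng(seed)
    # Fixed draw order (direction, then noise) so auto/manual plans of one
    # case share the same random fields.
    direction = rng.standard_normal(3)
    direction /= max(np.linalg.norm(direction), 1e-12)
    noise = None
    if params.noise_sd_gy > 0:
        noise = params.noise_sd_gy * _smooth_unit_field(rng, grid, params.noise_smoothing_mm)

    if params.penumbra_mm > 0:
        d_out = ndimage.distance_transform_edt(~ptv, sampling=grid.spacing)
        dose = rx * np.exp(-d_out / params.penumbra_mm, dtype=np.float64)
    else:
        dose = np.where(ptv, float(rx), 0.0)

    if params.hotspot_frac > 0:
        idx = np.argwhere(ptv)
        mm = idx * np.array(grid.spacing) + np.array(grid.origin)
        centroid = mm.mean(axis=0)
        half = np.maximum((mm.max(axis=0) - mm.min(axis=0)) / 2.0, grid.spacing)
        c_hot = centroid + 0.3 * direction * half
        s = params.hotspot_width_frac * float(half.mean())
        X, Y, Z = _coords_mm(grid)
        r2 = (X - c_hot[0]) ** 2 + (Y - c_hot[1]) ** 2 + (Z - c_hot[2]) ** 2
        dose = dose + rx * params.hotspot_frac * np.exp(-r2 / (2.0 * s * s))

    if noise is not None:
        dose = dose + noise
    np.clip(dose, 0.0, params.dmax_cap_frac * rx, out=dose)
    return dose.astype(np.float32)


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def _proportional_allocation(n: int) -> dict[str, int]:
    """Largest-remainder scaling of the reference 77/36/4 composition."""
    labels = list(DEFAULT_ALLOCATION)
    total = sum(DEFAULT_ALLOCATION.values())
    exact = {l: DEFAULT_ALLOCATION[l] * n / total for l in labels}
    counts = {l: int(math.floor(exact[l])) for l in labels}
    short = n - sum(counts.values())
    by_rem = sorted(labels, key=lambda l: exact[l] - counts[l], reverse=True)
    for l in by_rem[:short]:
        counts[l] += 1
    return counts


def _allocation_sequence(counts: dict[str, int], n: int) -> list[str]:
    """Deterministic interleaved label sequence hitting ``counts`` exactly."""
    labels = [l for l in counts if counts[l] > 0]
    assigned = {l: 0 for l in labels}
    seq = []
    for i in range(n):
        # pick the label furthest behind its ideal share at step i+1
        l = max(labels, key=lambda l: (counts[l] * (i + 1) / n - assigned[l], counts[l]))
        assigned[l] += 1
        seq.append(l)
    return seq


def _case_scenario(u: float, p_si: float, p_asym: float) -> str:
    if u < p_si:
        return "si_truncated"
    if u < p_si + p_asym:
        return "asymmetric"
    return "typical"


def generate_case(config: CohortConfig, index: int) -> PlanCase:
    """Generate the ``index``-th case of the configured cohort."""
    grid = config.grid()
    seed = config.seed
    n = max(config.n_cases, index + 1)
    counts = config.allocation or _proportional_allocation(config.n_cases or n)
    label = _allocation_sequence(counts, sum(counts.values()))[index] \
        if index < sum(counts.values()) else "other"
    prescription = PRESCRIPTIONS[label]

    auto = synthesize_anatomy(grid, [seed, index, 0], config.anatomy)
    u = float(np.random.default_rng([seed, index, 3]).uniform())
    scenario = _case_scenario(u, config.p_si_truncated, config.p_asymmetric)
    manual = perturb_to_manual(auto, scenario, config.perturb, seed=[seed, index, 1])
    dose_seed = [seed, index, 2]
    auto_dose = synthesize_dose(auto, prescription, config.dose, seed=dose_seed)
    manual_dose = synthesize_dose(manual, prescription, config.dose, seed=dose_seed)
    return PlanCase(
        case_id=f"case{index:03d}",
        prescription=prescription,
        auto_structures=auto,
        manual_structures=manual,
        auto_dose=auto_dose,
        manual_dose=manual_dose,
        scenario=scenario,
    )


def generate_cohort(config: CohortConfig) -> list[PlanCase]:
    """Generate the full synthetic cohort described by ``config``.

    Pure function of the config: identical configs (same seed) give
    bit-identical cohorts.
    """
    config.validate()
    return [generate_case(config, i) for i in range(config.n_cases)]
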