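"""Core domain containers: voxel grid, prescription, structure set, plan case.

Axis convention throughout the package: axis 0 = left-right (LR), axis 1 =
anterior-posterior (AP), axis 2 = superior-inferior (SI).  All physical
coordinates are millimetres; ``origin`` is the position of the centre of
voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, InvalidConfigError

#: ROI names every structure set must carry.
REQUIRED_ROIS = (
    "ptv",
    "bladder",
    "femoral_head_l",
    "femoral_head_r",
    "small_bowel",
    "rectum",
)

#: OARs whose overlap with the PTV the study tracks.
OVERLAP_OARS = ("bladder", "small_bowel", "rectum")


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular (possibly anisotropic) 3D voxel grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise InvalidConfigError("grid shape/spacing/origin must be 3-vectors")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if any(s < 1 for s in self.shape):
            raise InvalidConfigError(f"grid shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise InvalidConfigError(f"grid spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal; for NIfTI round-trips)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates (mm) of voxel centres."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def check_mask(self, mask: np.ndarray, name: str = "mask") -> np.ndarray:
        arr = np.asarray(mask)
        if arr.shape != self.shape:
            raise GridMismatchError(
                f"{name} has shape {arr.shape}, expected grid shape {self.shape}"
            )
        return arr.astype(bool, copy=False)


@dataclass(frozen=True)
class Prescription:
    """Total dose and fractionation of one treatment schedule.

    ``label`` is derived: the two schedules the study distinguishes get their
    canonical names, everything else is pooled as "other".
    """

    total_dose_gy: float
    fractions: int

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0:
            raise InvalidConfigError("total_dose_gy must be > 0")
        if int(self.fractions) < 1:
            raise InvalidConfigError("fractions must be a positive integer")
        object.__setattr__(self, "fractions", int(self.fractions))

    @property
    def label(self) -> str:
        if (self.total_dose_gy, self.fractions) == (25.0, 5):
            return "25Gy/5F"
        if (self.total_dose_gy, self.fractions) == (50.0, 25):
            return "50Gy/25F"
        return "other"


#: The two named schedules, plus the "other" pool (here: 30 Gy / 10 F).
PRESCRIPTIONS = {
    "25Gy/5F": Prescription(25.0, 5),
    "50Gy/25F": Prescription(50.0, 25),
    "other": Prescription(30.0, 10),
}


@dataclass
class StructureSet:
    """Named binary ROI masks for one patient on one grid."""

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = {
            name: self.grid.check_mask(m, name) for name, m in self.masks.items()
        }

    def validate(self) -> None:
        missing = [r for r in REQUIRED_ROIS if r not in self.masks]
        if missing:
            raise InvalidConfigError(f"structure set missing required ROIs: {missing}")
        if not self.masks["ptv"].any():
            raise InvalidConfigError("PTV mask is empty")

    def __getitem__(self, roi: str) -> np.ndarray:
        return self.masks[roi]

    def roi_names(self) -> list[str]:
        return sorted(self.masks)


@dataclass
class PlanCase:
    """One synthetic patient: paired structure sets and dose grids."""

    case_id: str
    prescription: Prescription
    auto_structures: StructureSet
    manual_structures: StructureSet
    auto_dose: np.ndarray
    manual_dose: np.ndarray
    scenario: str = "typical"

    def __post_init__(self) -> None:
        grid = self.auto_structures.grid
        if self.manual_structures.grid != grid:
            raise GridMismatchError("auto and manual structure sets on different grids")
        self.auto_dose = np.asarray(self.auto_dose, dtype=np.float32)
        self.manual_dose = np.asarray(self.manual_dose, dtype=np.float32)
        for name, dose in (("auto_dose", self.auto_dose), ("manual_dose", self.manual_dose)):
            if dose.shape != grid.shape:
                raise GridMismatchError(f"{name} shape {dose.shape} != grid {grid.shape}")
            if np.any(dose < 0):
                raise InvalidConfigError(f"{name} contains negative dose values")

    @property
    def grid(self) -> VoxelGrid:
        return self.auto_structures.grid
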