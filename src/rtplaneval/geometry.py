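"""Geometric agreement metrics for paired binary masks.

Implements the four contour-comparison metrics used to score automated
against manual delineation — Dice similarity coefficient (DSC), Jaccard
index (JI), Hausdorff distance (HD) and mean surface deviation (MDA) — plus
absolute volume and pairwise-overlap volumes.

Conventions
-----------
* DSC and JI are computed on full voxel sets, not surfaces.
* HD and MDA run over boundary-voxel centres in physical mm.  A foreground
  voxel is a boundary voxel when at least one of its six face-adjacent
  neighbours is background or lies outside the grid.
* HD is the exact (100th-percentile) symmetric Hausdorff distance; MDA is
  the average symmetric surface distance: the mean, pooled over the boundary
  points of both masks, of the distance to the nearest boundary point of the
  other mask.  This is the standard reading of a mean contour deviation and
  guarantees MDA <= HD.
* Distances honour anisotropic spacing (Euclidean in mm, never voxel units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyMaskError, GridMismatchError, UndefinedMetricError
from .grid import OVERLAP_OARS, PlanCase, StructureSet, VoxelGrid

__all__ = [
    "dice",
    "jaccard",
    "surface_points",
    "hausdorff",
    "mda",
    "volume_cc",
    "overlap_cc",
    "GeometricMetrics",
    "summarize_case_geometry",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _as_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise GridMismatchError(f"mask shapes differ: {x.shape} vs {y.shape}")
    return x, y


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y| / (|X| + |Y|)."""
    x, y = _as_pair(x, y)
    nx = int(x.sum())
    ny = int(y.sum())
    if nx == 0 and ny == 0:
        raise UndefinedMetricError("Dice is undefined for two empty masks")
    inter = int(np.count_nonzero(x & y))
    return 2.0 * inter / (nx + ny)


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard index |X∩Y| / |X∪Y|."""
    x, y = _as_pair(x, y)
    union = int(np.count_nonzero(x | y))
    if union == 0:
        raise UndefinedMetricError("Jaccard is undefined for two empty masks")
    inter = int(np.count_nonzero(x & y))
    return inter / union


def surface_points(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Physical-mm centres of the boundary voxels of ``mask``.

    Boundary = foreground voxel with >= 1 face-adjacent (6-connectivity)
    background neighbour; the grid border counts as background.

    Returns an (n, 3) float array, n >= 1.
    """
    mask = grid.check_mask(mask)
    if not mask.any():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    # border_value=0 treats out-of-grid as background, so voxels on the grid
    # face are boundary voxels.
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    return idx * spacing + origin


def _directed_nn_distances(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Distance from each point of p to its nearest neighbour in q (mm)."""
    tree = cKDTree(q)
    d, _ = tree.query(p, k=1)
    return np.asarray(d, dtype=float)


def hausdorff(x: np.ndarray, y: np.ndarray, grid: VoxelGrid) -> float:
    """Symmetric Hausdorff distance between the two mask surfaces, in mm.

    HD(X, Y) = max( sup_x inf_y d(x, y), sup_y inf_x d(x, y) ) over the
    boundary point sets.
    """
    px = surface_points(x, grid)
    py = surface_points(y, grid)
    d_xy = _directed_nn_distances(px, py).max()
    d_yx = _directed_nn_distances(py, px).max()
    return float(max(d_xy, d_yx))


def mda(x: np.ndarray, y: np.ndarray, grid: VoxelGrid) -> float:
    """Mean surface deviation (average symmetric surface distance), in mm."""
    px = surface_points(x, grid)
    py = surface_points(y, grid)
    d_xy = _directed_nn_distances(px, py)
    d_yx = _directed_nn_distances(py, px)
    return float((d_xy.sum() + d_yx.sum()) / (len(d_xy) + len(d_yx)))


def volume_cc(mask: np.ndarray, grid: VoxelGrid) -> float:
    """Foreground volume in cm³ (voxel count x voxel volume)."""
    mask = grid.check_mask(mask)
    return int(np.count_nonzero(mask)) * grid.voxel_volume_cc


def overlap_cc(a: np.ndarray, b: np.ndarray, grid: VoxelGrid) -> float:
    """Volume of the voxelwise intersection, in cm³."""
    a, b = _as_pair(grid.check_mask(a), grid.check_mask(b))
    return int(np.count_nonzero(a & b)) * grid.voxel_volume_cc


@dataclass(frozen=True)
class GeometricMetrics:
    """PTV agreement metrics plus volume/overlap bookkeeping for one case."""

    dsc: float
    ji: float
    hd_mm: float
    mda_mm: float
    vol_auto_cc: float
    vol_manual_cc: float
    overlap_auto_cc: dict[str, float]
    overlap_manual_cc: dict[str, float]


def summarize_case_geometry(
    auto: StructureSet | PlanCase,
    manual: StructureSet | None = None,
) -> GeometricMetrics:
    """All geometric quantities the cohort table needs for one case.

    Accepts either a :class:`PlanCase` or a pair of structure sets.  PTV
    agreement (DSC/JI/HD/MDA), PTV volumes for both sets, and PTV∩OAR
    overlap volumes against each set's own OAR masks.
    """
    if isinstance(auto, PlanCase):
        case = auto
        auto, manual = case.auto_structures, case.manual_structures
    if manual is None:
        raise ValueError("manual structure set required")
    grid = auto.grid
    if manual.grid != grid:
        raise GridMismatchError("structure sets on different grids")
    ptv_a = auto["ptv"]
    ptv_m = manual["ptv"]
    return GeometricMetrics(
        dsc=dice(ptv_a, ptv_m),
        ji=jaccard(ptv_a, ptv_m),
        hd_mm=hausdorff(ptv_a, ptv_m, grid),
        mda_mm=mda(ptv_a, ptv_m, grid),
        vol_auto_cc=volume_cc(ptv_a, grid),
        vol_manual_cc=volume_cc(ptv_m, grid),
        overlap_auto_cc={o: overlap_cc(ptv_a, auto[o], grid) for o in OVERLAP_OARS},
        overlap_manual_cc={o: overlap_cc(ptv_m, manual[o], grid) for o in OVERLAP_OARS},
    )
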