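"""Volume-overlap and surface-distance metrics for segmentation validation.

Compares a test mask A against a gold-standard mask B with the standard
voxel-count overlap measures (Dice, TPR, PPV, RV) and the symmetric average
and maximum Hausdorff distances (aHD, mHD) between surface-voxel sets, with
Euclidean distances measured in mm so anisotropic grids are handled
correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Mask


@dataclass(frozen=True)
class OverlapMetrics:
    """Voxel-count overlap between a test mask A and gold standard B.

    DICE = 2|A∩B| / (|A|+|B|); TPR = |A∩B|/|B| (sensitivity);
    PPV = |A∩B|/|A|; RV = |A|/|B| (relative volume).
    """

    dice: float
    tpr: float
    ppv: float
    rv: float

    def as_dict(self) -> dict[str, float]:
        return {"DICE": self.dice, "TPR": self.tpr, "PPV": self.ppv, "RV": self.rv}


@dataclass(frozen=True)
class SurfaceDistances:
    """Symmetric surface distances in mm.

    aHD averages the two directed nearest-surface distance sums over
    |S(A)| + |S(B)|; mHD is the larger of the two directed maxima.
    """

    ahd_mm: float
    mhd_mm: float

    def as_dict(self) -> dict[str, float]:
        return {"aHD_mm": self.ahd_mm, "mHD_mm": self.mhd_mm}


def _check_pair(a: Mask, b: Mask) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise ValueError("masks must share one grid")


def overlap_metrics(a: Mask, b: Mask) -> OverlapMetrics:
    """Overlap of test mask ``a`` against nonempty gold standard ``b``."""
    _check_pair(a, b)
    nb = b.count()
    if nb == 0:
        raise ValueError("gold-standard mask is empty")
    na = a.count()
    ni = int(np.logical_and(a.data, b.data).sum())
    dice = 2.0 * ni / (na + nb)
    tpr = ni / nb
    ppv = ni / na if na else 0.0
    return OverlapMetrics(dice=dice, tpr=tpr, ppv=ppv, rv=na / nb)


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_voxels(mask: Mask, connectivity: int = 1) -> np.ndarray:
    """Boolean array marking mask voxels with at least one face neighbor
    outside the mask; the volume border counts as outside."""
    if mask.count() == 0:
        raise ValueError("mask is empty")
    struct = ndimage.generate_binary_structure(3, connectivity)
    interior = ndimage.binary_erosion(mask.data, structure=struct, border_value=0)
    return np.logical_and(mask.data, ~interior)


def _surface_points_mm(mask: Mask, connectivity: int) -> np.ndarray:
    idx = np.argwhere(surface_voxels(mask, connectivity))
    return idx * np.asarray(mask.spacing)


def hausdorff(a: Mask, b: Mask, connectivity: int = 1) -> SurfaceDistances:
    """Symmetric average and maximum Hausdorff distance between the surface
    voxels of two masks, in mm.

    Implemented with a KD-tree over surface-voxel centers; on small inputs
    this agrees with the O(|S(A)|·|S(B)|) pairwise brute force to machine
    precision.
    """
    _check_pair(a, b)
    pa = _surface_points_mm(a, connectivity)
    pb = _surface_points_mm(b, connectivity)
    d_ab, _ = cKDTree(pb).query(pa)  # for each a-surface voxel, nearest b
    d_ba, _ = cKDTree(pa).query(pb)
    ahd = (d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb))
    mhd = max(d_ab.max(), d_ba.max())
    return SurfaceDistances(ahd_mm=float(ahd), mhd_mm=float(mhd))


def evaluate(a: Mask, b: Mask, connectivity: int = 1) -> dict[str, float]:
    """Full comparison report (overlap + surface distances) as one dict."""
    out = overlap_metrics(a, b).as_dict()
    out.update(hausdorff(a, b, connectivity).as_dict())
    return out
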