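"""Liver perfusion territory (LPT) splitting and split comparison.

Bilobar SIRT needs the liver divided into the left and right perfusion
territories. The expert draws a separation line on at least 3 transverse
slices (on contrast CBCT, where per-lobe arterial enhancement marks the
territory, or on CT using anatomical landmarks); a plane is then fit to the
sampled line points by total least squares and the liver mask is split by
the sign of the signed distance to that plane.

Two splits (perfusion-based vs anatomical) are compared with the volume
difference Vdiff — the fraction of liver assigned to different lobes —
the per-lobe ratios Rratio/Lratio of right-to-whole and left-to-whole
fractions, and the average/maximum Hausdorff distance between the in-liver
separator surfaces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Mask


@dataclass(frozen=True)
class LobeLine:
    """One expert separation line on a transverse slice (voxel coordinates).

    ``right_side`` is any in-plane point on the right-lobe side of the line,
    used to orient the fitted plane.
    """

    slice_index: int
    p0: tuple[float, float]
    p1: tuple[float, float]
    right_side: tuple[float, float] | None = None


@dataclass
class TransverseLineSet:
    """Separation lines on >= 3 distinct transverse slices, plus the grid
    geometry needed to map voxel coordinates to mm."""

    lines: list[LobeLine]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source: str = "CBCT"

    def __post_init__(self) -> None:
        if len({l.slice_index for l in self.lines}) < 3:
            raise ValueError("need lines on at least 3 distinct transverse slices")

    def to_json(self) -> str:
        return json.dumps({
            "source": self.source,
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "lines": [
                {"slice": l.slice_index, "p0": list(l.p0), "p1": list(l.p1),
                 "right_side": None if l.right_side is None else list(l.right_side)}
                for l in self.lines
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "TransverseLineSet":
        obj = json.loads(text)
        lines = [
            LobeLine(int(d["slice"]), tuple(d["p0"]), tuple(d["p1"]),
                     None if d.get("right_side") is None else tuple(d["right_side"]))
            for d in obj["lines"]
        ]
        return cls(lines, tuple(obj.get("spacing", (1, 1, 1))),
                   tuple(obj.get("origin", (0, 0, 0))), obj.get("source", "CBCT"))


@dataclass(frozen=True)
class PlaneModel:
    """Oriented plane in world mm: {x : normal·x = offset}, |normal| = 1.

    The normal points toward the right lobe, so ``signed_distance`` is
    positive on the right side.
    """

    normal: tuple[float, float, float]
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
            raise ValueError("plane normal must be unit length")

    def signed_distance(self, points_mm: np.ndarray) -> np.ndarray:
        return np.asarray(points_mm, dtype=float) @ np.asarray(self.normal) - self.offset

    def flipped(self) -> "PlaneModel":
        return PlaneModel(tuple(-np.asarray(self.normal)), -self.offset)


def _sample_segment(p0, p1, step: float = 0.5) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) / step)) + 1, 2)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


def fit_plane(lines: TransverseLineSet, sample_step_vox: float = 0.5) -> PlaneModel:
    """Total-least-squares plane through the sampled line points.

    Each segment is sampled densely in voxel coordinates, mapped to mm, and
    the plane minimising the orthogonal-distance sum of squares is obtained
    from the eigendecomposition of the second-moment (scatter) matrix. The
    normal is oriented so the majority of the lines' ``right_side`` markers
    fall on the positive side.
    """
    spacing = np.asarray(lines.spacing)
    origin = np.asarray(lines.origin)
    pts = []
    for l in lines.lines:
        seg = _sample_segment(l.p0, l.p1, sample_step_vox)
        vox = np.column_stack([seg, np.full(len(seg), float(l.slice_index))])
        pts.append(origin + vox * spacing)
    pts = np.vstack(pts)

    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    # points must span a 2D subspace for the plane to be determined
    if evals[1] < 1e-8 * max(evals[2], 1.0):
        raise ValueError("degenerate line samples: points span fewer than 2 dimensions")
    normal = evecs[:, 0]
    normal = normal / np.linalg.norm(normal)
    plane = PlaneModel(tuple(normal), float(normal @ centroid))

    markers = []
    for l in lines.lines:
        if l.right_side is not None:
            vox = np.array([l.right_side[0], l.right_side[1], float(l.slice_index)])
            markers.append(origin + vox * spacing)
    if markers:
        sd = plane.signed_distance(np.asarray(markers))
        if np.sum(sd > 0) < np.sum(sd < 0):
            plane = plane.flipped()
    return plane


@dataclass
class LobeSplit:
    """A liver partitioned into left and right lobes by a plane."""

    left: Mask
    right: Mask
    plane: PlaneModel

    def __post_init__(self) -> None:
        if np.logical_and(self.left.data, self.right.data).any():
            raise ValueError("lobe masks overlap")

    @property
    def left_volume_cc(self) -> float:
        return self.left.volume_cc

    @property
    def right_volume_cc(self) -> float:
        return self.right.volume_cc

    @property
    def liver_data(self) -> np.ndarray:
        return np.logical_or(self.left.data, self.right.data)

    @property
    def rtow(self) -> float:
        """Right-lobe to whole-liver volume fraction."""
        return self.right.count() / max(self.right.count() + self.left.count(), 1)

    @property
    def ltow(self) -> float:
        return self.left.count() / max(self.right.count() + self.left.count(), 1)


def split_liver(liver_mask: Mask, plane: PlaneModel) -> LobeSplit:
    """Assign every liver voxel to a lobe by the sign of its center's signed
    distance to the plane; exactly-zero distance goes to the right lobe."""
    if liver_mask.count() == 0:
        raise ValueError("liver mask is empty")
    idx = np.indices(liver_mask.shape, dtype=float)
    pts = np.stack([idx[i] * liver_mask.spacing[i] + liver_mask.origin[i] for i in range(3)], axis=-1)
    sd = pts @ np.asarray(plane.normal) - plane.offset
    right = np.logical_and(liver_mask.data, sd >= 0)
    left = np.logical_and(liver_mask.data, sd < 0)
    if not right.any() or not left.any():
        warnings.warn("plane does not intersect the liver; one lobe is empty")
    return LobeSplit(
        left=Mask.like(liver_mask, left, "left lobe"),
        right=Mask.like(liver_mask, right, "right lobe"),
        plane=plane,
    )


@dataclass(frozen=True)
class LobeComparison:
    """Disagreement between two lobe splits (A: perfusion/CBCT, B: anatomy/CT).

    ``vdiff`` is the liver fraction assigned to different lobes; ``rratio``
    (``lratio``) is RtoW (LtoW) of the B split over that of the A split;
    ``ahd_mm``/``mhd_mm`` are surface distances between the two in-liver
    separator surfaces.
    """

    vdiff: float
    rratio: float
    lratio: float
    ahd_mm: float
    mhd_mm: float

    def as_dict(self) -> dict[str, float]:
        return {"Vdiff": self.vdiff, "Rratio": self.rratio, "Lratio": self.lratio,
                "aHD_mm": self.ahd_mm, "mHD_mm": self.mhd_mm}


def _separator_surface_mm(split: LobeSplit, liver_data: np.ndarray, mask_ref: Mask) -> np.ndarray:
    """Liver voxel centers within half a voxel diagonal of the split's plane."""
    spacing = np.asarray(mask_ref.spacing)
    half_diag = 0.5 * float(np.linalg.norm(spacing))
    idx = np.argwhere(liver_data)
    pts = idx * spacing + np.asarray(mask_ref.origin)
    sd = split.plane.signed_distance(pts)
    sel = np.abs(sd) <= half_diag
    if not sel.any():
        raise ValueError("separator surface is empty within the liver")
    return pts[sel]


def compare_splits(split_a: LobeSplit, split_b: LobeSplit) -> LobeComparison:
    """Compare a CBCT-based split A against a CT-based split B.

    Vdiff = (|L_A ∩ R_B| + |L_B ∩ R_A|) / |L_B ∪ R_B|; the denominator is the
    B liver, which reduces to the common liver when both splits partition the
    same mask. Rratio and Lratio are ratios of the B split's right/left
    whole-liver fractions over the A split's, so they remain meaningful when
    the two liver masks differ.
    """
    la, ra = split_a.left.data, split_a.right.data
    lb, rb = split_b.left.data, split_b.right.data
    if la.shape != lb.shape:
        raise ValueError("splits must live on the same grid")
    denom = int(np.logical_or(lb, rb).sum())
    if denom == 0:
        raise ValueError("B split is empty")
    cross = int(np.logical_and(la, rb).sum()) + int(np.logical_and(lb, ra).sum())
    sa = _separator_surface_mm(split_a, split_a.liver_data, split_a.left)
    sb = _separator_surface_mm(split_b, split_b.liver_data, split_b.left)
    d_ab, _ = cKDTree(sb).query(sa)
    d_ba, _ = cKDTree(sa).query(sb)
    return LobeComparison(
        vdiff=cross / denom,
        rratio=split_b.rtow / split_a.rtow,
        lratio=split_b.ltow / split_a.ltow,
        ahd_mm=float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb))),
        mhd_mm=float(max(d_ab.max(), d_ba.max())),
    )
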