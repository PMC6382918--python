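"""Joint multi-modal region-growing liver segmentation.

The liver is delineated on three co-registered volumes at once — the
low-dose CT of the MAA study, the contrast CT of the FDG study, and the
FDG-PET (in SUV) — exploiting that adjacent organs which share HU with the
liver on CT differ from it in FDG uptake, and vice versa.

The operator outlines the liver on every 15th axial slice only. Between
each pair of annotated slices a *layer* is formed: the in-plane erosion
(r = 20 voxels) of the intersection of the two contours seeds a joint
region growing whose mask is the in-plane dilation (r = 20 voxels) of their
union. A candidate voxel joins the region only if, in *every* modality i,
its value lies within the stage bounds of the running mean μⁱ and standard
deviation σⁱ of the already-segmented voxels:

* stage 1 (per layer):  |v − μⁱ| <= 2 σⁱ  for all i
* stage 2 (whole liver, seeded by the union of stage-1 layers, masked by its
  20-voxel dilation):  k₁ⁱ σⁱ <= v − μⁱ <= k₂ⁱ σⁱ with
  (k₁, k₂) = (−2.5, 2) for both CTs and (−2, ∞) for PET, plus an absolute
  PET cap of SUV 2.5 (FDG-avid lesions and adjacent avid organs are kept out
  of the liver estimate).

Statistics are recomputed after every full frontier sweep, making growth
order-independent and deterministic. A 3-mm metric closing-then-opening and
a largest-component selection finalise the mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

from .core import Mask, Volume, close_mm, open_mm

_STRUCT6 = ndimage.generate_binary_structure(3, 1)

# stage-2 acceptance bounds (k1, k2) in units of sigma, per modality, in the
# fixed order (CT_MAA, CT_FDG, PET); PET additionally capped at SUV 2.5
STAGE2_BOUNDS = ((-2.5, 2.0), (-2.5, 2.0), (-2.0, np.inf))
PET_SUV_CAP = 2.5
PET_INDEX = 2


@dataclass
class SliceAnnotations:
    """Closed liver contours on sparsely annotated axial slices.

    ``contours`` maps axial slice index to a list of (N, 2) arrays of (x, y)
    voxel coordinates forming simple closed polygons.
    """

    contours: dict[int, list[np.ndarray]]
    period: int = 15

    def __post_init__(self) -> None:
        if len(self.contours) < 2:
            raise ValueError("need annotations on at least 2 slices")
        self.contours = {int(k): [np.asarray(c, dtype=float) for c in v]
                         for k, v in self.contours.items()}

    @property
    def slices(self) -> list[int]:
        return sorted(self.contours)

    def rasterize(self, slice_index: int, shape_xy: tuple[int, int]) -> np.ndarray:
        """Fill the slice's polygons into a 2D boolean (x, y) mask."""
        out = np.zeros(shape_xy, dtype=bool)
        for cont in self.contours[slice_index]:
            rr, cc = _sk_polygon(cont[:, 0], cont[:, 1], shape=shape_xy)
            out[rr, cc] = True
        return out

    def to_json(self) -> str:
        return json.dumps({
            "period": self.period,
            "contours": {str(k): [c.tolist() for c in v] for k, v in self.contours.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "SliceAnnotations":
        obj = json.loads(text)
        return cls({int(k): [np.asarray(c) for c in v] for k, v in obj["contours"].items()},
                   int(obj.get("period", 15)))


@dataclass
class LayerSeedMask:
    """Seed and growth mask for one inter-annotation layer."""

    seed: Mask
    mask: Mask
    slice_lo: int
    slice_hi: int  # inclusive

    def __post_init__(self) -> None:
        if not np.logical_and(self.seed.data, ~self.mask.data).sum() == 0:
            raise ValueError("seed must be contained in mask")
        if self.seed.count() == 0:
            raise ValueError("layer seed is empty")


def _disk_erode2d(m: np.ndarray, r: float) -> np.ndarray:
    if not m.any():
        return m.copy()
    return ndimage.distance_transform_edt(m) > r + 1e-9


def _disk_dilate2d(m: np.ndarray, r: float) -> np.ndarray:
    if not m.any():
        return m.copy()
    return ndimage.distance_transform_edt(~m) <= r + 1e-9


def build_layers(annotations: SliceAnnotations, shape: tuple[int, int, int],
                 spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                 r_vox: int = 20) -> list[LayerSeedMask]:
    """Seed/mask pairs for every pair of adjacent annotated slices.

    The seed is the in-plane ``r_vox`` erosion of the intersection of the
    two rasterized contours, extruded through the layer; the mask the
    in-plane dilation of their union. If erosion empties the intersection,
    the radius is halved until a nonempty seed remains (with a warning).
    """
    shape_xy = shape[:2]
    slices = annotations.slices
    if slices[-1] >= shape[2]:
        raise ValueError("annotated slice beyond grid extent")
    layers = []
    for s0, s1 in zip(slices[:-1], slices[1:]):
        m0 = annotations.rasterize(s0, shape_xy)
        m1 = annotations.rasterize(s1, shape_xy)
        inter = np.logical_and(m0, m1)
        union = np.logical_or(m0, m1)
        r = float(r_vox)
        seed2d = _disk_erode2d(inter, r)
        while not seed2d.any() and r >= 1.0:
            r /= 2.0
            warnings.warn(f"empty layer seed between slices {s0}-{s1}; retrying with r={r:g}")
            seed2d = _disk_erode2d(inter, r)
        if not seed2d.any():
            warnings.warn(f"layer {s0}-{s1} has no usable seed; skipped")
            continue
        mask2d = _disk_dilate2d(union, float(r_vox))
        seed3d = np.zeros(shape, dtype=bool)
        mask3d = np.zeros(shape, dtype=bool)
        seed3d[:, :, s0:s1 + 1] = seed2d[:, :, None]
        mask3d[:, :, s0:s1 + 1] = mask2d[:, :, None]
        layers.append(LayerSeedMask(
            seed=Mask(seed3d, spacing, origin, f"seed {s0}-{s1}"),
            mask=Mask(mask3d, spacing, origin, f"mask {s0}-{s1}"),
            slice_lo=s0, slice_hi=s1,
        ))
    if not layers:
        raise ValueError("no usable layers could be built from the annotations")
    return layers


def _accept(vals: np.ndarray, mean: float, std: float,
            k1: float, k2: float) -> np.ndarray:
    if std == 0.0:
        return vals == mean  # degenerate: exact-match criterion
    dev = vals - mean
    return np.logical_and(dev >= k1 * std, dev <= k2 * std)


def joint_region_grow(images: list[Volume], seed: np.ndarray, mask: np.ndarray,
                      stage: int = 1, pet_index: int = PET_INDEX,
                      pet_cap: float = PET_SUV_CAP, update: str = "sweep",
                      max_sweeps: int = 1000) -> np.ndarray:
    """Grow a region jointly constrained by all modalities.

    The frontier (6-neighbors of the current region inside the mask) is
    evaluated once per sweep against the per-modality statistics of the
    current region; all accepted voxels join simultaneously, then the
    statistics are recomputed (``update='sweep'``) or kept from the seed
    (``update='frozen'``). Terminates when a sweep adds nothing.
    """
    if update not in ("sweep", "frozen"):
        raise ValueError("update must be 'sweep' or 'frozen'")
    bounds = [(-2.0, 2.0)] * len(images) if stage == 1 else list(STAGE2_BOUNDS)
    if len(bounds) != len(images):
        raise ValueError("one bound pair per image required")
    seed = np.asarray(seed, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if np.logical_and(seed, ~mask).any():
        raise ValueError("seed must be contained in mask")
    arrs = [np.asarray(im.data, dtype=float) for im in images]

    current = seed.copy()
    frozen_stats = None
    if update == "frozen":
        frozen_stats = [(float(a[current].mean()), float(a[current].std())) for a in arrs]
    for _ in range(max_sweeps):
        stats = frozen_stats or [(float(a[current].mean()), float(a[current].std())) for a in arrs]
        frontier = np.logical_and(ndimage.binary_dilation(current, _STRUCT6), mask)
        frontier &= ~current
        if not frontier.any():
            return current
        idx = np.nonzero(frontier)
        ok = np.ones(idx[0].shape, dtype=bool)
        for i, (a, (mean, std), (k1, k2)) in enumerate(zip(arrs, stats, bounds)):
            vals = a[idx]
            ok &= _accept(vals, mean, std, k1, k2)
            if stage == 2 and i == pet_index:
                ok &= vals < pet_cap
        if not ok.any():
            return current
        current[idx[0][ok], idx[1][ok], idx[2][ok]] = True
    warnings.warn("region growing hit the sweep cap before converging")
    return current


def segment_liver(images: list[Volume], annotations: SliceAnnotations,
                  r_vox: int = 20, finalize_mm: float = 3.0,
                  update: str = "sweep", return_stages: bool = False):
    """Full semi-automatic liver segmentation.

    Stage 1 grows each inter-annotation layer independently; the union of
    the layer results seeds stage 2, masked by its 20-voxel in-plane
    dilation. A 3-mm metric closing then opening and a largest-6-connected-
    component selection replace the interactive clean-up of the clinical
    workflow.

    ``images`` must be the co-registered (CT_MAA, CT_FDG, PET-SUV) triple on
    one grid; pass median-filtered CTs for robust growth — the mask applies
    equally to the unsmoothed volumes.
    """
    ref = images[0]
    for im in images[1:]:
        if not ref.same_grid(im):
            raise ValueError("images must be co-registered on one grid")
    layers = build_layers(annotations, ref.shape, ref.spacing, ref.origin, r_vox)

    stage1 = np.zeros(ref.shape, dtype=bool)
    for layer in layers:
        stage1 |= joint_region_grow(images, layer.seed.data, layer.mask.data,
                                    stage=1, update=update)

    # stage-2 mask: 3D dilation by r_vox in index space, so the second pass
    # can also grow past the outermost annotated slices (liver caps)
    mask2 = ndimage.distance_transform_edt(~stage1) <= r_vox + 1e-9
    grown = joint_region_grow(images, stage1, mask2, stage=2, update=update)

    final = open_mm(close_mm(grown, finalize_mm, ref.spacing), finalize_mm, ref.spacing)
    final &= mask2  # morphology must not escape the stage-2 growth mask
    labels, n = ndimage.label(final, structure=_STRUCT6)
    if n == 0:
        raise ValueError("liver segmentation is empty")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    final = labels == (1 + int(np.argmax(sizes)))
    result = Mask(final, ref.spacing, ref.origin, "liver")
    if return_stages:
        return result, Mask(stage1, ref.spacing, ref.origin, "stage1"), \
            Mask(mask2, ref.spacing, ref.origin, "stage2 mask")
    return result
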