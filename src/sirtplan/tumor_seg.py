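"""Adaptive-threshold FDG tumor segmentation inside the liver.

The method generalises fixed-percentage PET thresholding by deriving a
tumor-specific threshold from each lesion's own background and maximum SUV:

1. Liver statistics: mean μ and standard deviation σ of the SUV over the
   liver mask define the core-detection threshold
   THR_init = μ + 2.802·σ (a 99.5% one-sided confidence bound).
2. Core detection: 6-connected components of {SUV >= THR_init} within the
   liver; each component is one tumor core, processed independently.
3. Per-core threshold: the core is dilated with a uniform 25-mm sphere;
   the background BG is the mean SUV of dilated-mask voxels with SUV < 2.5;
   with the core maximum, THR = BG + 0.41·(max − BG). The final mask is the
   connected component of {SUV >= THR} within the dilated mask that contains
   the core.

All statistics are computed on the unsmoothed SUV volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Mask, Volume, dilate_mm

INIT_THRESHOLD_SIGMAS = 2.802     # 99.5% confidence bound
ADAPTIVE_FRACTION = 0.41          # threshold fraction between BG and max
BG_SUV_CUTOFF = 2.5               # voxels below this SUV count as background
DILATION_RADIUS_MM = 25.0

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class LiverUptakeStats:
    """Liver SUV statistics and the derived core-detection threshold."""

    mean: float
    std: float

    @property
    def thr_init(self) -> float:
        return self.mean + INIT_THRESHOLD_SIGMAS * self.std


@dataclass
class TumorCandidate:
    """One detected lesion with its adaptive threshold and final mask."""

    core: Mask
    dilated: Mask
    bg: float
    max_suv: float
    thr: float
    final: Mask

    @property
    def volume_cc(self) -> float:
        return self.final.volume_cc

    def report(self) -> dict[str, float]:
        return {"BG": self.bg, "max": self.max_suv, "THR": self.thr,
                "volume_cc": self.volume_cc}


def liver_stats(pet_suv: Volume, liver_mask: Mask) -> LiverUptakeStats:
    """Population mean/std of the SUV over the liver mask."""
    if liver_mask.count() == 0:
        raise ValueError("liver mask is empty")
    vals = pet_suv.data[liver_mask.data]
    return LiverUptakeStats(mean=float(vals.mean()), std=float(vals.std()))


def detect_cores(pet_suv: Volume, liver_mask: Mask, thr_init: float,
                 min_voxels: int = 1) -> list[Mask]:
    """6-connected components of {SUV >= THR_init} inside the liver."""
    hot = np.logical_and(pet_suv.data >= thr_init, liver_mask.data)
    labels, n = ndimage.label(hot, structure=_STRUCT6)
    cores = []
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() >= min_voxels:
            cores.append(Mask.like(liver_mask, comp, f"tumor core {i}"))
    return cores


def tumor_threshold(core: Mask, pet_suv: Volume,
                    exclude_other_cores: Mask | None = None) -> TumorCandidate:
    """Adaptive threshold and final mask for one tumor core.

    ``exclude_other_cores`` optionally removes other lesions' voxels from the
    background estimate; by default every dilated-mask voxel with SUV below
    the 2.5 cutoff contributes.
    """
    if core.count() == 0:
        raise ValueError("tumor core is empty")
    dilated_data = dilate_mm(core.data, DILATION_RADIUS_MM, core.spacing)
    dilated = Mask.like(core, dilated_data, core.label + " dilated")

    suv = pet_suv.data
    bg_sel = np.logical_and(dilated_data, suv < BG_SUV_CUTOFF)
    if exclude_other_cores is not None:
        bg_sel &= ~exclude_other_cores.data
    if bg_sel.any():
        bg = float(suv[bg_sel].mean())
    else:
        warnings.warn("no background voxels below the SUV cutoff; using BG = 0")
        bg = 0.0

    max_suv = float(suv[core.data].max())
    if max_suv <= bg:
        warnings.warn("tumor max does not exceed background; keeping the core as final mask")
        thr = bg
        final = core.data.copy()
    else:
        thr = bg + ADAPTIVE_FRACTION * (max_suv - bg)
        above = np.logical_and(suv >= thr, dilated_data)
        labels, _ = ndimage.label(above, structure=_STRUCT6)
        core_labels = np.unique(labels[core.data])
        core_labels = core_labels[core_labels > 0]
        final = np.isin(labels, core_labels)
    return TumorCandidate(core=core, dilated=dilated, bg=bg, max_suv=max_suv,
                          thr=thr, final=Mask.like(core, final, core.label + " final"))


def segment_tumors(pet_suv: Volume, liver_mask: Mask,
                   min_core_voxels: int = 1) -> list[TumorCandidate]:
    """Full chain: liver stats -> core detection -> per-core adaptive threshold.

    Overlapping final masks are merged into the earlier candidate with a
    warning. An empty list means no voxel exceeded THR_init.
    """
    stats = liver_stats(pet_suv, liver_mask)
    cores = detect_cores(pet_suv, liver_mask, stats.thr_init, min_core_voxels)
    candidates = [tumor_threshold(core, pet_suv) for core in cores]

    merged: list[TumorCandidate] = []
    for cand in candidates:
        overlap = next((m for m in merged if np.logical_and(m.final.data, cand.final.data).any()), None)
        if overlap is None:
            merged.append(cand)
        else:
            warnings.warn("overlapping tumor masks merged")
            overlap.final = overlap.final.with_data(np.logical_or(overlap.final.data, cand.final.data))
    return merged
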