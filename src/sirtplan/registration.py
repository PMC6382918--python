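"""Registration of all pre-treatment volumes to the CT_MAA frame.

Workflow:

1. Per-lobe early/late CBCTs are aligned to each other by a multi-resolution
   rigid registration minimising the sum of squared differences (SSD); the
   aligned CBCTs are averaged into a *meta-CBCT* that covers the union field
   of view and in which the per-lobe contrast enhancement is suppressed.
2. The meta-CBCT and the CT of the FDG study are registered to the CT of the
   MAA study deformably, starting from a rigid initialisation. The
   deformation is a dense per-voxel displacement field driven by mutual
   information (MI) and regularised by springs connecting 6-neighboring
   voxels. The spring weights depend on a tissue-class map (air / liver /
   soft / bone from HU thresholding): the liver is kept much stiffer than
   its surroundings so its registration stays close to rigid and is driven
   by the high-gradient liver boundary rather than by featureless interior.
3. The FDG-PET is warped with the field obtained for its CT.
4. The Jacobian determinant of the field quantifies local volume change as
   a QC measure (1 = volume preserving; <= 0 flags a folding deformation),
   summarised over the entire liver, the liver eroded by a 10-mm metric
   ball, and their difference (the boundary shell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .core import Mask, Volume, erode_mm, dilate_mm

__all__ = [
    "RigidTransform", "DeformationField", "TissueClassMap", "JacobianStats",
    "RegistrationError", "register_rigid", "resample_rigid", "build_meta_cbct",
    "classify_tissue", "register_deformable", "warp", "jacobian_determinant",
    "jacobian_stats",
]


class RegistrationError(RuntimeError):
    """Raised when an optimisation diverges; carries diagnostics."""


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, extrinsic x-y-z) + translation (mm) about a center.

    The transform is the *resampling map*: it sends a world point of the
    fixed frame to the corresponding world point of the moving frame, so
    pulling the moving image back through it aligns it with the fixed image.
    For content that was translated by ``s`` mm, the recovered translation
    equals ``s``.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def linear(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (np.asarray(pts, float) - c) @ self.linear.T + c + t

    def inverse_points(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (np.asarray(pts, float) - c - t) @ self.linear + c


def _world_grid(shape, spacing, origin) -> np.ndarray:
    """(nx, ny, nz, 3) array of voxel-center world coordinates."""
    idx = np.indices(shape, dtype=float)
    return np.stack([idx[i] * spacing[i] + origin[i] for i in range(3)], axis=-1)


def _sample(vol: Volume, pts_mm: np.ndarray, order: int = 1, cval: float = np.nan) -> np.ndarray:
    """Interpolate a volume at world points (pull-back)."""
    coords = [(pts_mm[..., i] - vol.origin[i]) / vol.spacing[i] for i in range(3)]
    return ndimage.map_coordinates(np.asarray(vol.data, float), coords, order=order,
                                   mode="constant", cval=cval, prefilter=False)


def resample_rigid(moving: Volume, fixed: Volume, transform: RigidTransform,
                   order: int = 1, cval: float = np.nan) -> Volume:
    """Resample the moving volume onto the fixed grid through the transform."""
    pts = _world_grid(fixed.shape, fixed.spacing, fixed.origin)
    data = _sample(moving, transform.apply_points(pts), order=order, cval=cval)
    return Volume(data, fixed.spacing, fixed.origin, moving.modality)


def _bbox_mm(vol: Volume) -> tuple[np.ndarray, np.ndarray]:
    lo = np.asarray(vol.origin)
    hi = lo + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)
    return lo, hi


def _downsample(vol: Volume) -> Volume:
    """Halve the resolution by 2x2x2 block averaging (edge-padded)."""
    data = np.asarray(vol.data, float)
    pads = [(0, s % 2) for s in data.shape]
    data = np.pad(data, pads, mode="edge")
    sx, sy, sz = data.shape
    data = data.reshape(sx // 2, 2, sy // 2, 2, sz // 2, 2).mean(axis=(1, 3, 5))
    spacing = tuple(2 * s for s in vol.spacing)
    origin = tuple(o + 0.5 * s for o, s in zip(vol.origin, vol.spacing))
    return Volume(data, spacing, origin, vol.modality)


def _pyramid(vol: Volume, levels: int) -> list[Volume]:
    pyr = [vol]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) < 8:
            break
        pyr.append(_downsample(pyr[-1]))
    return pyr[::-1]  # coarse to fine


def register_rigid(moving: Volume, fixed: Volume, levels: int = 3,
                   init: RigidTransform | None = None) -> RigidTransform:
    """Multi-resolution rigid registration minimising mean SSD.

    Powell's method optimises the 3 rotation angles (degrees) and 3
    translations (mm) coarse-to-fine; rotations are about the fixed volume's
    world center. Requires overlapping fields of view.
    """
    lo_m, hi_m = _bbox_mm(moving)
    lo_f, hi_f = _bbox_mm(fixed)
    if np.any(np.minimum(hi_m, hi_f) < np.maximum(lo_m, lo_f)):
        raise RegistrationError("moving and fixed fields of view do not overlap")

    center = tuple(0.5 * (lo_f + hi_f))
    pyr_m = _pyramid(moving, levels)
    pyr_f = _pyramid(fixed, levels)
    x = np.zeros(6)
    if init is not None:
        x = np.array(list(init.rotation_deg) + list(init.translation_mm), float)

    for mov_l, fix_l in zip(pyr_m, pyr_f):
        pts = _world_grid(fix_l.shape, fix_l.spacing, fix_l.origin)
        fdat = np.asarray(fix_l.data, float)
        # SSD on a strided voxel subset at fine levels keeps the cost cheap
        # without biasing the optimum (the subset is a regular lattice)
        stride = max(1, int(round((pts[..., 0].size / 50000.0) ** (1 / 3))))
        sub = (slice(None, None, stride),) * 3
        pts_s = pts[sub].reshape(-1, 3)
        fdat_s = fdat[sub].ravel()

        def cost(p):
            tr = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
            samp = _sample(mov_l, tr.apply_points(pts_s))
            valid = np.isfinite(samp)
            if valid.sum() < 0.25 * samp.size:
                return 1e12
            diff = samp[valid] - fdat_s[valid]
            return float(np.mean(diff * diff))

        # initial direction scales: 4 deg for rotations, 2 mm for
        # translations — wide enough for the line search to bracket past
        # shallow interpolation-induced local dips near the start
        direc = np.diag([4.0, 4.0, 4.0, 2.0, 2.0, 2.0])
        res = optimize.minimize(cost, x, method="Powell",
                                options={"xtol": 1e-3, "ftol": 1e-7,
                                         "maxfev": 2500, "direc": direc})
        x = res.x
    return RigidTransform(tuple(x[:3]), tuple(x[3:]), center)


# ---------------------------------------------------------------------------
# Meta-CBCT
# ---------------------------------------------------------------------------

def build_meta_cbct(cbcts: list[Volume], transforms: list[RigidTransform] | None = None) -> Volume:
    """Average rigidly aligned CBCTs on the union field of view.

    ``transforms[i]`` maps reference-frame points into CBCT ``i``'s frame
    (identity for the first / reference CBCT). Voxels covered by a single
    CBCT keep that CBCT's value; per-lobe contrast enhancement is suppressed
    wherever several CBCTs average together.
    """
    if not cbcts:
        raise ValueError("need at least one CBCT")
    if transforms is None:
        transforms = [RigidTransform() for _ in cbcts]
    if len(transforms) != len(cbcts):
        raise ValueError("one transform per CBCT required")

    ref = cbcts[0]
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for vol, tr in zip(cbcts, transforms):
        blo, bhi = _bbox_mm(vol)
        corners = np.array([[blo[i] if b & (1 << i) == 0 else bhi[i] for i in range(3)]
                            for b in range(8)])
        back = tr.inverse_points(corners)  # region covered in reference frame
        lo = np.minimum(lo, back.min(axis=0))
        hi = np.maximum(hi, back.max(axis=0))

    spacing = np.asarray(ref.spacing)
    shape = tuple(int(np.floor((hi[i] - lo[i]) / spacing[i])) + 1 for i in range(3))
    grid = Volume(np.zeros(shape), tuple(spacing), tuple(lo), ref.modality)
    pts = _world_grid(shape, grid.spacing, grid.origin)

    total = np.zeros(shape)
    count = np.zeros(shape)
    for vol, tr in zip(cbcts, transforms):
        samp = _sample(vol, tr.apply_points(pts))
        valid = np.isfinite(samp)
        total[valid] += samp[valid]
        count[valid] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    mean = np.nan_to_num(mean, nan=float(np.nanmin(mean)))
    return Volume(mean, grid.spacing, grid.origin, ref.modality)


# ---------------------------------------------------------------------------
# Tissue classification
# ---------------------------------------------------------------------------

TISSUE_LABELS = {"air": 0, "soft": 1, "liver": 2, "bone": 3}
DEFAULT_RIGIDITY = {"air": 0.2, "soft": 1.0, "liver": 10.0, "bone": 5.0}


@dataclass
class TissueClassMap:
    """Per-voxel tissue label and per-class spring rigidity."""

    labels: np.ndarray  # uint8, values of TISSUE_LABELS
    rigidity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RIGIDITY))
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rigidity["liver"] < max(self.rigidity.values()) - 1e-12:
            raise ValueError("liver rigidity must be the largest")

    def rigidity_map(self) -> np.ndarray:
        lut = np.zeros(len(TISSUE_LABELS))
        for name, lab in TISSUE_LABELS.items():
            lut[lab] = self.rigidity[name]
        return lut[self.labels]


def classify_tissue(ct: Volume, liver_hint_mask: Mask | None = None,
                    air_thr: float = -200.0, bone_thr: float = 300.0,
                    liver_window: tuple[float, float] = (30.0, 200.0),
                    hint_dilate_mm: float = 10.0,
                    rigidity: dict[str, float] | None = None) -> TissueClassMap:
    """Threshold a CT into air / liver / other soft tissue / bone.

    Liver voxels are those inside the (dilated) liver hint whose HU falls in
    the liver window; without a hint the window alone defines the liver
    class. The remainder of the non-air, non-bone volume is generic soft
    tissue.
    """
    hu = np.asarray(ct.data, float)
    labels = np.full(ct.shape, TISSUE_LABELS["soft"], dtype=np.uint8)
    labels[hu < air_thr] = TISSUE_LABELS["air"]
    labels[hu > bone_thr] = TISSUE_LABELS["bone"]
    in_window = np.logical_and(hu >= liver_window[0], hu <= liver_window[1])
    if liver_hint_mask is not None:
        hint = dilate_mm(liver_hint_mask.data, hint_dilate_mm, ct.spacing)
        in_window &= hint
    liver = np.logical_and(in_window, labels == TISSUE_LABELS["soft"])
    labels[liver] = TISSUE_LABELS["liver"]
    return TissueClassMap(labels, dict(rigidity or DEFAULT_RIGIDITY), ct.spacing, ct.origin)


# ---------------------------------------------------------------------------
# Deformation fields
# ---------------------------------------------------------------------------

@dataclass
class DeformationField:
    """Dense per-voxel displacement (mm) on the fixed grid.

    ``disp[..., k]`` is the k-th component of the displacement added to a
    fixed-frame voxel-center world coordinate to reach the corresponding
    moving-frame point (pull-back convention).
    """

    disp: np.ndarray  # (nx, ny, nz, 3) mm
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("displacement must be (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.disp, axis=-1)


def warp(volume: Volume | Mask, field: DeformationField,
         interpolation: str = "linear", fill: float | None = None):
    """Pull a volume back through a deformation field.

    Intensity images use linear interpolation, masks must use nearest
    (warping a mask linearly is a contract violation). Out-of-field voxels
    take ``fill`` (default: 0 for masks, the volume minimum for images).
    """
    is_mask = isinstance(volume, Mask)
    if is_mask and interpolation == "linear":
        raise ValueError("masks must be warped with nearest interpolation")
    order = {"linear": 1, "nearest": 0}[interpolation]
    pts = _world_grid(field.shape, field.spacing, field.origin) + field.disp
    if is_mask:
        src = Volume(volume.data.astype(np.uint8), volume.spacing, volume.origin)
        data = _sample(src, pts, order=order, cval=0.0)
        return Mask(data > 0.5, field.spacing, field.origin, volume.label)
    cval = float(np.min(volume.data)) if fill is None else float(fill)
    src = Volume(volume.data, volume.spacing, volume.origin)
    data = _sample(src, pts, order=order, cval=np.nan)
    data = np.where(np.isfinite(data), data, cval)
    return Volume(data, field.spacing, field.origin, volume.modality)


# ---------------------------------------------------------------------------
# Deformable registration: MI + class-rigidity springs
# ---------------------------------------------------------------------------

def _mutual_information_and_weight(fvals: np.ndarray, mvals: np.ndarray,
                                   bins: int = 32):
    """MI (nats) of two intensity samples plus a per-sample weight.

    The joint histogram uses linear (partial-volume) weighting along the
    moving-intensity axis and a light Parzen smoothing. The returned weight
    is the derivative of MI with respect to each sample's moving intensity,
    obtained by finite differences of the pointwise log-likelihood ratio
    L = log p(f, m) − log p(f) p(m) across moving bins; multiplied by the
    spatial gradient of the warped image it yields the MI force.
    """
    f_lo, f_hi = fvals.min(), fvals.max()
    m_lo, m_hi = mvals.min(), mvals.max()
    f_rng = max(f_hi - f_lo, 1e-6)
    m_rng = max(m_hi - m_lo, 1e-6)
    fb = np.clip((fvals - f_lo) / f_rng * (bins - 1), 0, bins - 1)
    mb = np.clip((mvals - m_lo) / m_rng * (bins - 1), 0, bins - 1)
    fi = fb.astype(np.int64)
    mi0 = np.floor(mb).astype(np.int64)
    mw = mb - mi0
    mi1 = np.minimum(mi0 + 1, bins - 1)

    joint = np.zeros((bins, bins))
    np.add.at(joint, (fi, mi0), 1.0 - mw)
    np.add.at(joint, (fi, mi1), mw)
    joint = ndimage.gaussian_filter(joint, 0.7)
    joint /= joint.sum()
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    eps = 1e-12
    log_ratio = np.log(joint + eps) - np.log(pf[:, None] + eps) - np.log(pm[None, :] + eps)
    mi_value = float(np.sum(joint * log_ratio))

    # dL/dm via central differences along the moving-bin axis, per sample
    dL = np.zeros_like(log_ratio)
    dL[:, 1:-1] = (log_ratio[:, 2:] - log_ratio[:, :-2]) * 0.5
    dL[:, 0] = log_ratio[:, 1] - log_ratio[:, 0]
    dL[:, -1] = log_ratio[:, -1] - log_ratio[:, -2]
    bin_width = m_rng / (bins - 1)
    mnear = np.where(mw < 0.5, mi0, mi1)
    weight = dL[fi, mnear] / bin_width / len(fvals)
    return mi_value, weight


def _spring_energy(u: np.ndarray, rig: np.ndarray) -> float:
    """E = 1/2 sum over 6-neighbor pairs of w_pair |u_i − u_j|², per voxel.

    The pair weight is the mean of the two voxels' class rigidities (the
    linearised nonlinear-spring model).
    """
    energy = 0.0
    for ax in range(3):
        du = np.diff(u, axis=ax)
        w = 0.5 * (np.take(rig, range(1, rig.shape[ax]), axis=ax)
                   + np.take(rig, range(0, rig.shape[ax] - 1), axis=ax))
        energy += 0.5 * float(np.sum(w * np.sum(du * du, axis=-1)))
    return energy / u[..., 0].size


def _spring_relax(u: np.ndarray, rig: np.ndarray, alpha: float, sweeps: int) -> np.ndarray:
    """Approximate implicit solve of  min_v |v − u|² + α E_spring(v).

    Jacobi iterations of v_i = (u_i + α Σ_j w_ij v_j) / (1 + α Σ_j w_ij):
    where the class rigidity w is large (liver) the field is pulled hard
    toward its neighbor average (near-rigid motion); where it is small (air)
    the data update passes through almost unchanged.
    """
    target = u
    v = u.copy()
    for _ in range(sweeps):
        wsum = np.zeros(u.shape[:3])
        acc = np.zeros_like(u)
        for ax in range(3):
            w = 0.5 * (np.take(rig, range(1, rig.shape[ax]), axis=ax)
                       + np.take(rig, range(0, rig.shape[ax] - 1), axis=ax))
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(0, -1)
            sl_hi[ax] = slice(1, None)
            v_lo, v_hi = v[tuple(sl_lo)], v[tuple(sl_hi)]
            acc[tuple(sl_lo)] += w[..., None] * v_hi
            acc[tuple(sl_hi)] += w[..., None] * v_lo
            wsum[tuple(sl_lo)] += w
            wsum[tuple(sl_hi)] += w
        v = (target + alpha * acc) / (1.0 + alpha * wsum)[..., None]
    return v


def _resize_field(u: np.ndarray, new_shape) -> np.ndarray:
    zoom = [ns / os for ns, os in zip(new_shape, u.shape[:3])]
    out = np.stack([ndimage.zoom(u[..., k], zoom, order=1, mode="nearest")
                    for k in range(3)], axis=-1)
    return out


def _downsample_labels(labels: np.ndarray, new_shape) -> np.ndarray:
    zoom = [ns / os for ns, os in zip(new_shape, labels.shape)]
    return ndimage.zoom(labels, zoom, order=0, mode="nearest")


def register_deformable(moving: Volume, fixed: Volume, class_map: TissueClassMap,
                        init: RigidTransform | None = None, levels: int = 3,
                        iterations: int = 60, reg_weight: float = 0.02,
                        spring_alpha: float = 1.0, relax_sweeps: int = 4,
                        step_mm: float | None = None, bins: int = 32,
                        smooth_update_vox: float = 2.0,
                        divergence_patience: int = 10) -> DeformationField:
    """Deformable registration of ``moving`` onto the ``fixed`` grid.

    Coarse-to-fine minimisation of cost = −MI(fixed, warped) +
    reg_weight · E_spring. Each iteration takes a demons-style data step —
    the MI force (histogram-derivative weight times the spatial gradient of
    the warped moving image, Gaussian-smoothed) normalised per voxel with a
    trust region of ``step_mm`` — and then relaxes the field against the
    class-rigidity springs by an approximate implicit solve
    (``spring_alpha``, ``relax_sweeps``): stiff (liver) voxels are pulled
    toward near-rigid motion, lax (air) voxels follow the data. A trial
    update is only accepted if the cost decreases, otherwise the step is
    halved; if the step collapses while the cost still exceeds its starting
    value the registration raises :class:`RegistrationError` with
    diagnostics.

    The returned field is composed with the rigid initialisation: warping
    the original moving image with it directly aligns it to ``fixed``.
    """
    if class_map.labels.shape != fixed.shape:
        raise ValueError("class map must live on the fixed grid")
    if init is None:
        init = RigidTransform(center_mm=tuple(
            np.asarray(fixed.origin) + 0.5 * (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing)))

    pyr_f = _pyramid(fixed, levels)
    u = np.zeros(pyr_f[0].shape + (3,))

    mdata = np.asarray(moving.data, float)
    grad_m = np.stack(np.gradient(mdata, *moving.spacing), axis=-1)
    R = init.linear

    for li, fix_l in enumerate(pyr_f):
        if u.shape[:3] != fix_l.shape:
            u = _resize_field(u, fix_l.shape)
        labels_l = _downsample_labels(class_map.labels, fix_l.shape)
        lut = np.zeros(len(TISSUE_LABELS))
        for name, lab in TISSUE_LABELS.items():
            lut[lab] = class_map.rigidity[name]
        rig = lut[labels_l]
        pts = _world_grid(fix_l.shape, fix_l.spacing, fix_l.origin)
        fdat = np.asarray(fix_l.data, float)
        fflat = fdat.ravel()
        step = step_mm if step_mm is not None else 0.4 * min(fix_l.spacing)

        def evaluate(u_arr):
            warped_pts = init.apply_points(pts + u_arr)
            samp = _sample(Volume(mdata, moving.spacing, moving.origin), warped_pts)
            fill = float(mdata.min())
            samp = np.where(np.isfinite(samp), samp, fill)
            mi_value, wgt = _mutual_information_and_weight(fflat, samp.ravel(), bins)
            cost = -mi_value + reg_weight * _spring_energy(u_arr, rig)
            return cost, mi_value, wgt.reshape(fdat.shape), warped_pts

        cost, mi_value, wgt, warped_pts = evaluate(u)
        cost0 = cost
        stalls = 0
        for _ in range(iterations):
            # spatial gradient of warped moving image, pulled back via the
            # rigid linear part (chain rule through init)
            gm = np.stack([_sample(Volume(grad_m[..., k], moving.spacing, moving.origin),
                                   warped_pts) for k in range(3)], axis=-1)
            gm = np.where(np.isfinite(gm), gm, 0.0)
            force = wgt[..., None] * (gm @ R)  # dMI/du, ascent direction
            force = np.stack([ndimage.gaussian_filter(force[..., k], smooth_update_vox)
                              for k in range(3)], axis=-1)
            # soft per-voxel normalisation (demons-style): voxels with a
            # clear force move ~step mm, near-zero-force voxels barely move
            mag = np.linalg.norm(force, axis=-1, keepdims=True)
            if not (mag > 0).any():
                break
            eps = 0.1 * np.percentile(mag[mag > 0], 99)
            if eps < 1e-300:
                break
            delta = force / (mag + eps) * step
            # relax the increment against the class-rigidity springs: stiff
            # (liver) regions deform coherently, lax (air) regions freely
            new_u = u + _spring_relax(delta, rig, spring_alpha, relax_sweeps)
            new_cost, new_mi, new_wgt, new_pts = evaluate(new_u)
            if new_cost < cost:
                u, cost, mi_value, wgt, warped_pts = new_u, new_cost, new_mi, new_wgt, new_pts
                step = min(step * 1.1, 2.0 * min(fix_l.spacing))
                stalls = 0
            else:
                step *= 0.5
                stalls += 1
                if step < 1e-6:
                    if cost > cost0 + 1e-9:
                        raise RegistrationError(
                            f"deformable registration diverged at level {li}: "
                            f"cost {cost:.6f} vs initial {cost0:.6f}, MI {mi_value:.4f}")
                    break
                if stalls >= divergence_patience:
                    break

    # compose with the rigid initialisation: total map x -> T_init(x + u(x))
    pts = _world_grid(fixed.shape, fixed.spacing, fixed.origin)
    if u.shape[:3] != fixed.shape:
        u = _resize_field(u, fixed.shape)
    total = init.apply_points(pts + u) - pts
    return DeformationField(total, fixed.spacing, fixed.origin)


# ---------------------------------------------------------------------------
# Jacobian QC
# ---------------------------------------------------------------------------

def jacobian_determinant(defo: DeformationField) -> np.ndarray:
    """det(I + ∇d) per voxel, gradients in mm/mm (central differences in the
    interior, one-sided at borders). 1 everywhere for the identity field."""
    d = defo.disp
    J = np.zeros(d.shape[:3] + (3, 3))
    for i in range(3):
        grads = np.gradient(d[..., i], *defo.spacing)
        for j in range(3):
            J[..., i, j] = grads[j]
    J[..., 0, 0] += 1.0
    J[..., 1, 1] += 1.0
    J[..., 2, 2] += 1.0
    return np.linalg.det(J)


def _stats(vals: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear (type-7) quartiles
    return {"min": float(vals.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(vals.max()), "mean": float(vals.mean())}


@dataclass(frozen=True)
class JacobianStats:
    """Per-VOI summary of the Jacobian determinant."""

    entire: dict[str, float]
    eroded: dict[str, float] | None
    excluded: dict[str, float]
    nonpositive_fraction: float

    def as_dict(self) -> dict:
        return {"entire": self.entire, "eroded": self.eroded,
                "excluded": self.excluded,
                "nonpositive_fraction": self.nonpositive_fraction}


def jacobian_stats(jac: np.ndarray, liver_mask: Mask, erosion_mm: float = 10.0) -> JacobianStats:
    """Summaries over the entire liver, the liver eroded by a metric ball of
    ``erosion_mm``, and the boundary shell (entire minus eroded).

    The fraction of liver voxels with a nonpositive Jacobian is reported as
    a QC flag (folding deformation)."""
    if liver_mask.count() == 0:
        raise ValueError("liver mask is empty")
    entire = liver_mask.data
    eroded = erode_mm(entire, erosion_mm, liver_mask.spacing)
    excluded = np.logical_and(entire, ~eroded)
    nonpos = float(np.mean(jac[entire] <= 0))
    if not eroded.any():
        warnings.warn("eroded liver is empty; reporting entire/excluded only")
        return JacobianStats(_stats(jac[entire]), None, _stats(jac[excluded]), nonpos)
    return JacobianStats(_stats(jac[entire]), _stats(jac[eroded]),
                         _stats(jac[excluded]), nonpos)
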