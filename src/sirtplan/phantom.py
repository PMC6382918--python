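"""Synthetic multi-modal liver phantoms with known ground truth.

No public dataset exists for the SIRT planning workflow (the clinical data
are private), so every downstream stage is exercised on digital phantoms
that emulate the multi-modal appearance of the pre-treatment studies:

* an ellipsoidal liver (HU ≈ 60) inside a soft-tissue body (HU ≈ 20) with a
  bone (spine) cylinder and air background;
* an oriented plane through the liver defining the true left/right
  perfusion territories;
* spherical FDG-avid lesions with a peak SUV and a small HU offset;
* per-lobe CBCTs in which only the fed lobe is contrast-enhanced (early and
  late arterial phase boosts);
* a smooth synthetic deformation (sum of low-frequency sinusoids with a
  closed-form Jacobian) relating the FDG frame to the MAA frame — the FDG
  images are the analytic scene evaluated at the deformed coordinates, so
  no interpolation error enters the ground truth;
* independent Gaussian noise per modality, all driven by one integer seed.

The scene is evaluated *analytically* at arbitrary world points, which
makes truth masks, lobe volumes and the deformation Jacobian exact up to
voxelization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .core import Mask, Modality, Volume
from .liver_seg import SliceAnnotations
from .lobes import LobeLine, PlaneModel, TransverseLineSet
from .registration import DeformationField


@dataclass(frozen=True)
class TumorSpec:
    """One spherical lesion: center/radius in world mm, PET peak SUV and the
    HU offset it adds on CT."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_suv: float = 8.0
    hu_offset: float = 30.0


@dataclass(frozen=True)
class DeformationSpec:
    """Smooth synthetic displacement: d_i(p) = A_i sin(2π p·u_i / λ + φ_i).

    ``amplitude_mm`` bounds the displacement magnitude; ``wavelength_mm``
    sets the smoothness. The Jacobian is known in closed form.
    """

    amplitude_mm: float = 6.0
    wavelength_mm: float = 80.0

    # fixed component directions and phases; |weights| normalised to 1 so
    # the peak displacement magnitude equals amplitude_mm
    _weights = (1.0, 0.6, 0.4)
    _dirs = ((0.0, 1.0, 0.0), (1.0, 0.0, 1.0), (1.0, 1.0, 0.0))
    _phases = (0.0, 1.0, 2.0)

    def _amps(self) -> np.ndarray:
        w = np.asarray(self._weights)
        return self.amplitude_mm * w / np.linalg.norm(w)

    def displacement(self, pts_mm: np.ndarray) -> np.ndarray:
        """(..., 3) displacement in mm at world points."""
        pts = np.asarray(pts_mm, float)
        amps = self._amps()
        out = np.zeros_like(pts)
        for i in range(3):
            u = np.asarray(self._dirs[i]) / np.linalg.norm(self._dirs[i])
            phase = 2 * np.pi * (pts @ u) / self.wavelength_mm + self._phases[i]
            out[..., i] = amps[i] * np.sin(phase)
        return out

    def jacobian(self, pts_mm: np.ndarray) -> np.ndarray:
        """Closed-form det(I + ∇d) at world points."""
        pts = np.asarray(pts_mm, float)
        amps = self._amps()
        J = np.zeros(pts.shape[:-1] + (3, 3))
        for i in range(3):
            u = np.asarray(self._dirs[i]) / np.linalg.norm(self._dirs[i])
            phase = 2 * np.pi * (pts @ u) / self.wavelength_mm + self._phases[i]
            coef = amps[i] * 2 * np.pi / self.wavelength_mm * np.cos(phase)
            for j in range(3):
                J[..., i, j] = coef * u[j]
        for k in range(3):
            J[..., k, k] += 1.0
        return np.linalg.det(J)


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise model of one synthetic patient.

    Defaults describe a 64³ grid at 2.5 mm isotropic spacing (160 mm field
    of view) with a liver of roughly 410 cc, two FDG-avid lesions, +40/+80
    HU early/late CBCT enhancement of the fed lobe, CT noise of 20 HU, PET
    noise of 0.3 SUV and a 6-mm peak synthetic deformation.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    liver_center_mm: tuple[float, float, float] = (78.0, 75.0, 80.0)
    liver_semiaxes_mm: tuple[float, float, float] = (55.0, 40.0, 45.0)

    # true lobe separator; normal points toward the right lobe
    plane_normal: tuple[float, float, float] = (0.94, 0.25, 0.23)
    plane_point_mm: tuple[float, float, float] = (66.0, 75.0, 80.0)

    tumors: tuple[TumorSpec, ...] = (
        TumorSpec(center_mm=(100.0, 80.0, 85.0), radius_mm=9.0, peak_suv=8.0),
        TumorSpec(center_mm=(55.0, 70.0, 70.0), radius_mm=7.0, peak_suv=6.0),
    )

    hu_air: float = -1000.0
    hu_liver: float = 60.0
    hu_soft: float = 20.0
    hu_bone: float = 700.0

    body_semiaxes_mm: tuple[float, float, float] = (75.0, 70.0, 80.0)
    spine_center_xy_mm: tuple[float, float] = (78.0, 20.0)
    spine_radius_mm: float = 9.0

    cbct_enhancement_hu: dict = field(default_factory=lambda: {"early": 40.0, "late": 80.0})

    pet_liver_suv: float = 2.0
    pet_body_suv: float = 0.5

    ct_noise_hu: float = 20.0
    cbct_noise_hu: float = 20.0
    pet_noise_suv: float = 0.3
    pet_psf_fwhm_mm: float = 0.0  # optional resolution blur of the PET

    deformation: DeformationSpec = field(default_factory=DeformationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.liver_semiaxes_mm):
            raise ValueError("liver semi-axes must be positive")
        if self.ct_noise_hu < 0 or self.pet_noise_suv < 0 or self.cbct_noise_hu < 0:
            raise ValueError("noise sigmas must be nonnegative")
        c = np.asarray(self.liver_center_mm)
        ax = np.asarray(self.liver_semiaxes_mm)
        for t in self.tumors:
            # conservative containment: sphere center inside the ellipsoid
            # shrunk by the tumor radius on every semi-axis
            shrunk = ax - t.radius_mm
            if np.any(shrunk <= 0) or np.sum(((np.asarray(t.center_mm) - c) / shrunk) ** 2) > 1.0:
                raise ValueError(f"tumor at {t.center_mm} is not inside the liver")

    @property
    def plane(self) -> PlaneModel:
        n = np.asarray(self.plane_normal, float)
        n = n / np.linalg.norm(n)
        return PlaneModel(tuple(n), float(n @ np.asarray(self.plane_point_mm)))


@dataclass
class PhantomTruth:
    """Exact ground truth of one phantom, in the MAA frame unless noted."""

    liver: Mask
    left_lobe: Mask
    right_lobe: Mask
    tumors: list[Mask]
    plane: PlaneModel
    deformation_spec: DeformationSpec
    field: DeformationField           # FDG-frame sampling displacement d(x)
    liver_fdg: Mask                   # liver as it appears in the FDG frame

    def __post_init__(self) -> None:
        lobes = np.logical_or(self.left_lobe.data, self.right_lobe.data)
        if not np.array_equal(lobes, self.liver.data):
            raise ValueError("lobe masks must partition the liver mask")
        for t in self.tumors:
            if np.logical_and(t.data, ~self.liver.data).any():
                raise ValueError("tumor masks must lie inside the liver")


@dataclass
class PhantomStudy:
    """The generated multi-modal image set of one synthetic patient."""

    ct_maa: Volume
    ct_fdg: Volume
    pet_fdg: Volume
    cbct_early_left: Volume
    cbct_late_left: Volume
    cbct_early_right: Volume
    cbct_late_right: Volume
    truth: PhantomTruth

    @property
    def cbcts(self) -> list[Volume]:
        return [self.cbct_early_left, self.cbct_late_left,
                self.cbct_early_right, self.cbct_late_right]


# ---------------------------------------------------------------------------
# Analytic scene evaluation
# ---------------------------------------------------------------------------

def _ellipsoid(pts, center, semiaxes) -> np.ndarray:
    d = (np.asarray(pts, float) - np.asarray(center)) / np.asarray(semiaxes)
    return np.sum(d * d, axis=-1) <= 1.0


def _scene_masks(spec: PhantomSpec, pts: np.ndarray) -> dict[str, np.ndarray]:
    grid_center = np.asarray(spec.origin) + 0.5 * (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    body = _ellipsoid(pts, grid_center, spec.body_semiaxes_mm)
    liver = _ellipsoid(pts, spec.liver_center_mm, spec.liver_semiaxes_mm)
    liver &= body
    cx, cy = spec.spine_center_xy_mm
    spine = ((pts[..., 0] - cx) ** 2 + (pts[..., 1] - cy) ** 2) <= spec.spine_radius_mm ** 2
    spine &= body & ~liver
    tumors = []
    for t in spec.tumors:
        d = pts - np.asarray(t.center_mm)
        tumors.append(np.sum(d * d, axis=-1) <= t.radius_mm ** 2)
    return {"body": body, "liver": liver, "spine": spine, "tumors": tumors}


def _scene_hu(spec: PhantomSpec, pts: np.ndarray,
              enhance_lobe: str | None = None, enhance_hu: float = 0.0) -> np.ndarray:
    m = _scene_masks(spec, pts)
    hu = np.full(pts.shape[:-1], spec.hu_air)
    hu[m["body"]] = spec.hu_soft
    hu[m["liver"]] = spec.hu_liver
    for t, tm in zip(spec.tumors, m["tumors"]):
        hu[tm] = spec.hu_liver + t.hu_offset
    hu[m["spine"]] = spec.hu_bone
    if enhance_lobe is not None:
        sd = spec.plane.signed_distance(pts)
        lobe = m["liver"] & (sd >= 0 if enhance_lobe == "right" else sd < 0)
        hu[lobe] += enhance_hu
    return hu


def _scene_suv(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    m = _scene_masks(spec, pts)
    suv = np.zeros(pts.shape[:-1])
    suv[m["body"]] = spec.pet_body_suv
    suv[m["liver"]] = spec.pet_liver_suv
    for t, tm in zip(spec.tumors, m["tumors"]):
        suv[tm] = t.peak_suv
    return suv


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape, dtype=float)
    return np.stack([idx[i] * spec.spacing[i] + spec.origin[i] for i in range(3)], axis=-1)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Generate the full multi-modal study of one synthetic patient.

    The MAA-frame CT is the analytic scene on the grid; the FDG-frame CT and
    PET are the scene evaluated at ``x + d(x)`` with ``d`` the synthetic
    deformation, so the truth field is exact. Each per-lobe CBCT enhances
    only its fed lobe. Identical seeds give bit-identical outputs.
    """
    pts = _grid_points(spec)
    rng = np.random.default_rng(spec.seed)
    # one independent child stream per generated volume, in a fixed order
    streams = rng.spawn(7)

    def noisy(data, sigma, stream):
        if sigma > 0:
            return data + stream.normal(0.0, sigma, size=data.shape)
        return data

    geom = dict(spacing=spec.spacing, origin=spec.origin)
    ct_maa = Volume(noisy(_scene_hu(spec, pts), spec.ct_noise_hu, streams[0]),
                    modality=Modality.CT_MAA, **geom)

    disp = spec.deformation.displacement(pts)
    pts_fdg = pts + disp
    ct_fdg = Volume(noisy(_scene_hu(spec, pts_fdg), spec.ct_noise_hu, streams[1]),
                    modality=Modality.CT_FDG, **geom)
    suv = _scene_suv(spec, pts_fdg)
    if spec.pet_psf_fwhm_mm > 0:
        from scipy import ndimage as _ndi
        sigma_vox = spec.pet_psf_fwhm_mm / 2.35482 / np.asarray(spec.spacing)
        suv = _ndi.gaussian_filter(suv, sigma_vox)
    pet_fdg = Volume(np.maximum(noisy(suv, spec.pet_noise_suv, streams[2]), 0.0),
                     modality=Modality.PET_FDG, **geom)

    cbcts = []
    for k, (lobe, phase) in enumerate([("left", "early"), ("left", "late"),
                                       ("right", "early"), ("right", "late")]):
        hu = _scene_hu(spec, pts, enhance_lobe=lobe,
                       enhance_hu=spec.cbct_enhancement_hu[phase])
        cbcts.append(Volume(noisy(hu, spec.cbct_noise_hu, streams[3 + k]),
                            modality=Modality.CBCT, **geom))

    masks = _scene_masks(spec, pts)
    sd = spec.plane.signed_distance(pts)
    liver = Mask(masks["liver"], label="liver", **geom)
    truth = PhantomTruth(
        liver=liver,
        left_lobe=Mask(masks["liver"] & (sd < 0), label="left lobe", **geom),
        right_lobe=Mask(masks["liver"] & (sd >= 0), label="right lobe", **geom),
        tumors=[Mask(tm & masks["liver"], label=f"tumor {i}", **geom)
                for i, tm in enumerate(masks["tumors"])],
        plane=spec.plane,
        deformation_spec=spec.deformation,
        field=DeformationField(disp, spec.spacing, spec.origin),
        liver_fdg=Mask(_scene_masks(spec, pts_fdg)["liver"], label="liver (FDG frame)", **geom),
    )
    return PhantomStudy(ct_maa, ct_fdg, pet_fdg, *cbcts, truth=truth)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_phantom(truth: PhantomTruth, every_n: int = 15,
                     n_line_slices: int = 3, jitter_mm: float = 0.0,
                     seed: int = 0) -> tuple[SliceAnnotations, TransverseLineSet]:
    """Emulate the manual input: liver contours on every ``every_n``-th axial
    slice and lobe-separation lines on ``n_line_slices`` transverse slices.

    Contours are traced from the truth liver mask; lines are sampled from
    the true plane's intersection with evenly spaced liver slices. Optional
    Gaussian jitter (mm, seeded) perturbs the line endpoints perpendicular
    to the line, emulating operator variability.
    """
    liver = truth.liver
    spacing = np.asarray(liver.spacing)
    origin = np.asarray(liver.origin)
    rng = np.random.default_rng(seed)

    z_has = np.nonzero(liver.data.any(axis=(0, 1)))[0]
    if len(z_has) == 0:
        raise ValueError("liver mask is empty")
    annotated = [z for z in range(0, liver.shape[2], every_n)
                 if liver.data[:, :, z].any()]
    if len(annotated) < 2:
        raise ValueError("liver spans fewer than 2 annotation slices")

    contours: dict[int, list[np.ndarray]] = {}
    for z in annotated:
        sl = liver.data[:, :, z].astype(float)
        cs = measure.find_contours(sl, 0.5)
        contours[z] = [c for c in cs if len(c) >= 3]
    ann = SliceAnnotations(contours, period=every_n)

    # lobe lines: plane ∩ axial slice, clipped to the liver's in-slice bbox
    n_lines = max(n_line_slices, 3)
    zsel = np.unique(np.linspace(z_has[0] + 1, z_has[-1] - 1, n_lines).round().astype(int))
    n = np.asarray(truth.plane.normal)
    lines = []
    for z in zsel:
        sl = liver.data[:, :, z]
        if not sl.any():
            continue
        z_mm = origin[2] + z * spacing[2]
        # in-plane line: n_x x + n_y y = offset − n_z z
        rhs = truth.plane.offset - n[2] * z_mm
        nxy = n[:2]
        norm_xy = np.linalg.norm(nxy)
        if norm_xy < 1e-9:
            continue  # plane parallel to the slice: no in-plane trace
        xs, ys = np.nonzero(sl)
        lo = np.array([xs.min(), ys.min()]) * spacing[:2] + origin[:2]
        hi = np.array([xs.max(), ys.max()]) * spacing[:2] + origin[:2]
        direction = np.array([-nxy[1], nxy[0]]) / norm_xy
        point = nxy * rhs / (norm_xy ** 2)
        # clip the parametric line to the bbox
        ts = []
        for dim in range(2):
            if abs(direction[dim]) > 1e-12:
                ts.extend([(lo[dim] - point[dim]) / direction[dim],
                           (hi[dim] - point[dim]) / direction[dim]])
        if not ts:
            continue
        t0, t1 = min(ts), max(ts)
        p0 = point + t0 * direction
        p1 = point + t1 * direction
        if jitter_mm > 0:
            p0 = p0 + rng.normal(0, jitter_mm) * nxy / norm_xy
            p1 = p1 + rng.normal(0, jitter_mm) * nxy / norm_xy
        mid = 0.5 * (p0 + p1)
        right_marker = mid + 10.0 * nxy / norm_xy  # toward positive side
        to_vox = lambda q: tuple((q - origin[:2]) / spacing[:2])
        lines.append(LobeLine(int(z), to_vox(p0), to_vox(p1), to_vox(right_marker)))
    if len({l.slice_index for l in lines}) < 3:
        raise ValueError("could not place lobe lines on 3 distinct slices")
    line_set = TransverseLineSet(lines, tuple(spacing), tuple(origin), source="CBCT")
    return ann, line_set
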