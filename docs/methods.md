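# Methods

`sirtplan` implements the image-analysis chain needed to plan yttrium-90
radioembolization (SIRT) of bilobar liver disease from the pre-treatment
studies: the CT of the ⁹⁹ᵐTc-MAA SPECT/CT (`CT_MAA`, the dosimetric
reference frame), the contrast CT and FDG-PET of the ¹⁸F-FDG PET/CT
(`CT_FDG`, `PET_FDG`), and per-lobe contrast-enhanced cone-beam CTs
(CBCT). This note documents the models, the parameters that matter, the
synthetic data used for validation, and the numerical choices.

## Geometry and preprocessing

Volumes are axis-aligned scalar grids (`world = origin + index·spacing`,
indices 0-based, boxes half-open); oblique affines are out of scope. A
manually chosen crop box bounds the liver on each study and all processing
runs on the cropped volumes.

CT/CBCT noise is suppressed with slice-wise 3×3 median filters applied in
the axial, coronal and sagittal orientations in turn. The phrase "three
consecutive" is ambiguous between *three orientations, once* and *the
orientation triple, three times*; both are supported
(`median_filter_stack(passes=n)`). The pipeline default is one triple: on
sharp-edged data the repeated triple builds an intermediate-intensity rim
around curved boundaries that the region-growing acceptance band then
excludes. Smoothed volumes drive registration/segmentation *decisions*
only; every reported quantity (SUV statistics, thresholds, volumes, doses)
is computed on the unsmoothed data.

PET activity concentration (kBq/cc) converts to body-weight SUV with
exponential decay correction of the injected activity and unit tissue
density; the variant is a deliberate design choice since only "SUV" is
specified upstream.

## Registration

**Rigid.** Multi-resolution (3 levels, ×2 block averaging) minimisation of
mean SSD over 3 rotations + 3 translations with Powell's method. Initial
direction scales are 4° / 2 mm: wide enough for the bracketing line search
to step over shallow local dips created by interpolation blur near the
identity. The SSD is evaluated on a regular voxel sub-lattice (≤ ~50 k
points) for speed; the transform maps fixed-frame points into the moving
frame (pull-back), so the recovered translation equals the physical content
shift.

**Meta-CBCT.** Each per-lobe CBCT sees arterial enhancement in its fed lobe
only. After rigid alignment, averaging the CBCTs on the union field of
view suppresses the enhancement (the +80 HU late-phase boost halves when
two CBCTs cover a voxel) and yields one larger-FOV image suitable for
deformable registration to `CT_MAA`.

**Deformable.** A dense per-voxel displacement field (mm, on the fixed
grid) minimises

    cost = −MI(fixed, warped moving) + w_reg · E_spring(u)

where MI uses a 32-bin joint histogram with partial-volume (linear)
weighting and light Parzen smoothing, and `E_spring` is the linearised
nonlinear-spring model: quadratic in the displacement difference of
6-neighbors, with the pair weight the mean of the two voxels' class
rigidities. Tissue classes come from HU thresholding (air < −200, bone
> 300, liver = HU ∈ [30, 200] within a dilated liver hint, remainder soft);
default rigidities are liver 10, bone 5, soft 1, air 0.2 — the liver is
kept an order of magnitude stiffer than its surroundings so its motion
stays near-rigid and is driven by the high-gradient boundary rather than
by the featureless interior.

Optimisation is demons-style, coarse-to-fine (3 levels): the MI force
(histogram log-likelihood-ratio derivative × spatial gradient of the
warped image, Gaussian-smoothed with σ = 2 voxels) is normalised per voxel
(`F/(|F|+ε)`, ε = 10% of the 99th force percentile) and scaled to a trust
region that adapts between ~1e-6 and 2 voxels; the increment is then
relaxed against the class-rigidity springs by a few Jacobi sweeps of the
implicit system `(I + αL_w)δ = δ_data` (α = 1, 4 sweeps), so stiff regions
deform coherently while lax regions follow the data. A trial update is
accepted only if the cost decreases; otherwise the step halves, and a step
collapse with the cost above its starting value raises a divergence error
with diagnostics. Per-voxel normalisation is essential here: the MI force
at the liver boundary is an order of magnitude weaker than at the body
surface, and any globally normalised step starves the liver.

The returned field composes the rigid initialisation, so warping the
original moving volume with it aligns it to the fixed frame directly. The
PET is warped with the field of its own CT (linear interpolation for
intensities; masks must use nearest neighbor — enforced).

**Jacobian QC.** `det(I + ∇d)` with central differences (one-sided at
borders, gradients in mm/mm) summarises local volume change over the
entire liver, the liver eroded by a 10-mm metric ball, and the boundary
shell (entire − eroded); quartiles use linear (type-7) interpolation. A
nonpositive determinant marks a folding deformation and is reported as a
QC flag.

## Liver segmentation (joint region growing)

The operator contours the liver on sparse axial slices (every 15th slice
on ~1-mm data; the phantom runs use every 6th slice of the 2.5-mm grid —
the same 15 mm). Between adjacent annotated slices a layer is formed:
seed = in-plane erosion (r = 20 voxels on 1-mm data, 8 voxels ≈ 20 mm on
the phantom grid) of the contour intersection; growth mask = in-plane
dilation of the union; both extruded through the layer. If erosion empties
the seed the radius halves until nonempty (warned).

Growth is jointly constrained: a frontier voxel (6-connectivity) joins only
if its value is acceptable in *all three* modalities. Stage 1 uses the
symmetric band μ±2σ per modality; stage 2 — seeded by the union of the
stage-1 layers and masked by its 3D r-voxel dilation (a 2D mask could never
reach the liver caps above/below the annotated span) — uses asymmetric
bands (k₁,k₂)·σ of (−2.5, 2) for both CTs and (−2, ∞) for PET plus an
absolute PET cap of SUV 2.5 that keeps FDG-avid lesions and adjacent avid
organs out. Statistics are recomputed once per sweep from the segmented
set (order-independent and deterministic; a frozen-from-seed mode exists
because the upstream description is ambiguous), and σ = 0 degenerates to
an exact-match criterion. A 3-mm metric closing-then-opening, clipping to
the stage-2 mask, and largest-component selection replace the interactive
expert clean-up of the clinical workflow.

## Tumor segmentation (adaptive threshold)

Within the liver mask, SUV mean μ and standard deviation σ give the
core-detection threshold THR_init = μ + 2.802σ (99.5% confidence bound).
Each 6-connected super-threshold component is processed independently: the
core is dilated with a 25-mm metric sphere; the background BG is the mean
SUV of dilated-mask voxels below SUV 2.5 (literal reading — neighboring
lesions' sub-threshold voxels are *not* excluded by default; a flag
excludes them); the lesion threshold is THR = BG + 0.41·(max − BG) with
max taken over the core (not the dilated mask, so a hot neighbor cannot
inflate it). The final mask is the connected component of
{SUV ≥ THR} ∩ dilated mask containing the core.

## Perfusion-territory splitting and comparison

The expert draws separation lines on ≥ 3 transverse slices (CBCT for
perfusion territories, CT for anatomical lobes). Segments are sampled
densely, mapped to mm, and a plane is fitted by total least squares
(eigendecomposition of the point scatter; degenerate < 2-D samples are
rejected). The normal is oriented toward the right lobe by the majority of
per-line side markers. Liver voxels split by the sign of the signed
distance of their centers; exact zeros go right (measure-zero tie,
documented; jittered tests avoid it). One plane divides exactly two
territories — multi-territory splitting is out of scope.

Two splits A (perfusion/CBCT) and B (anatomy/CT) are compared with
Vdiff = (|L_A∩R_B| + |L_B∩R_A|) / |L_B∪R_B| (B's liver as the
denominator, which generalises to splits of two different liver masks),
the ratios Rratio/Lratio of right- and left-to-whole fractions (B over A),
and surface distances between the in-liver separator surfaces (liver
voxels within half a voxel diagonal of each plane).

## Segmentation metrics

Dice, TPR, PPV and RV are exact voxel-count formulas. Surface voxels are
mask voxels with a face neighbor outside (volume border counts as outside;
6- vs 26-connectivity is configurable). aHD/mHD are the symmetrised
average/maximum of directed nearest-distance sums between surface-voxel
centers in mm, computed with a KD-tree and validated against the O(n²)
pairwise brute force.

## Partition-model dosimetry

IA[GBq] = D[Gy]·m[kg]/49.380 and D = 49.380·IA/m (⁹⁰Y dose factor);
volume→mass via ρ = 1.03 g/cm³ (both overridable). The impact simulation
prescribes per-lobe activity for a 40 Gy target on the anatomical (CT)
lobes and evaluates the delivered dose on the perfusion (CBCT) lobes taken
as ground truth, so the deviation is identically D·(m_CT/m_CBCT − 1).
Lung shunt, extra-hepatic deposition and tumor/normal compartments are
deliberately excluded — the simulation is lobe-level.

## Synthetic phantoms

No public dataset exists for this workflow, so validation uses digital
phantoms with exact ground truth: an ellipsoidal liver (HU 60) inside a
soft-tissue body (HU 20) with a bone cylinder (HU 700) and air background;
a true separator plane; spherical FDG-avid lesions (uniform peak SUV,
+30 HU on CT; an optional Gaussian PSF blur is off by default so the
zero-noise PET maximum equals the specified peak exactly); per-lobe CBCTs
enhancing only the fed lobe (+40/+80 HU early/late); independent Gaussian
noise per modality (defaults: 20 HU CT/CBCT, 0.3 SUV PET); and a smooth
synthetic deformation (sum of three low-frequency sinusoids, 6-mm peak,
80-mm wavelength) with a closed-form Jacobian relating the FDG frame to
the MAA frame. The FDG-frame images are the *analytic scene evaluated at
the deformed coordinates*, so the truth field carries no interpolation
error. All randomness flows from one integer seed through spawned PCG64
streams; identical seeds give bit-identical volumes. Default problem size
is a 64³ grid at 2.5 mm (≈ 410 cc liver, right-to-whole ≈ 0.65).

What the phantom does *not* emulate: partial-volume edges (tissue
interfaces are sharp), streak artifacts, breathing motion, anatomically
shaped livers and heterogeneous parenchyma, SPECT reconstruction. Passing
phantom tests therefore demonstrates correctness of the algorithms under
the stated noise/deformation model, not clinical-grade robustness; the
clinical figures quoted in validation tests (e.g. a Dice floor of 0.92 for
liver segmentation) serve as plausibility floors, not reproduction claims.

## Known limitations

* The deformable registration recovers the deformation near the liver
  boundary (where the image evidence lives); deep-interior displacement is
  constrained only by the springs, so the field inside a featureless liver
  is an extrapolation — exactly the regime the Jacobian QC is meant to
  flag.
* Expert manual adjustment of the liver mask and the interactive review of
  the fitted plane are not modelled.
* Rigid recovery is validated for shifts ≤ 8 mm and small rotations,
  matching the clinical same-session CBCT setting.
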