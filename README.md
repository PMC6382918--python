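# sirtplan

Multi-modal image analysis for planning yttrium-90 radioembolization
(SIRT) of liver malignancies.

Before SIRT, several studies are acquired: a ⁹⁹ᵐTc-MAA SPECT/CT that
simulates the microsphere distribution, an ¹⁸F-FDG PET/CT showing the
tumor burden, and per-lobe contrast-enhanced cone-beam CTs (CBCT) that
outline the liver *perfusion territories* (LPTs) of the hepatic-artery
branches. Planning the administered activity requires all of these in one
frame, plus segmentations of the liver, the tumors and the two LPTs.
`sirtplan` provides that chain for physicists and method developers:

* **Registration** — rigid SSD alignment of the CBCTs and their average
  ("meta-CBCT", union field of view, suppressed enhancement), then
  deformable registration to the MAA-study CT driven by mutual information
  and regularised by tissue-class-dependent spring rigidity (a stiff
  liver, lax surroundings); the PET is warped with its CT's field. The
  Jacobian determinant of the field, summarised over the liver, its 10-mm
  erosion and the boundary shell, serves as volume-preservation QC.
* **Liver segmentation** — joint region growing on the co-registered
  (CT_MAA, CT_FDG, PET) triple from sparse manual contours: a voxel joins
  only if acceptable in *every* modality
  (stage 1: |v−μⁱ| ≤ 2σⁱ; stage 2: k₁ⁱσⁱ ≤ v−μⁱ ≤ k₂ⁱσⁱ with
  (−2.5, 2)/(−2.5, 2)/(−2, ∞) for CT_MAA/CT_FDG/PET and a PET cap of
  SUV 2.5), finished by 3-mm closing/opening.
* **Tumor segmentation** — adaptive PET thresholding:
  THR_init = μ + 2.802σ finds the cores; each core gets its own threshold
  THR = BG + 0.41·(SUV_max − BG) with BG the mean sub-2.5-SUV value in a
  25-mm dilation.
* **LPT splitting** — a total-least-squares plane fitted to expert lines
  on ≥3 transverse slices splits the liver; two splits are compared with
  Vdiff, Rratio/Lratio and surface distances (aHD/mHD).
* **Segmentation metrics** — Dice, TPR, PPV, RV and average/maximum
  Hausdorff distances between surface voxels (mm, anisotropy-aware).
* **Partition-model dosimetry** — IA = D·m/49.380 GBq (ρ = 1.03 g/cm³)
  per lobe; a simulation quantifies the dose error made by prescribing on
  anatomical (CT) lobes when the perfusion (CBCT) lobes are the truth:
  D = 40·(m_CT/m_CBCT) Gy per lobe.
* **Phantoms** — synthetic multi-modal patients (known liver/lobe/tumor
  masks, analytic deformation field with closed-form Jacobian, per-lobe
  CBCT enhancement, seeded noise) so the whole chain is testable without
  clinical data.

## Worked example

```python
import numpy as np
import sirtplan as sp

# a synthetic patient: 64³ @ 2.5 mm, 6-mm deformation, CT noise 20 HU
study = sp.generate_phantom(sp.PhantomSpec(seed=0))
truth = study.truth

# register the FDG-frame CT onto the MAA frame
fixed  = sp.median_filter_stack(study.ct_maa, 1)
moving = sp.median_filter_stack(study.ct_fdg, 1)
classes = sp.classify_tissue(fixed, truth.liver)
field = sp.register_deformable(moving, fixed, classes)

warped_liver = sp.warp(truth.liver_fdg, field, "nearest")
print("liver Dice after registration:",
      round(sp.overlap_metrics(warped_liver, truth.liver).dice, 3))

jac = sp.jacobian_determinant(field)
stats = sp.jacobian_stats(jac, truth.liver)
print("liver Jacobian median:", round(stats.entire["median"], 3),
      "nonpositive fraction:", stats.nonpositive_fraction)

# bring the FDG-frame images into the MAA frame, then segment the liver
# jointly from sparse contours and grade it against truth
ct_fdg_reg = sp.warp(moving, field)
pet_reg = sp.warp(study.pet_fdg, field)
ann, lines = sp.annotate_phantom(truth, every_n=6)
liver = sp.segment_liver([fixed, ct_fdg_reg, pet_reg], ann, r_vox=8)
print("segmentation Dice:",
      round(sp.overlap_metrics(liver, truth.liver).dice, 3))

# split into perfusion territories and simulate the dosimetry impact
from sirtplan import lobes, dosimetry
plane_cbct = lobes.fit_plane(lines)
plane_ct = lobes.PlaneModel(plane_cbct.normal, plane_cbct.offset + 6.0)
split_cbct = lobes.split_liver(truth.liver, plane_cbct)
split_ct = lobes.split_liver(truth.liver, plane_ct)
rep = dosimetry.dose_impact(split_ct, split_cbct, d_target_gy=40.0)
for lobe in rep.lobes:
    print(f"{lobe.name} lobe: {lobe.dose_gy:.1f} Gy "
          f"({lobe.deviation_gy:+.1f} Gy vs 40 Gy target)")
```

Output:

```
liver Dice after registration: 0.97
liver Jacobian median: 1.008 nonpositive fraction: 0.0
segmentation Dice: 0.934
left lobe: 49.4 Gy (+9.4 Gy vs 40 Gy target)
right lobe: 35.0 Gy (-5.0 Gy vs 40 Gy target)
```

The deformable registration raises the liver overlap from 0.94 (unregistered)
to 0.97 with a volume-preserving, fold-free field; the joint region growing
recovers the liver to Dice 0.93 under 20 HU CT noise; and a 6-mm error in
the lobe-separating plane already shifts the delivered mean dose by about
±5–10 Gy per lobe at a 40 Gy prescription — the motivation for delineating
perfusion territories on CBCT rather than anatomical landmarks.

## Command line

Each stage is exposed as a subcommand writing NIfTI/JSON:

```bash
sirtplan phantom --seed 0 --out ph/ --every-n 6
sirtplan register --fixed ph/ct_maa.nii.gz --moving ph/ct_fdg.nii.gz \
                  --liver-hint ph/truth_liver.nii.gz --out field.nii.gz
sirtplan jacobian field.nii.gz --liver ph/truth_liver.nii.gz --report jac.json
sirtplan segment-liver --ct-maa ph/ct_maa.nii.gz --ct-fdg ph/ct_fdg.nii.gz \
                       --pet ph/pet_fdg.nii.gz --annotations ph/annotations.json \
                       --r-vox 8 --out liver.nii.gz
sirtplan segment-tumor --pet-suv ph/pet_fdg.nii.gz --liver liver.nii.gz --out-dir tumors/
sirtplan split-lobes --liver liver.nii.gz --lines ph/lobe_lines.json --out-prefix lobes
sirtplan metrics --test liver.nii.gz --gold ph/truth_liver.nii.gz --out metrics.json
sirtplan dosimetry --ct-left ct_left.nii.gz --ct-right ct_right.nii.gz \
                   --cbct-left cbct_left.nii.gz --cbct-right cbct_right.nii.gz \
                   --out dose.json
```

All randomness flows from `--seed`; outputs are bit-reproducible.

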