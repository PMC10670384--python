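# Methods

## The problem

Stereotactic EEG (SEEG) localises epileptogenic tissue with depth
electrodes implanted through the skull. The post-implant CT shows the
electrodes with high contrast but little soft-tissue anatomy; the
pre-implant MRI shows anatomy but no electrodes. Clinical review therefore
works on a fused image: the MRI rigidly registered to the CT, with the
segmented electrodes overlaid.

Rigid CT–MRI registration conventionally maximises mutual information
(MI), estimated from a joint intensity histogram over sampled voxel pairs.
Electrodes violate MI's implicit assumption that the two images depict the
same tissue: metal voxels (≥1500 HU) exist only in the CT. Samples drawn
from them contribute joint-histogram mass with no anatomical counterpart
and can bias or destabilise the optimisation. The method implemented here
removes those samples: the electrodes are segmented from the CT, and the
complement of the segmentation is used as a *sampling mask* restricting
which fixed-image voxels the metric may sample.

## Pipeline

1. **Initial electrode segmentation** (`segmentation`). Threshold the CT
   at the closed window [1500, 3000] HU. Because cortical bone overlaps
   this window ([300, 1900] HU), a skull mask is built — threshold
   [300, 1900], erode with the 7-voxel 6-connected cross (3×3×3), close
   and dilate with a discrete Euclidean ball (nominal extent 4, realised
   as radius 2 since an even kernel has no centre voxel) — and combined
   through mask algebra: head mask (Otsu + 3-D hole filling) AND
   NOT(skull) gives a brain-region mask; electrode threshold AND
   brain-region gives the initial electrode mask. Contested voxels in the
   overlap band [1500, 1900] are resolved purely by this algebra, in this
   order; no extra arbitration.
2. **Sampling mask**: voxelwise complement of the electrode mask.
3. **Masked registration** (`registration`). 6-DOF rigid transform (a
   12-DOF affine mode exists behind `RegistrationConfig.mode`), Mattes MI
   with 50 bins, random sampling of 20 % of voxels *rejected outside the
   mask*, 3-level pyramid (shrink 4/2/1, smoothing 2/1/0 voxels),
   regular-step gradient descent (initial step 2 mm-equivalent,
   relaxation 0.8, minimum step 1e-4, ≤300 iterations per level, scales
   from physical shift), geometric-centre initialisation. A larger
   initial step converges faster on gross misalignments but oscillates
   within the sampling-noise ball near the optimum and loses sub-voxel
   precision; the smaller default favours precision. A sampling
   fraction of 1.0 reduces masked sampling to deterministic exclusion.
   All of this machinery is SimpleITK's; this package owns the mask
   plumbing, configuration and conventions. Seeded sampling makes results
   reproducible run-to-run on one machine.
4. **Brain extraction** (`brain`). The pipeline needs a brain mask from
   the registered MRI only to discard residual bone. Production-grade
   skull stripping (e.g. ROBEX, BET) is treated as an external, pluggable
   provider (`command`); the built-in provider (Otsu → largest component
   → opening, ball radius 2 → hole fill) is a deliberately simple
   surrogate adequate for phantoms; a `file` provider loads ground truth.
5. **Refinement**: initial electrode mask AND brain mask.
6. **Merging** (`fusion`): electrode voxels are *overlaid* onto the
   registered MRI at a marker intensity (default: the MRI maximum).
   Arithmetic addition of HU to MRI units would be incoherent.

### Transform conventions

Transforms map **fixed-image (CT) world points into moving-image (MRI)
space** — the resampling convention of ITK-family toolkits — and act as
`p' = M (p − c) + c + t` about a centre `c` in world mm. Fiducial
evaluation uses the same objects directly, so a registration result both
resamples the MRI and maps evaluation points with no sign juggling. World
coordinates come from the NIfTI affine (voxel-centre anchored); no axis
flipping is performed anywhere. `perturb_moving(mri, t)` produces an
image satisfying `out(x) = mri(t(x))`, so the registration that undoes it
recovers `t.inverse()`.

## Evaluation metrics

* **Fiducial error**: Euclidean distance in mm between reference and test
  points; summaries report median, mean and sample sd (n−1). The headline
  statistic of the validation protocol is the **median** — recomputing
  the bundled 64-value validation table confirms the published headline
  values (1.3176 masked / 1.2789 unmasked) are the medians, not means.
* **MI**: joint-histogram estimate, base-2 logs, 0·log 0 ≡ 0.
* **SSIM**: mean over 7³ uniform windows of
  luminance^α·contrast^β·structure^γ (defaults α=β=γ=1, constants
  K₁=0.01, K₂=0.03), borders cropped to full windows. With unit
  exponents this matches scikit-image's implementation, which the test
  suite uses as an independent cross-check.
* **RMSE**: the *literal* form is the square root of the **sum** of
  squared differences (no division), because the reference results for
  this method are only consistent with that unnormalised scale; the
  conventional normalised form is also provided and the two are related
  exactly by √(voxel count).
* **PSNR**: `10·log10((MNP)² / RMSE_literal)` with a flagged infinity at
  RMSE 0. The formula's rendering in the source material is ambiguous;
  this reading is isolated in one function so it can be swapped.

### A note on the bundled clinical distance table

Recomputing the distances from the bundled clinical coordinates
reproduces the distance table only with the two method columns
interchanged relative to their printed labels (verified on all 20 cells,
max deviation 0.0005 mm). The fixture loaders return the numerically
consistent pairing rather than silently preserving the inconsistent
labels.

## The phantom generator

`phantom.make_head_phantom` builds a co-registered CT/MRI pair: an
ellipsoidal head (default semi-axes 70/85/75 mm on a 160³ grid at
1.5 mm), nested scalp (5 mm), skull shell (6 mm, CT band 400–1400 HU,
inside the [300, 1900] segmentation window before noise), brain interior,
and two off-centre ventricle-like inclusions that break mirror symmetry
and anchor rotation. MRI tissue values are T1-like (brain 500, skull 80,
scalp 300, ventricle 900 a.u.); the MRI brain additionally carries smooth
random intensity lumps (amplitude ±80, radius 18 mm) because a perfectly
uniform brain would make electrode voxels carry no metric information at
all. Gaussian noise: 10 HU (CT), 15 a.u. (MRI). All outputs are
bit-reproducible per seed.

`insert_electrodes` implants flat-capped cylinders (defaults: 12
electrodes, 3 mm diameter, 80 mm length, per-voxel intensities uniform in
[1500, 3000] HU — per-voxel rather than per-electrode, the harsher
segmentation test; a constant-intensity mode exists). Axes are rejected
unless they lie wholly inside the eroded brain mask, and pairwise axis
distance must exceed diameter + √3·spacing + 1 mm so voxelised electrodes
can never touch under 26-connectivity — component counting stays
well-defined. The exact voxelisation is returned as ground truth.

What the phantom does **not** model: real cortical folding, CT
beam-hardening and metal artefacts, MRI bias fields, partial-volume
effects at real slice thicknesses, and ROBEX-grade skull-stripping
difficulty. Passing phantom tests demonstrates the pipeline's mask
algebra, geometry handling and registration behaviour under controlled
conditions, not clinical-grade accuracy.

## The simulated validation experiment

`pipeline.run_simulated_experiment` mirrors the synthetic validation
protocol: per seed, (1) build a phantom pair; (2) implant electrodes;
(3) add focal tissue variations; (4) misalign the MRI by a known random
rigid transform (defaults ≤6°, ≤10 mm); (5) register the *clean* CT to
the misaligned MRI to obtain the reference transform and reference
corner points; (6) register the electrode CT twice — with the
segmentation-derived sampling mask and without any mask; (7) report
per-corner Euclidean errors of both arms against the reference. The
with-mask arm deliberately uses the *segmented* mask so segmentation
errors propagate realistically; `use_truth_mask=True` isolates pure
registration behaviour.

Tissue variations emulate brain tissue that changed between the MRI and
CT acquisitions in areas the electrodes traverse (pathology evolution,
implantation-induced edema, small local shifts): chains of spheres
(radius 6 mm, intensity offset −400 a.u.) along the middle 60 % of six of
the twelve trajectories, displaced 5 mm along a random perpendicular.
The displacement gives the inconsistent tissue coherent structure *near*
the metal tracks: the unmasked metric samples electrode voxels whose
joint-histogram contribution favours poses aligning metal with the
displaced structure, while the masked metric never sees them. On-track
(zero-offset) variations produce a weaker effect because with them the
electrode voxels' preferred pose coincides with the true one.

## Problem sizes and defaults used in testing

The test suite and the experiment run on a 96×104×96 grid at 2 mm
(head semi-axes 62/76/66 mm) — the package's chosen working size for
routine validation, with the 160³/1.5 mm generator default exercised by
the acceptance script. Parameter recovery uses misalignments within
8°/12 mm (inside the 10°/15 mm envelope the protocol targets), 10 seeds
per experiment. The registration defaults above were fixed after a
small optimiser sweep on translation/rotation recovery; they are exposed
in `RegistrationConfig` and in the YAML pipeline config.

## Known limitations

* The built-in brain extractor is not a substitute for a shape-model
  tool on clinical MRI; use the `command` provider for real data.
* Only rigid (and optionally affine) alignment; no deformable step, so
  genuine brain shift between acquisitions is out of scope.
* The literal-RMSE/PSNR readings cannot be verified against clinical
  values without the original images; they are documented and isolated.
* Electrode contacts are not rendered (the cylinders are homogeneous);
  `ElectrodeSpec` records the eight-contact/10 mm-pitch geometry the
  dimensions mirror, but the validation protocol does not image it.
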