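# seegfuse

Electrode-aware CT–MRI fusion for stereotactic EEG (SEEG).

After SEEG electrode implantation, clinicians review a fused image: the
pre-implant MRI rigidly registered onto the post-implant CT, with the
electrodes overlaid. The registration conventionally maximises mutual
information

    MI(I_i, I_f) = H(I_i) + H(I_f) − H(I_i, I_f),

but metal electrodes exist only in the CT and voxels sampled from them
mislead the metric. `seegfuse` implements a fusion pipeline that accounts
for them:

1. segment the electrodes from the CT (threshold [1500, 3000] HU plus
   skull/head mask algebra);
2. form a **sampling mask** — the complement of the electrode mask;
3. register the MRI to the CT with Mattes MI sampled **only at
   non-electrode voxels** (6-DOF rigid, gradient descent, 3-level pyramid);
4. extract a brain mask from the registered MRI (pluggable provider;
   use your skull stripper of choice for clinical data);
5. refine the electrode mask with the brain mask;
6. overlay the electrodes onto the registered MRI at a marker intensity.

Registration accuracy is quantified as the Euclidean fiducial error
`‖P_R − P‖₂` (mm) at reference points, and fusion quality by MI, SSIM,
RMSE and PSNR. A fully synthetic head-phantom generator (ellipsoidal head,
skull shell, implanted 3 mm × 80 mm electrode cylinders at random poses)
makes every stage testable without any external dataset.

## Worked example

```python
import numpy as np
import seegfuse as sf

# a synthetic head with 12 implanted electrodes, misaligned by a known pose
pair = sf.make_head_phantom(sf.PhantomConfig(
    dims=(96, 104, 96), spacing=(2.0, 2.0, 2.0),
    head_semiaxes_mm=(62.0, 76.0, 66.0), seed=7))
ct, truth, _ = sf.insert_electrodes(pair.ct, pair.brain_mask,
                                    sf.ElectrodeSpec(), seed=11)
pose = sf.RigidTransform.from_euler(np.deg2rad([4, -6, 8]), [5, -3, 9],
                                    center=0.5 * np.asarray(ct.extent_mm))
mri = sf.perturb_moving(pair.mri, pose.inverse())

result = sf.run_fusion_pipeline(ct, mri, sf.FusionConfig(
    registration=sf.RegistrationConfig(seed=1)))

err = np.linalg.norm(result.transform.apply(pair.fiducials.coords)
                     - pose.apply(pair.fiducials.coords), axis=1)
print("electrode components:", sf.count_components(result.electrodes_final))
print("corner-point error (mm): max %.2f median %.2f" % (err.max(), np.median(err)))
```

prints

```
electrode components: 12
corner-point error (mm): max 0.98 median 0.84
```

i.e. all 12 electrodes were segmented and merged, and the masked
registration recovered the known misalignment to under half a voxel at
the volume corners (the hardest points, where rotation errors are
amplified most).

Short narrative scripts in `examples/` demonstrate each capability:
phantom simulation, electrode segmentation, masked registration recovery,
the fusion metrics, and the masked-vs-unmasked experiment. A thin CLI
exposes the same steps (`seegfuse simulate | segment | register | fuse |
evaluate | experiment | pipeline`).

## Documentation

`docs/methods.md` describes the model, conventions (world-mm coordinates,
fixed-to-moving transforms), the phantom's assumptions and limits, and
every numerical default with its rationale.
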