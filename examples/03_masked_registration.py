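"""Recover a known misalignment with electrode-masked MI registration.

The MRI is displaced by a known rigid pose; the electrode CT is registered
back with the sampling mask, and the error is read off at the volume
corner fiducials (where rotation errors hurt most).
"""

import numpy as np

import seegfuse as sf

pair = sf.make_head_phantom(sf.PhantomConfig(
    dims=(96, 104, 96), spacing=(2.0, 2.0, 2.0),
    head_semiaxes_mm=(62.0, 76.0, 66.0), seed=7))
ct, _, _ = sf.insert_electrodes(pair.ct, pair.brain_mask,
                                sf.ElectrodeSpec(), seed=11)

pose = sf.RigidTransform.from_euler(np.deg2rad([4, -6, 8]), [5, -3, 9],
                                    center=0.5 * np.asarray(ct.extent_mm))
mri = sf.perturb_moving(pair.mri, pose.inverse())

mask = sf.make_sampling_mask(sf.segment_electrodes_initial(ct))
res = sf.register(ct, mri, mask, sf.RegistrationConfig(seed=1))

corners = pair.fiducials.coords
err = np.linalg.norm(res.transform.apply(corners) - pose.apply(corners), axis=1)
print(f"metric (negative MI): {res.final_metric:.4f}  "
      f"iterations: {res.iterations_run}  converged: {res.converged}")
print("corner-point recovery error (mm):", np.round(err, 3))
print(f"max {err.max():.3f} mm on a {ct.spacing[0]} mm grid "
      "- sub-voxel recovery of a 6-DOF pose")
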