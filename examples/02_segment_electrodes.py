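"""Segment implanted electrodes from a phantom CT.

Shows the mask algebra: HU threshold, skull removal by morphology, head
mask, and the final brain-restricted electrode mask, scored against the
generator's ground truth.
"""

import seegfuse as sf

pair = sf.make_head_phantom(sf.PhantomConfig(
    dims=(96, 104, 96), spacing=(2.0, 2.0, 2.0),
    head_semiaxes_mm=(62.0, 76.0, 66.0), seed=7))
ct, truth, _ = sf.insert_electrodes(pair.ct, pair.brain_mask,
                                    sf.ElectrodeSpec(), seed=11)

thresholded = sf.threshold_range(ct, sf.ELECTRODE_WINDOW)
segmented = sf.segment_electrodes_initial(ct)
refined = sf.refine_electrodes(segmented, pair.brain_mask)

tp = (refined.as_bool & truth.as_bool).sum()
print(f"raw threshold [1500, 3000] HU:  {int(thresholded.data.sum())} voxels "
      "(on clinical CT this also catches dense bone; the phantom skull "
      "band tops out below the window)")
print(f"after skull/head mask algebra:  {int(segmented.data.sum())} voxels")
print(f"after brain-mask refinement:    {int(refined.data.sum())} voxels")
print(f"recall vs ground truth: {tp / truth.data.sum():.3f}  "
      f"(components: {sf.count_components(refined)} of 12 electrodes)")

sampling = sf.make_sampling_mask(segmented)
print(f"sampling mask covers {sampling.data.mean():.4%} of voxels "
      "(everything except detected electrodes)")
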