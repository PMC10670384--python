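import numpy as np
import pytest
from scipy import ndimage

import seegfuse as sf
from seegfuse.errors import ContractError, GeometryError
from seegfuse.segmentation import ELECTRODE_WINDOW, SKULL_WINDOW, HUWindow


class TestThresholdRange:
    @pytest.mark.parametrize("value,expected", [
        (2000, 1), (1500, 1), (3000, 1),   # inside, inclusive bounds
        (1200, 0), (1499.9, 0), (3000.1, 0),
    ])
    def test_electrode_window_membership(self, value, expected):
        v = sf.Volume(np.full((2, 2, 2), value, dtype=np.float32))
        assert sf.threshold_range(v, ELECTRODE_WINDOW).data.flat[0] == expected

    def test_zero_volume_gives_empty_mask(self):
        v = sf.Volume(np.zeros((4, 4, 4)))
        assert sf.threshold_range(v, ELECTRODE_WINDOW).data.sum() == 0

    def test_invalid_window_rejected(self):
        with pytest.raises(ContractError):
            HUWindow(3000, 1500)

    def test_mask_matches_direct_scan(self, phantom_with_electrodes):
        """Defining property: voxel is 1 iff its intensity lies in the window."""
        _, ct, _, _ = phantom_with_electrodes
        mask = sf.threshold_range(ct, ELECTRODE_WINDOW)
        expected = (ct.data >= 1500) & (ct.data <= 3000)
        assert np.array_equal(mask.as_bool, expected)

    def test_constant_intensity_cylinder_segmented_exactly(self, phantom):
        """A 2200-HU cylinder in ~40-HU brain thresholds to its exact voxelization."""
        spec = sf.ElectrodeSpec(count=1, intensity=2200.0)
        ct, truth, _ = sf.insert_electrodes(phantom.ct, phantom.brain_mask, spec, seed=2)
        mask = sf.threshold_range(ct, ELECTRODE_WINDOW)
        assert np.array_equal(mask.data, truth.data)


class TestSkullMask:
    def test_uniform_air_ct_gives_empty_mask(self):
        ct = sf.Volume(np.full((12, 12, 12), -1000, dtype=np.float32))
        assert sf.make_skull_mask(ct).data.sum() == 0

    def test_covers_shell_and_misses_interior_electrodes(self, phantom_with_electrodes):
        phantom_pair, ct, truth, _ = phantom_with_electrodes
        skull = sf.make_skull_mask(ct)
        shell = phantom_pair.labels == 2  # generator's skull label
        # most of the bone shell is recovered
        assert (skull.as_bool & shell).sum() / shell.sum() > 0.5
        # no electrode voxel deep inside the brain survives in the skull mask
        interior = ndimage.binary_erosion(phantom_pair.brain_mask.as_bool, iterations=3)
        assert not (skull.as_bool & truth.as_bool & interior).any()

    def test_thin_plate_removed_by_erosion(self):
        """A 1-voxel bone plate cannot survive the 3x3x3 cross erosion."""
        data = np.full((9, 9, 9), -1000, dtype=np.float32)
        data[4, :, :] = 800.0  # one-voxel-thick plate in the bone window
        ct = sf.Volume(data)
        # oracle: erosion of a 1-thick slab with the 6-connected cross is empty,
        # so the whole pipeline must return an empty mask
        assert sf.make_skull_mask(ct).data.sum() == 0


class TestMaskAlgebra:
    def test_no_skull_is_complement_and_involution(self, rng):
        m = sf.BinaryMask((rng.random((6, 6, 6)) > 0.4).astype(np.uint8))
        c = sf.make_no_skull_mask(m)
        assert np.array_equal(sf.make_no_skull_mask(c).data, m.data)
        assert not (c.data & m.data).any()
        assert ((c.data | m.data) == 1).all()

    def test_empty_skull_complement_is_all_ones(self):
        m = sf.BinaryMask(np.zeros((3, 3, 3), dtype=np.uint8))
        assert sf.make_no_skull_mask(m).data.all()

    def test_brain_region_is_voxelwise_and(self, rng):
        a = sf.BinaryMask((rng.random((5, 5, 5)) > 0.5).astype(np.uint8))
        b = sf.BinaryMask((rng.random((5, 5, 5)) > 0.5).astype(np.uint8))
        assert np.array_equal(sf.make_brain_region_mask(a, b).data, a.data & b.data)

    def test_brain_region_geometry_mismatch(self):
        a = sf.BinaryMask(np.ones((4, 4, 4), dtype=np.uint8))
        b = sf.BinaryMask(np.ones((4, 4, 4), dtype=np.uint8), spacing=(2, 2, 2))
        with pytest.raises(GeometryError):
            sf.make_brain_region_mask(a, b)

    def test_sampling_mask_complements_electrodes(self, rng):
        e = sf.BinaryMask((rng.random((6, 6, 6)) > 0.8).astype(np.uint8))
        s = sf.make_sampling_mask(e)
        assert not (s.data & e.data).any()
        assert ((s.data | e.data) == 1).all()

    def test_empty_electrodes_sample_everywhere(self):
        e = sf.BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8))
        assert sf.make_sampling_mask(e).data.all()


class TestHeadMask:
    def test_constant_image_rejected(self):
        with pytest.raises(ContractError):
            sf.make_head_mask(sf.Volume(np.zeros((5, 5, 5))))

    def test_two_level_image_split_at_brute_force_otsu(self):
        # solid high-level block in low background (no interior holes, so the
        # hole-filling step is a no-op and the mask is purely the Otsu split)
        data = np.zeros((16, 16, 16))
        data[3:12, 2:13, 4:11] = 100.0
        v = sf.Volume(data)
        mask = sf.make_head_mask(v)
        # brute-force Otsu over candidate thresholds: maximal between-class variance
        flat = data.ravel()
        candidates = np.linspace(flat.min(), flat.max(), 256)[1:-1]
        best = max(
            candidates,
            key=lambda t: (flat[flat <= t].size * flat[flat > t].size / flat.size**2)
            * (flat[flat <= t].mean() - flat[flat > t].mean()) ** 2
            if 0 < (flat <= t).sum() < flat.size else -1,
        )
        assert np.array_equal(mask.as_bool, data > best)

    def test_phantom_head_covers_tissue_without_internal_holes(self, phantom):
        mask = sf.make_head_mask(phantom.ct)
        head_truth = phantom.labels > 0
        recall = (mask.as_bool & head_truth).sum() / head_truth.sum()
        assert recall > 0.95
        # flood-fill oracle: no zero voxel unreachable from the border
        outside = np.zeros(mask.dims, bool)
        bg = ~mask.as_bool
        labels, _ = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
        border = np.unique(np.concatenate([
            labels[0].ravel(), labels[-1].ravel(), labels[:, 0].ravel(),
            labels[:, -1].ravel(), labels[:, :, 0].ravel(), labels[:, :, -1].ravel()]))
        interior_holes = bg & ~np.isin(labels, border)
        assert not interior_holes.any()

    def test_interior_cavity_filled(self):
        data = np.full((20, 20, 20), -1000.0)
        data[4:16, 4:16, 4:16] = 100.0
        data[9:11, 9:11, 9:11] = -1000.0  # air cavity
        mask = sf.make_head_mask(sf.Volume(data))
        assert mask.data[10, 10, 10] == 1


class TestElectrodeSegmentation:
    def test_recall_of_implanted_electrodes(self, phantom_with_electrodes):
        phantom_pair, ct, truth, _ = phantom_with_electrodes
        seg = sf.segment_electrodes_initial(ct)
        in_brain = truth.as_bool & phantom_pair.brain_mask.as_bool
        recall = (seg.as_bool & in_brain).sum() / in_brain.sum()
        assert recall >= 0.95

    def test_segmentation_subset_of_threshold(self, phantom_with_electrodes):
        _, ct, _, _ = phantom_with_electrodes
        seg = sf.segment_electrodes_initial(ct)
        thresholded = sf.threshold_range(ct, ELECTRODE_WINDOW)
        assert not (seg.as_bool & ~thresholded.as_bool).any()

    def test_electrode_free_ct_near_empty(self, phantom):
        seg = sf.segment_electrodes_initial(phantom.ct)
        assert seg.data.sum() < 0.001 * phantom.brain_mask.data.sum()

    def test_all_air_ct_empty(self):
        rng = np.random.default_rng(0)
        ct = sf.Volume(rng.normal(-1000, 5, (16, 16, 16)).astype(np.float32))
        assert sf.segment_electrodes_initial(ct).data.sum() == 0

    def test_component_count_matches_electrode_count(self, phantom_with_electrodes):
        phantom_pair, ct, truth, _ = phantom_with_electrodes
        seg = sf.segment_electrodes_initial(ct)
        final = sf.refine_electrodes(seg, phantom_pair.brain_mask)
        assert sf.count_components(final) == 12

    def test_sampling_mask_excludes_detected_electrodes(self, phantom_with_electrodes):
        _, ct, truth, _ = phantom_with_electrodes
        seg = sf.segment_electrodes_initial(ct)
        sampling = sf.make_sampling_mask(seg)
        detected = seg.as_bool & truth.as_bool
        assert not sampling.as_bool[detected].any()


class TestRefineElectrodes:
    def test_removes_fragment_outside_brain(self):
        initial = np.zeros((10, 10, 10), dtype=np.uint8)
        initial[2, 2, 2] = 1    # bone fragment
        initial[6, 6, 6] = 1    # electrode voxel
        brain = np.zeros_like(initial)
        brain[5:9, 5:9, 5:9] = 1
        out = sf.refine_electrodes(sf.BinaryMask(initial), sf.BinaryMask(brain))
        assert out.data[6, 6, 6] == 1 and out.data[2, 2, 2] == 0

    def test_full_brain_mask_is_identity(self, rng):
        init = sf.BinaryMask((rng.random((6, 6, 6)) > 0.7).astype(np.uint8))
        ones = sf.BinaryMask(np.ones((6, 6, 6), dtype=np.uint8))
        assert np.array_equal(sf.refine_electrodes(init, ones).data, init.data)

    def test_output_subset_of_both_inputs(self, rng):
        a = sf.BinaryMask((rng.random((6, 6, 6)) > 0.5).astype(np.uint8))
        b = sf.BinaryMask((rng.random((6, 6, 6)) > 0.5).astype(np.uint8))
        out = sf.refine_electrodes(a, b)
        assert not (out.as_bool & ~a.as_bool).any()
        assert not (out.as_bool & ~b.as_bool).any()

    def test_no_voxel_outside_brain_after_full_pipeline(self, phantom_with_electrodes):
        phantom_pair, ct, _, _ = phantom_with_electrodes
        seg = sf.segment_electrodes_initial(ct)
        final = sf.refine_electrodes(seg, phantom_pair.brain_mask)
        assert not (final.as_bool & ~phantom_pair.brain_mask.as_bool).any()
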