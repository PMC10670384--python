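import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.metrics import structural_similarity as skimage_ssim

import seegfuse as sf
from seegfuse.errors import ContractError, GeometryError
from seegfuse.metrics import SsimParams, entropy_bits


class TestEuclideanError:
    def test_printed_clinical_pair(self):
        """Pineal-gland localisation: CT vs mask-registered MRI, image 1."""
        d = sf.euclidean_error((1.399, 132.381, 139.294), (-0.381, 134.024, 139.112))
        assert d == pytest.approx(2.429, abs=1e-3)

    def test_identical_points_zero(self):
        assert sf.euclidean_error((1, 2, 3), (1, 2, 3)) == 0.0

    def test_3_4_5_triangle(self):
        assert sf.euclidean_error((0, 0, 0), (3, 4, 0)) == 5.0

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.uniform(-100, 100, (3, 3))
        dab = sf.euclidean_error(a, b)
        assert dab >= 0
        assert dab == pytest.approx(sf.euclidean_error(b, a))
        assert dab <= sf.euclidean_error(a, c) + sf.euclidean_error(c, b) + 1e-9


class TestFiducialErrors:
    def test_printed_anterior_commissure_distance(self):
        """CT vs no-mask-registered MRI, image 3, anterior commissure."""
        d = sf.euclidean_error((-0.425, 170.072, -410.326), (-0.905, 169.695, -409.541))
        assert d == pytest.approx(0.994, abs=1e-3)

    def test_identical_sets_all_zero(self):
        s = sf.FiducialSet.from_arrays(["a", "b"], [[0, 0, 0], [1, 1, 1]])
        assert np.allclose(sf.fiducial_errors(s, s), 0)

    def test_unit_offset_all_ones(self):
        a = sf.FiducialSet.from_arrays(["a", "b"], [[0, 0, 0], [5, 5, 5]])
        b = sf.FiducialSet.from_arrays(["a", "b"], [[1, 0, 0], [6, 5, 5]])
        assert np.allclose(sf.fiducial_errors(a, b), 1)

    def test_label_mismatch_rejected(self):
        a = sf.FiducialSet.from_arrays(["a"], [[0, 0, 0]])
        b = sf.FiducialSet.from_arrays(["b"], [[0, 0, 0]])
        with pytest.raises(ContractError):
            sf.fiducial_errors(a, b)

    def test_csv_roundtrip(self, tmp_path):
        s = sf.FiducialSet.from_arrays(["p1", "p2"], [[0.5, -1.25, 3.0], [4, 5, 6]])
        s.to_csv(tmp_path / "f.csv")
        back = sf.FiducialSet.from_csv(tmp_path / "f.csv")
        assert back.labels == s.labels
        assert np.allclose(back.coords, s.coords)


class TestSummarizeErrors:
    def test_hand_computed_example(self):
        s = sf.summarize_errors([1, 2, 3, 4])
        assert s.median == 2.5
        assert s.mean == 2.5
        assert s.sd == pytest.approx(1.2910, abs=1e-4)

    def test_constant_list(self):
        s = sf.summarize_errors([2.5, 2.5, 2.5])
        assert s.sd == 0.0 and s.median == 2.5

    def test_single_value_rejected(self):
        with pytest.raises(ContractError):
            sf.summarize_errors([1.0])

    def test_median_permutation_invariant(self, rng):
        vals = rng.uniform(0, 10, 17)
        s1 = sf.summarize_errors(vals)
        s2 = sf.summarize_errors(rng.permutation(vals))
        assert s1.median == s2.median and s1.mean == pytest.approx(s2.mean)


class TestMutualInformation:
    def test_self_mi_equals_entropy(self, rng):
        v = sf.Volume(rng.integers(0, 16, (20, 20, 20)).astype(float))
        mi = sf.mutual_information_metric(v, v, bins=16)
        h, _ = np.histogram(v.data, bins=16)
        assert mi == pytest.approx(entropy_bits(h), abs=1e-12)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        a = sf.Volume(rng.random((100, 100, 100)))
        b = sf.Volume(rng.random((100, 100, 100)))
        assert sf.mutual_information_metric(a, b, bins=16) < 0.01

    def test_known_joint_distribution(self):
        """Joint pmf (0.4, 0.1 / 0.1, 0.4) has MI = 0.278 bits (brute force)."""
        n = 10  # 1000 voxels split 400/100/100/400
        data_a = np.zeros((n, n, n))
        data_b = np.zeros((n, n, n))
        flat_a, flat_b = data_a.ravel(), data_b.ravel()
        flat_a[:400] = 0; flat_b[:400] = 0
        flat_a[400:500] = 0; flat_b[400:500] = 1
        flat_a[500:600] = 1; flat_b[500:600] = 0
        flat_a[600:] = 1; flat_b[600:] = 1
        mi = sf.mutual_information_metric(sf.Volume(data_a), sf.Volume(data_b), bins=2)
        # brute force over the 4 cells
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        expected = sum(
            p[i, j] * math.log2(p[i, j] / (p[i].sum() * p[:, j].sum()))
            for i in range(2) for j in range(2)
        )
        assert mi == pytest.approx(expected, abs=1e-12)
        assert mi == pytest.approx(0.278, abs=1e-3)

    def test_symmetry_and_nonnegativity(self, rng):
        a = sf.Volume(rng.normal(size=(15, 15, 15)))
        b = sf.Volume(rng.normal(size=(15, 15, 15)) + 0.5 * a.data)
        mab = sf.mutual_information_metric(a, b)
        mba = sf.mutual_information_metric(b, a)
        assert mab >= 0
        assert mab == pytest.approx(mba, abs=1e-12)

    def test_geometry_mismatch_rejected(self):
        a = sf.Volume(np.zeros((4, 4, 4)))
        b = sf.Volume(np.zeros((4, 4, 4)), spacing=(2, 2, 2))
        with pytest.raises(GeometryError):
            sf.mutual_information_metric(a, b)


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        v = sf.Volume(rng.normal(size=(12, 12, 12)))
        assert sf.ssim_metric(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_degradation(self, rng):
        v = sf.Volume(rng.normal(0, 1, (16, 16, 16)))
        small = sf.Volume(v.data + rng.normal(0, 0.1, v.dims))
        large = sf.Volume(v.data + rng.normal(0, 2.0, v.dims))
        assert sf.ssim_metric(v, large) < sf.ssim_metric(v, small) < 1.0

    def test_matches_independent_reference_implementation(self, rng):
        """Cross-check against scikit-image's SSIM (uniform window, same constants)."""
        a = rng.normal(0, 1, (20, 20, 20))
        b = a + rng.normal(0, 0.5, a.shape)
        dr = float(max(a.max(), b.max()) - min(a.min(), b.min()))
        ours = sf.ssim_metric(sf.Volume(a), sf.Volume(b), data_range=dr)
        theirs = skimage_ssim(a, b, win_size=7, data_range=dr, gaussian_weights=False)
        assert ours == pytest.approx(theirs, abs=5e-3)

    def test_unit_exponents_equal_product_form(self, rng):
        a = sf.Volume(rng.normal(size=(10, 10, 10)))
        b = sf.Volume(rng.normal(size=(10, 10, 10)))
        default = sf.ssim_metric(a, b)
        explicit = sf.ssim_metric(a, b, SsimParams(alpha=1.0, beta=1.0, gamma=1.0))
        assert default == explicit


class TestRmsePsnr:
    def test_identical_zero(self, rng):
        v = sf.Volume(rng.normal(size=(6, 6, 6)))
        assert sf.rmse_metric(v, v) == 0.0

    def test_literal_sum_form(self):
        # 2x2(x1) images differing by 1 everywhere: sqrt(4) = 2
        a = sf.Volume(np.zeros((2, 2, 1)))
        b = sf.Volume(np.ones((2, 2, 1)))
        assert sf.rmse_metric(a, b) == pytest.approx(2.0)
        assert sf.rmse_metric(a, b, normalized=True) == pytest.approx(1.0)

    def test_literal_equals_normalized_times_sqrt_n(self, rng):
        a = sf.Volume(rng.normal(size=(7, 8, 9)))
        b = sf.Volume(rng.normal(size=(7, 8, 9)))
        n = np.prod(a.dims)
        assert sf.rmse_metric(a, b) == pytest.approx(
            sf.rmse_metric(a, b, normalized=True) * math.sqrt(n), rel=1e-12
        )

    def test_psnr_literal_formula(self):
        # 2x2(x1) pair with literal RMSE 2: 10*log10(16/2) = 9.031
        a = sf.Volume(np.zeros((2, 2, 1)))
        b = sf.Volume(np.ones((2, 2, 1)))
        assert sf.psnr_metric(a, b) == pytest.approx(10 * math.log10(16 / 2), abs=1e-9)
        assert sf.psnr_metric(a, b) == pytest.approx(9.031, abs=1e-3)

    def test_psnr_drops_3dB_when_rmse_doubles(self, rng):
        base = rng.normal(size=(8, 8, 8))
        a = sf.Volume(base)
        diff = rng.normal(size=(8, 8, 8))
        b1 = sf.Volume(base + diff)
        b2 = sf.Volume(base + 2 * diff)
        drop = sf.psnr_metric(a, b1) - sf.psnr_metric(a, b2)
        assert drop == pytest.approx(10 * math.log10(2), abs=1e-9)

    def test_psnr_infinite_for_identical(self, rng):
        v = sf.Volume(rng.normal(size=(5, 5, 5)))
        assert math.isinf(sf.psnr_metric(v, v))
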