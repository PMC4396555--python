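"""Quantization, histograms, entropy, MI and SMI estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import smiband as sb
from smiband.infometrics import (
    DissimilarityMatrix,
    Histogram,
    JointHistogram,
    WeightFunction,
    absolute_difference,
    load_dissimilarity_csv,
    save_dissimilarity_csv,
)
from smiband.raster_io import HyperspectralCube


def _plugin_mi_oracle(counts):
    """Independent route: H(X) + H(Y) - H(X,Y) from plain numpy entropies."""

    def H(c):
        c = np.asarray(c, float).ravel()
        p = c[c > 0] / c.sum()
        return float(-(p * np.log2(p)).sum())

    counts = np.asarray(counts, float)
    return H(counts.sum(1)) + H(counts.sum(0)) - H(counts)


class TestQuantize:
    def test_eight_bit_identity(self):
        band = np.arange(256).reshape(16, 16)
        q = sb.quantize(band, 256)
        np.testing.assert_array_equal(q.levels, band)

    def test_constant_band_maps_to_zero(self):
        q = sb.quantize(np.full((3, 3), 7.0), 16)
        assert q.levels.max() == 0

    def test_floor_rule(self):
        q = sb.quantize(np.array([[0.0, 0.5, 1.0]]), 2)
        np.testing.assert_array_equal(q.levels, [[0, 1, 1]])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            sb.quantize(np.zeros((2, 2)), 1)

    @given(
        band=hnp.arrays(
            float, (5, 5), elements=st.floats(-1e6, 1e6, allow_nan=False)
        ),
        n_levels=st.integers(2, 64),
    )
    def test_levels_always_in_range(self, band, n_levels):
        q = sb.quantize(band, n_levels)
        assert q.levels.min() >= 0
        assert q.levels.max() < n_levels


class TestHistograms:
    def test_marginal_counts(self):
        q = sb.quantize(np.array([[0, 0], [1, 1]]), 2)
        h = sb.marginal_histogram(q)
        np.testing.assert_array_equal(h.counts, [2, 2])
        assert h.total == 4

    def test_constant_band_histogram(self):
        h = sb.marginal_histogram(sb.quantize(np.full((3, 3), 5), 4))
        assert h.counts[0] == 9 and h.total == 9

    def test_histogram_invariant_under_shuffle(self, rng):
        band = rng.uniform(0, 1, (8, 8))
        q = sb.quantize(band, 16)
        shuffled = rng.permutation(band.ravel()).reshape(8, 8)
        qs = sb.quantize(shuffled, 16, q.source_min, q.source_max)
        np.testing.assert_array_equal(
            sb.marginal_histogram(q).counts, sb.marginal_histogram(qs).counts
        )

    def test_joint_identical_bands_on_diagonal(self):
        q = sb.quantize(np.array([[0, 1], [2, 3]]), 4)
        jh = sb.joint_histogram(q, q)
        assert jh.total == 4
        np.testing.assert_array_equal(jh.counts, np.eye(4, dtype=int))

    def test_joint_constructed_independence(self):
        qx = sb.quantize(np.array([[0, 0], [1, 1]]), 2)
        qy = sb.quantize(np.array([[0, 1], [0, 1]]), 2)
        np.testing.assert_array_equal(sb.joint_histogram(qx, qy).counts, np.ones((2, 2)))

    def test_joint_swap_transposes(self, rng):
        qa = sb.quantize(rng.uniform(size=(6, 6)), 8)
        qb = sb.quantize(rng.uniform(size=(6, 6)), 8)
        np.testing.assert_array_equal(
            sb.joint_histogram(qa, qb).counts, sb.joint_histogram(qb, qa).counts.T
        )

    def test_joint_marginals_match_marginal_histograms(self, rng):
        qa = sb.quantize(rng.uniform(size=(7, 5)), 8)
        qb = sb.quantize(rng.uniform(size=(7, 5)), 8)
        jh = sb.joint_histogram(qa, qb)
        np.testing.assert_array_equal(jh.marginal_x().counts, sb.marginal_histogram(qa).counts)
        np.testing.assert_array_equal(jh.marginal_y().counts, sb.marginal_histogram(qb).counts)

    def test_shape_mismatch_rejected(self):
        qa = sb.quantize(np.zeros((2, 2)), 4)
        qb = sb.quantize(np.zeros((3, 3)), 4)
        with pytest.raises(ValueError):
            sb.joint_histogram(qa, qb)


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([2, 2], 1.0),
            ([9], 0.0),
            ([3, 1], 0.8112781244591328),  # frozen from -sum p log2 p by hand
        ],
    )
    def test_known_values(self, counts, expected):
        assert sb.entropy(Histogram(np.array(counts))) == pytest.approx(expected, abs=1e-12)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            sb.entropy(Histogram(np.zeros(4)))


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self):
        jh = JointHistogram(np.diag([2, 2]))
        assert sb.mutual_information(jh) == pytest.approx(1.0, abs=1e-12)

    def test_independence_gives_zero(self):
        assert sb.mutual_information(JointHistogram(np.ones((2, 2)))) == 0.0

    def test_fixed_fixture_against_both_oracles(self):
        """Cell-by-cell sum and the entropy identity agree on a 4x4 fixture."""
        counts = np.array([[4, 1, 0, 1], [2, 3, 1, 0], [0, 2, 5, 1], [1, 0, 2, 3]])
        jh = JointHistogram(counts)
        mi = sb.mutual_information(jh)
        assert mi == pytest.approx(0.6165624309340136, abs=1e-9)  # frozen cell-by-cell sum
        assert mi == pytest.approx(_plugin_mi_oracle(counts), abs=1e-9)

    def test_estimator_identity_on_random_histograms(self, rng):
        """The direct sum equals H(X)+H(Y)-H(X,Y) on 200 random tables."""
        for _ in range(200):
            L = int(rng.integers(2, 17))
            counts = rng.integers(0, 50, size=(L, L))
            if counts.sum() == 0:
                counts[0, 0] = 1
            jh = JointHistogram(counts)
            mi = sb.mutual_information(jh)
            assert mi == pytest.approx(_plugin_mi_oracle(counts), abs=1e-9)
            assert mi >= 0.0
            hx = sb.entropy(jh.marginal_x())
            hy = sb.entropy(jh.marginal_y())
            assert mi <= min(hx, hy) + 1e-9


class TestSpatialMutualInformation:
    def test_diagonal_joint_histogram_scores_zero(self, rng):
        counts = np.diag(rng.integers(1, 20, size=8))
        assert sb.spatial_mutual_information(JointHistogram(counts)) == 0.0

    def test_independence_scores_zero(self):
        counts = np.outer([3, 5], [2, 7])
        assert sb.spatial_mutual_information(JointHistogram(counts)) == 0.0

    def test_antidiagonal_fixture(self):
        """Hand-evaluated 2x2 sum: both cells weight 1, log term 1 bit."""
        jh = JointHistogram(np.array([[0, 2], [2, 0]]))
        assert sb.spatial_mutual_information(jh) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        counts = rng.integers(0, 30, size=(6, 6))
        counts[0, 0] += 1
        jh = JointHistogram(counts)
        a = sb.spatial_mutual_information(jh)
        b = sb.spatial_mutual_information(jh.transpose())
        assert a == pytest.approx(b, abs=1e-12)

    def test_asymmetric_weight_rejected(self):
        bad = WeightFunction(fn=lambda x, y, L: np.maximum(x - y, 0), name="bad")
        with pytest.raises(ValueError, match="symmetric"):
            sb.spatial_mutual_information(JointHistogram(np.ones((3, 3))), bad)

    def test_shuffle_sensitivity(self, rng):
        """SMI separates a structured band from its pixel-shuffled copy.

        Marginal statistics cannot: the shuffled copy has the identical
        histogram.  Self-SMI is exactly 0; SMI against the shuffled copy
        is positive.
        """
        band = np.zeros((24, 24))
        band[:, 12:] = 1.0
        band += rng.normal(0, 0.1, band.shape)
        q = sb.quantize(band, 32)
        shuffled = rng.permutation(band.ravel()).reshape(band.shape)
        qs = sb.quantize(shuffled, 32, q.source_min, q.source_max)
        np.testing.assert_array_equal(
            sb.marginal_histogram(q).counts, sb.marginal_histogram(qs).counts
        )
        assert sb.spatial_mutual_information(sb.joint_histogram(q, q)) == 0.0
        assert sb.spatial_mutual_information(sb.joint_histogram(q, qs)) > 0.0


class TestPairwiseDissimilarity:
    def test_identical_bands_mi_zero_matrix(self):
        band = np.arange(16, dtype=float).reshape(4, 4)
        cube = HyperspectralCube(np.stack([band, band, band], axis=2))
        dm = sb.pairwise_dissimilarity(cube, metric="mi", bins=16)
        np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)

    def test_duplicate_pair_is_smi_matrix_minimum(self, rng):
        band = rng.uniform(size=(8, 8))
        other = rng.uniform(size=(8, 8))
        cube = HyperspectralCube(np.stack([band, band.copy(), other], axis=2))
        dm = sb.pairwise_dissimilarity(cube, metric="smi", bins=16)
        assert dm.values[0, 1] == dm.values[:, :].min() == 0.0

    def test_symmetric_and_unit_diagonal_scale(self, rng):
        cube = HyperspectralCube(rng.uniform(size=(8, 8, 5)))
        for metric in ("mi", "smi", "smi-scalar"):
            dm = sb.pairwise_dissimilarity(cube, metric=metric, bins=8)
            np.testing.assert_array_equal(dm.values, dm.values.T)
            assert dm.values.min() >= 0.0 and dm.values.max() <= 1.0

    def test_permutation_equivariance(self, rng):
        data = rng.uniform(size=(8, 8, 5))
        perm = np.array([3, 0, 4, 1, 2])
        d1 = sb.pairwise_dissimilarity(HyperspectralCube(data), metric="smi", bins=8)
        d2 = sb.pairwise_dissimilarity(HyperspectralCube(data[:, :, perm]), metric="smi", bins=8)
        np.testing.assert_allclose(d2.values, d1.values[np.ix_(perm, perm)], atol=1e-12)

    def test_zero_entropy_band_under_mi_warns_and_maxes(self, rng):
        cube = HyperspectralCube(
            np.stack([np.full((4, 4), 3.0), rng.uniform(size=(4, 4))], axis=2)
        )
        with pytest.warns(UserWarning, match="zero-entropy"):
            dm = sb.pairwise_dissimilarity(cube, metric="mi", bins=8)
        assert dm.values[0, 1] == 1.0

    def test_default_bins_rule(self):
        assert sb.infometrics.default_bins(np.arange(256, dtype=np.uint8)) == 256
        assert sb.infometrics.default_bins(np.arange(1000)) == 64
        assert sb.infometrics.default_bins(np.linspace(0, 1, 50)) == 64

    def test_csv_round_trip(self, tmp_path, rng):
        cube = HyperspectralCube(rng.uniform(size=(6, 6, 4)))
        dm = sb.pairwise_dissimilarity(cube, metric="smi", bins=8)
        save_dissimilarity_csv(dm, tmp_path / "d.csv")
        back = load_dissimilarity_csv(tmp_path / "d.csv", metric_name="smi", rescaled=True)
        np.testing.assert_allclose(back.values, dm.values, atol=1e-12)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), "mi", False)
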