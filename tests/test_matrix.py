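"""Contact matrices: binning conservation, ICE balancing, comparisons."""

import numpy as np
import pytest

from diffarch.genome import BinTable
from diffarch.matrix import (
    ContactMatrix, MatrixError, bin_pairs, expected_by_distance, ice_correct,
    log2_ratio_matrix, normalize_to_common_depth, read_triplet_matrix,
    sum_matrices, write_triplet_matrix,
)


def sinkhorn_oracle(a, max_iter=20000, tol=1e-13):
    """Independent symmetric Sinkhorn balancing to equal unit marginals."""
    w = a.copy().astype(float)
    for _ in range(max_iter):
        s = w.sum(axis=1)
        if s.std() / s.mean() < tol:
            break
        w = w / np.sqrt(s)[:, None] / np.sqrt(s)[None, :]
    return w


def random_symmetric(rng, n, low=0.1, high=1.0):
    a = rng.uniform(low, high, (n, n))
    return (a + a.T) / 2


class TestBinPairs:
    def test_adjacent_bin_pair(self):
        bins = BinTable("chr1", 1000, 500)
        m = bin_pairs([(100, 600)], bins)
        assert m.counts[0, 1] == 1 and m.counts[1, 0] == 1
        assert m.total == 1

    def test_intra_bin_pairs_once_on_diagonal(self):
        bins = BinTable("chr1", 1000, 500)
        m = bin_pairs([(10, 20)] * 10, bins)
        assert m.counts[0, 0] == 10
        assert m.total == 10

    def test_mass_conservation_random_pairs(self):
        """Total matrix mass equals the pair count (brute-force tally)."""
        rng = np.random.default_rng(42)
        bins = BinTable("chr1", 100_000, 1000)
        pairs = rng.integers(0, 100_000, size=(1000, 2))
        m = bin_pairs(pairs, bins)
        assert m.total == 1000
        # brute-force tally of one specific cell
        i, j = 3, 7
        expect = sum(
            1 for p1, p2 in pairs
            if {p1 // 1000, p2 // 1000} == {i, j}
        )
        assert m.counts[i, j] == expect

    def test_out_of_range_pair_is_error(self):
        bins = BinTable("chr1", 1000, 500)
        with pytest.raises(MatrixError, match="1500"):
            bin_pairs([(100, 1500)], bins)


class TestSumAndDepth:
    def _mat(self, counts):
        counts = np.asarray(counts, dtype=float)
        return ContactMatrix(BinTable("chr1", counts.shape[0] * 10, 10), counts)

    def test_sum_identity_and_doubling(self):
        a = self._mat([[1, 2], [2, 3]])
        z = self._mat(np.zeros((2, 2)))
        np.testing.assert_array_equal(sum_matrices(a, z).counts, a.counts)
        np.testing.assert_array_equal(sum_matrices(a, a).counts, 2 * a.counts)

    def test_sum_requires_matching_bins(self):
        a = self._mat([[1, 2], [2, 3]])
        b = ContactMatrix(BinTable("chr2", 20, 10), np.ones((2, 2)))
        with pytest.raises(MatrixError):
            sum_matrices(a, b)

    def test_depth_normalization_to_smaller_total(self):
        a = self._mat([[0, 10], [10, 0]])       # total 10
        b = self._mat([[0, 5], [5, 0]])         # total 5
        na, nb = normalize_to_common_depth(a, b)
        assert na.total == pytest.approx(5)
        assert nb.total == pytest.approx(5)
        # relative structure preserved
        a2 = self._mat([[2, 10], [10, 6]])
        na2, _ = normalize_to_common_depth(a2, b)
        ratio = a2.counts[0, 1] / a2.counts[0, 0]
        assert na2.counts[0, 1] / na2.counts[0, 0] == pytest.approx(ratio)

    def test_zero_mass_is_error(self):
        a = self._mat(np.zeros((2, 2)))
        b = self._mat([[0, 5], [5, 0]])
        with pytest.raises(MatrixError):
            normalize_to_common_depth(a, b)


class TestIceCorrect:
    def test_balanced_matrix_is_fixed_point(self):
        # constant symmetric matrix is already balanced
        m = ContactMatrix(BinTable("chr1", 40, 10), np.full((4, 4), 2.0))
        c = ice_correct(m, mad_filter=None)
        np.testing.assert_allclose(c.counts, m.counts, rtol=1e-6)
        np.testing.assert_allclose(c.weights, np.ones(4), rtol=1e-4)

    def test_3x3_example_matches_sinkhorn_oracle(self):
        a = np.array([[0, 2, 4], [2, 0, 2], [4, 2, 0]], dtype=float)
        m = ContactMatrix(BinTable("chr1", 30, 10), a)
        c = ice_correct(m, mad_filter=None, tol=1e-9, max_iter=5000)
        marg = c.counts.sum(axis=1)
        assert marg.std() / marg.mean() < 1e-6
        oracle = sinkhorn_oracle(a)
        ours = c.counts / c.counts.sum()
        theirs = oracle / oracle.sum()
        np.testing.assert_allclose(ours, theirs, atol=1e-5)

    def test_zero_coverage_bin_masked_remainder_balanced(self):
        a = np.array([[0, 2, 0], [2, 0, 0], [0, 0, 0]], dtype=float)
        m = ContactMatrix(BinTable("chr1", 30, 10), a)
        c = ice_correct(m, mad_filter=None)
        assert np.isnan(c.weights[2])
        assert np.all(c.counts[2, :] == 0)
        marg = c.counts[:2, :2].sum(axis=1)
        assert marg.std() / marg.mean() < 1e-5

    def test_all_masked_is_error(self):
        m = ContactMatrix(BinTable("chr1", 30, 10), np.zeros((3, 3)))
        with pytest.raises(MatrixError, match="too sparse"):
            ice_correct(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_marginal_cv_below_tolerance_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        a = random_symmetric(rng, 30)
        m = ContactMatrix(BinTable("chr1", 300, 10), a)
        c = ice_correct(m, mad_filter=None)
        marg = c.counts.sum(axis=1)
        assert marg.std() / marg.mean() < 1e-5

    def test_bias_identity(self):
        """Corrected counts times the outer bias product reproduce the input."""
        rng = np.random.default_rng(3)
        a = random_symmetric(rng, 20)
        m = ContactMatrix(BinTable("chr1", 200, 10), a)
        c = ice_correct(m, mad_filter=None)
        np.testing.assert_allclose(
            c.counts * np.outer(c.weights, c.weights), a, rtol=1e-4)


class TestExpectedByDistance:
    def test_uniform_matrix_constant_profile(self):
        m = ContactMatrix(BinTable("chr1", 50, 10), np.full((5, 5), 3.0))
        prof = expected_by_distance(m)
        np.testing.assert_allclose(prof.values, 3.0)

    def test_decaying_matrix_monotone_profile(self):
        n = 20
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = ContactMatrix(BinTable("chr1", n * 10, 10), 100.0 / (d + 1.0))
        prof = expected_by_distance(m)
        assert np.all(np.diff(prof.values) < 0)

    def test_5x5_integer_matrix_matches_hand_computation(self):
        a = np.array([
            [4, 3, 1, 0, 2],
            [3, 5, 2, 1, 0],
            [1, 2, 6, 3, 1],
            [0, 1, 3, 4, 2],
            [2, 0, 1, 2, 5],
        ], dtype=float)
        m = ContactMatrix(BinTable("chr1", 50, 10), a)
        prof = expected_by_distance(m)
        # brute-force diagonal means
        for d in range(5):
            expect = np.mean([a[i, i + d] for i in range(5 - d)])
            assert prof[d] == pytest.approx(expect)


class TestLog2Ratio:
    def _mat(self, counts):
        counts = np.asarray(counts, dtype=float)
        return ContactMatrix(BinTable("chr1", counts.shape[0] * 10, 10), counts)

    def test_identical_matrices_give_zero(self):
        a = self._mat([[1, 2], [2, 4]])
        np.testing.assert_allclose(log2_ratio_matrix(a, a), 0.0)

    def test_doubling_gives_ones_at_zero_pseudocount(self):
        a = self._mat([[1, 2], [2, 4]])
        b = self._mat([[2, 4], [4, 8]])
        np.testing.assert_allclose(log2_ratio_matrix(a, b, pseudocount=0), 1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = self._mat(random_symmetric(rng, 6))
        b = self._mat(random_symmetric(rng, 6))
        np.testing.assert_allclose(
            log2_ratio_matrix(a, b) + log2_ratio_matrix(b, a), 0.0, atol=1e-12)

    def test_common_rescale_invariance_at_zero_pseudocount(self):
        rng = np.random.default_rng(1)
        a = self._mat(random_symmetric(rng, 6))
        b = self._mat(random_symmetric(rng, 6))
        r1 = log2_ratio_matrix(a, b, pseudocount=0)
        r2 = log2_ratio_matrix(a.scaled(7.5), b.scaled(7.5), pseudocount=0)
        np.testing.assert_allclose(r1, r2, rtol=1e-10)


class TestTripletIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        mats = {}
        for chrom, n in (("chr1", 8), ("chr2", 5)):
            a = np.round(random_symmetric(rng, n) * 10)
            mats[chrom] = ContactMatrix(BinTable(chrom, n * 100, 100), a)
        p = tmp_path / "m.tsv"
        write_triplet_matrix(mats, p)
        back = read_triplet_matrix(p)
        for chrom in mats:
            assert back[chrom].bins == mats[chrom].bins
            np.testing.assert_allclose(back[chrom].counts, mats[chrom].counts)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(MatrixError, match="symmetric"):
            ContactMatrix(BinTable("chr1", 20, 10), np.array([[1.0, 2.0], [3.0, 4.0]]))
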