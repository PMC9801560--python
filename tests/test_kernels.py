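"""String and profile kernels against exhaustive enumeration, plus Gram properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_wd, naive_wds
from conftest import random_dna
from pbdtss.kernels import (
    KernelConfig,
    KernelGram,
    clip_negative_eigenvalues,
    hybrid_gram,
    min_max_eigenvalues,
    normalize_gram,
    rbf_gamma_heuristic,
    rbf_gram,
    rbf_kernel,
    wd_gram,
    wd_kernel,
    wd_self_similarity,
    wd_weights,
    wds_kernel,
)

dna = st.text(alphabet="ACGT", min_size=6, max_size=20)


class TestWDKernel:
    def test_hand_examples(self):
        assert wd_kernel("AAAA", "CCCC", 2) == 0.0
        assert wd_kernel("ACGT", "ACTT", 1) == pytest.approx(3.0)
        assert wd_kernel("ACGTA", "ACGTA", 2) == pytest.approx(14.0 / 3.0)

    @pytest.mark.parametrize("d", [1, 2, 5, 12, 24, 30])
    def test_order_weights_sum_to_one(self, d):
        assert wd_weights(d).sum() == pytest.approx(1.0, rel=1e-12)

    def test_self_similarity_closed_form(self, rng):
        for _ in range(10):
            s = random_dna(rng, 15)
            assert wd_kernel(s, s, 4) == pytest.approx(wd_self_similarity(15, 4), rel=1e-12)

    @given(s1=dna, s2=dna, d=st.integers(1, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, s1, s2, d):
        L = min(len(s1), len(s2))
        s1, s2 = s1[:L], s2[:L]
        if L < d:
            return
        assert wd_kernel(s1, s2, d) == pytest.approx(naive_wd(s1, s2, d), rel=1e-12)

    def test_gram_agrees_with_pairwise_kernel(self, rng):
        seqs = random_dna(rng, 21, n=8)
        grams = wd_gram(seqs, [3, 6])
        for d in (3, 6):
            for i in range(8):
                for j in range(8):
                    assert grams[d][i, j] == pytest.approx(
                        wd_kernel(seqs[i], seqs[j], d), rel=1e-12)

    def test_cross_gram_orientation(self, rng):
        a = random_dna(rng, 15, n=4)
        b = random_dna(rng, 15, n=6)
        cross = wd_gram(a, 3, other=b)
        assert cross.shape == (4, 6)
        assert cross[2, 5] == pytest.approx(wd_kernel(a[2], b[5], 3), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            wd_kernel("ACGT", "ACG", 2)
        with pytest.raises(ValueError, match="shorter"):
            wd_kernel("ACG", "ACG", 5)


class TestWDSKernel:
    def test_reduces_to_wd_at_zero_shift(self, rng):
        for _ in range(8):
            s1, s2 = random_dna(rng, 12), random_dna(rng, 12)
            assert wds_kernel(s1, s2, 4, 0) == pytest.approx(
                wd_kernel(s1, s2, 4), rel=1e-12)

    def test_shifted_matches_found(self):
        # "CACG" is "ACG" shifted by one: only shifted 1-mers can match
        assert wd_kernel("ACGT", "CACG", 1) == 0.0
        assert wds_kernel("ACGT", "CACG", 1, 1) == pytest.approx(
            naive_wds("ACGT", "CACG", 1, 1))

    @given(s1=dna, s2=dna, d=st.integers(1, 4), shift=st.integers(0, 3))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, s1, s2, d, shift):
        L = min(len(s1), len(s2))
        s1, s2 = s1[:L], s2[:L]
        if L < d:
            return
        got = wds_kernel(s1, s2, d, shift)
        assert got == pytest.approx(naive_wds(s1, s2, d, shift), rel=1e-12)
        assert got == pytest.approx(wds_kernel(s2, s1, d, shift), rel=1e-12)


class TestRBFKernel:
    def test_identity_and_closed_form(self):
        x = np.array([0.2, 0.7, 0.1])
        assert rbf_kernel(x, x, 3.0) == 1.0
        assert rbf_kernel([0.0, 0.0], [1.0, 0.0], 1.0) == pytest.approx(math.exp(-1.0))

    def test_symmetric_and_bounded(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=5), rng.normal(size=5)
            k = rbf_kernel(a, b, 0.7)
            assert 0.0 < k <= 1.0
            assert k == pytest.approx(rbf_kernel(b, a, 0.7), rel=1e-14)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rbf_kernel([1.0, 2.0], [1.0], 1.0)

    def test_gamma_heuristic_matches_pooled_variance(self, rng):
        X = rng.random((30, 200))
        assert rbf_gamma_heuristic(X) == pytest.approx(1.0 / (200 * X.var()), rel=1e-12)


class TestGramProperties:
    def test_wd_gram_psd_on_random_windows(self, rng):
        seqs = random_dna(rng, 201, n=30)
        K = wd_gram(seqs, 12)
        lo, hi = min_max_eigenvalues(K)
        assert lo >= -1e-8 * hi

    def test_rbf_gram_psd(self, rng):
        K = rbf_gram(rng.random((40, 20)), gamma=2.0)
        lo, hi = min_max_eigenvalues(K)
        assert lo >= -1e-8 * hi

    def test_normalization_unit_diagonal_idempotent_bounded(self, rng):
        seqs = random_dna(rng, 30, n=15)
        K = normalize_gram(wd_gram(seqs, 6))
        np.testing.assert_allclose(np.diag(K), 1.0, atol=1e-12)
        np.testing.assert_allclose(normalize_gram(K), K, atol=1e-12)
        assert np.all(np.abs(K) <= 1.0 + 1e-12)

    def test_cauchy_schwarz_bound(self, rng):
        seqs = random_dna(rng, 25, n=12)
        K = wd_gram(seqs, 8)
        diag = np.diag(K)
        assert np.all(K**2 <= np.outer(diag, diag) * (1 + 1e-12))

    def test_negative_eigenvalue_clipping(self):
        K = np.array([[1.0, 0.0], [0.0, -0.5]])
        repaired = clip_negative_eigenvalues(K)
        lo, hi = min_max_eigenvalues(repaired)
        assert lo >= -1e-12
        sane = np.array([[2.0, 0.3], [0.3, 1.0]])
        np.testing.assert_array_equal(clip_negative_eigenvalues(sane), sane)


class TestHybridAndContainers:
    def _grams(self, rng, n=10):
        seqs = random_dna(rng, 21, n=n)
        X = rng.random((n, 8))
        ids = tuple(f"w{i}" for i in range(n))
        gs = KernelGram(ids, wd_gram(seqs, 6), KernelConfig(kind="WD", d=6))
        gp = KernelGram(ids, rbf_gram(X, gamma=1.0), KernelConfig(kind="RBF"))
        return gs, gp

    def test_equal_weight_average_of_normalized_components(self, rng):
        gs, gp = self._grams(rng)
        h = hybrid_gram(gs, gp)
        np.testing.assert_allclose(np.diag(h.values), 1.0, atol=1e-12)
        want = 0.5 * normalize_gram(gs.values) + 0.5 * normalize_gram(gp.values)
        np.testing.assert_allclose(h.values, want, atol=1e-12)
        lo, hi = min_max_eigenvalues(h.values)
        assert lo >= -1e-8 * hi

    def test_identical_inputs_fixed_point(self, rng):
        gs, _ = self._grams(rng)
        h = hybrid_gram(gs, gs, weights=(0.5, 0.5))
        np.testing.assert_allclose(h.values, normalize_gram(gs.values), atol=1e-12)

    def test_component_extremes_average_to_half(self):
        ids = ("a", "b")
        one = KernelGram(ids, np.array([[1.0, 1.0], [1.0, 1.0]]))
        zero = KernelGram(ids, np.eye(2))
        h = hybrid_gram(one, zero)
        assert h.values[0, 1] == pytest.approx(0.5)

    def test_instance_order_mismatch_rejected(self, rng):
        gs, gp = self._grams(rng)
        shuffled = KernelGram(gp.instance_ids[::-1], gp.values, gp.config)
        with pytest.raises(ValueError, match="orderings"):
            hybrid_gram(gs, shuffled)

    def test_gram_tsv_round_trip(self, rng, tmp_path):
        gs, _ = self._grams(rng, n=5)
        path = tmp_path / "gram.tsv"
        gs.save_tsv(path)
        back = KernelGram.load_tsv(path)
        assert back.instance_ids == gs.instance_ids
        assert back.config == gs.config
        np.testing.assert_array_equal(back.values, gs.values)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            KernelGram(("a", "b"), np.array([[1.0, 0.2], [0.3, 1.0]]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            KernelConfig(kind="linear")
        with pytest.raises(ValueError):
            KernelConfig(gamma=0.0)
        with pytest.raises(ValueError):
            KernelConfig(weights=(0.7, 0.7))
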