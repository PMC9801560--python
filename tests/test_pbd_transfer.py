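"""Transfer-integral statistics against brute-force dense quadrature.

For 2-3 base-pair chains every constrained configuration integral can be
evaluated as a dense 2-D/3-D quadrature sum over the same grid; the iterative
transfer scheme must agree to high relative precision.  Longer chains are
covered by internal-consistency and physical-ordering properties.
"""

import math

import numpy as np
import pytest

from _oracles import (
    dense_dsdna_denominator,
    dense_exact_bubble,
    dense_opening,
    dense_weight,
)
from pbdtss.pbd import (
    CLOSED,
    FREE,
    OPEN,
    NumericalRegimeError,
    QuadratureGrid,
    SequenceAlphabetError,
    TransferIntegrator,
    closed_probability,
    profile_for_window,
    transfer_partition,
)

T310 = 310.0
RTOL = 1e-6


@pytest.fixture(scope="module")
def engine(params, small_grid):
    return TransferIntegrator(params, small_grid, T310)


class TestPartitionFunction:
    @pytest.mark.parametrize("seq", ["AA", "AT", "GC", "AG"])
    def test_unconstrained_matches_dense(self, engine, params, small_grid, seq):
        got = math.exp(engine.log_partition(seq))
        want = dense_weight(seq, T310, small_grid, params)
        assert got == pytest.approx(want, rel=RTOL)

    @pytest.mark.parametrize("states", [
        (CLOSED, FREE), (OPEN, FREE), (CLOSED, CLOSED), (OPEN, OPEN), (CLOSED, OPEN),
    ])
    def test_constrained_two_mer_matches_dense(self, engine, params, small_grid, states):
        mask = {CLOSED: small_grid.closed_mask, OPEN: small_grid.open_mask, FREE: None}
        got = math.exp(engine.log_partition("AT", list(states)))
        want = dense_weight("AT", T310, small_grid, params,
                            masks=[mask[s] for s in states])
        assert got == pytest.approx(want, rel=RTOL)

    def test_middle_closed_three_mer_matches_dense(self, engine, params, small_grid):
        got = math.exp(engine.log_partition("AGT", {2: CLOSED}))
        want = dense_weight("AGT", T310, small_grid, params,
                            masks=[None, small_grid.closed_mask, None])
        assert got == pytest.approx(want, rel=RTOL)

    def test_subevent_weights_bounded_by_total(self, engine):
        # Z(all closed) + Z(all open) <= Z_I: sub-events of the full ensemble
        for seq in ("AA", "GC", "AT"):
            z_i = engine.log_partition(seq)
            z_cl = engine.log_partition(seq, [CLOSED, CLOSED])
            z_op = engine.log_partition(seq, [OPEN, OPEN])
            assert np.logaddexp(z_cl, z_op) <= z_i + 1e-12

    def test_invalid_inputs_rejected(self, engine):
        with pytest.raises(ValueError, match="at least 2"):
            engine.log_partition("A")
        with pytest.raises(ValueError, match="outside"):
            engine.log_partition("ACG", {4: CLOSED})
        with pytest.raises(ValueError, match="state"):
            engine.log_partition("ACG", {1: "ajar"})
        with pytest.raises(SequenceAlphabetError):
            engine.log_partition("ACN")

    def test_module_level_wrapper(self, params, small_grid, engine):
        assert transfer_partition("AT", T310, small_grid, params) == pytest.approx(
            engine.log_partition("AT"), rel=1e-12)


class TestClosedProbability:
    def test_two_mer_matches_dense_ratio(self, engine, params, small_grid):
        probs = engine.closed_probabilities("AT")
        denom = dense_dsdna_denominator("AT", T310, small_grid, params)
        for j in range(2):
            masks = [None, None]
            masks[j] = small_grid.closed_mask
            want = dense_weight("AT", T310, small_grid, params, masks=masks) / denom
            assert probs[j] == pytest.approx(want, rel=RTOL)

    def test_closed_plus_open_is_one(self, engine):
        seq = "ACGGTA"
        closed = engine.closed_probabilities(seq)
        opening = engine.opening_profile(seq).values
        np.testing.assert_allclose(closed + opening, 1.0, atol=1e-10)

    def test_deep_well_dominates_at_low_temperature(self, params, small_grid):
        cold = TransferIntegrator(params, small_grid, 150.0)
        # chain-end pairs breathe slightly more; all stay essentially closed
        assert np.all(cold.closed_probabilities("GCAT") > 0.99)

    def test_position_wrapper_and_bounds(self, params, small_grid):
        p = closed_probability("AT", T310, small_grid, params, j=1)
        assert 0.0 <= p <= 1.0
        with pytest.raises(ValueError, match="outside"):
            closed_probability("AT", T310, small_grid, params, j=3)


class TestBubbleMatrix:
    def test_three_mer_matches_dense(self, engine, params, small_grid):
        seq = "AGT"
        bub = engine.bubble_matrix(seq)
        for m in (1, 2, 3):
            for start in range(3 - m + 1):
                offset = (m - 1) // 2 if m % 2 else m // 2 - 1
                k = start + offset
                want = dense_exact_bubble(seq, T310, small_grid, params, start, m)
                if want == 0.0:
                    assert bub.values[k, m - 1] == 0.0
                else:
                    assert bub.values[k, m - 1] == pytest.approx(want, rel=RTOL)

    def test_full_chain_bubble_excluded(self, engine):
        # the exact-size-N bubble would be the all-open state, excluded by mu
        for seq in ("AT", "AGT", "ACGTGA"):
            bub = engine.bubble_matrix(seq)
            assert np.all(bub.values[:, len(seq) - 1] == 0.0)

    def test_homopolymer_reversal_symmetry(self, engine):
        n = 8
        bub = engine.bubble_matrix("A" * n).values
        for m in range(1, n + 1):
            col = bub[:, m - 1]
            if m % 2 == 1:
                np.testing.assert_allclose(col, col[::-1], rtol=1e-8)
            else:
                # even-size centres sit left of the midpoint: k -> N-2-k (0-based)
                starts = np.arange(n - m + 1)
                ks = starts + m // 2 - 1
                np.testing.assert_allclose(col[ks], col[(n - 2) - ks], rtol=1e-8)

    def test_m_max_out_of_range_rejected(self, engine):
        with pytest.raises(ValueError, match="m_max"):
            engine.bubble_matrix("ACG", m_max=4)


class TestParticipation:
    def test_three_mer_opening_matches_dense(self, engine, params, small_grid):
        seq = "AGT"
        bub = engine.bubble_matrix(seq)
        part1 = engine.participation_profile(bub, 1)
        want = dense_opening(seq, T310, small_grid, params, j=1)
        assert part1.values[1] == pytest.approx(want, rel=RTOL)

    def test_nonincreasing_in_bubble_size(self, engine):
        bub = engine.bubble_matrix("ACGTTAAG")
        prev = engine.participation_profile(bub, 1).values
        for m in range(2, 9):
            cur = engine.participation_profile(bub, m).values
            assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_size_one_participation_contains_exact_bubble(self, engine):
        # P_part(k,1) = <theta_k>_mu >= P_bub(k,1): opening includes larger bubbles
        bub = engine.bubble_matrix("GACGTA")
        part1 = engine.participation_profile(bub, 1).values
        assert np.all(part1 >= bub.values[:, 0] - 1e-12)
        assert np.any(part1 > bub.values[:, 0])

    def test_participation_complements_closed(self, engine):
        seq = "TTAGCC"
        bub = engine.bubble_matrix(seq)
        part1 = engine.participation_profile(bub, 1).values
        closed = engine.closed_probabilities(seq)
        np.testing.assert_allclose(part1 + closed, 1.0, atol=1e-9)

    def test_requires_full_bubble_matrix(self, engine):
        bub = engine.bubble_matrix("ACGTAC", m_max=3)
        with pytest.raises(ValueError, match="m_max = N"):
            engine.participation_profile(bub, 1)
        full = engine.bubble_matrix("ACGTAC")
        with pytest.raises(ValueError, match="m must be"):
            engine.participation_profile(full, 7)


class TestNumericalBehaviour:
    def test_grid_refinement_stability(self, params):
        # doubling the default point count moves no probability by 1e-4
        seq = "ATGCGTATCCGA"
        vals = {}
        for n in (600, 1200):
            eng = TransferIntegrator(params, QuadratureGrid(n_points=n), 345.0)
            bub = eng.bubble_matrix(seq)
            vals[n] = np.concatenate([
                eng.opening_profile(seq).values,
                eng.participation_profile(bub, 4).values,
                bub.values.ravel(),
            ])
        assert np.abs(vals[600] - vals[1200]).max() < 1e-4

    def test_thermal_monotonicity_short_chain(self, params, small_grid):
        seq = "ATGCGTATCCGA"
        profiles = [TransferIntegrator(params, small_grid, t).opening_profile(seq).values
                    for t in (310.0, 335.0, 360.0)]
        assert np.all(profiles[1] >= profiles[0] - 1e-12)
        assert np.all(profiles[2] >= profiles[1] - 1e-12)

    def test_scaling_invariance_of_probabilities(self, params, small_grid):
        # probabilities are weight ratios: identical from one engine or another
        a = TransferIntegrator(params, small_grid, T310).closed_probabilities("ACGT")
        b = TransferIntegrator(params, small_grid, T310).closed_probabilities("ACGT")
        np.testing.assert_array_equal(a, b)


class TestWindowProfiles:
    def test_trimmed_window_profile_shape(self, params):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 300))
        prof = profile_for_window(seq, 345.0, QuadratureGrid(n_points=64),
                                  params, m=8, sequence_id="w")
        assert prof.values.shape == (200,)
        assert prof.trimmed and prof.m == 8
        assert np.all((prof.values >= 0) & (prof.values <= 1))

    def test_wrong_length_or_alphabet_rejected(self, params, small_grid):
        with pytest.raises(ValueError, match="300"):
            profile_for_window("ACGT" * 50, 345.0, small_grid, params)
        with pytest.raises(SequenceAlphabetError):
            profile_for_window("N" * 300, 345.0, small_grid, params)
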