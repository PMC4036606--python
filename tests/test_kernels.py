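"""Update kernels: brute-force conditional-phenotype oracle, cross-kernel
agreement, residual bookkeeping, and operation counting."""

import numpy as np
import pytest

from rhsgibbs import kernels
from rhsgibbs.coding import assign_blocks, encode_group_codes, make_locus_coding
from conftest import random_raw


def _instance(m=10, n=5, seed=0):
    """Random model state with consistent residuals."""
    rng = np.random.default_rng(seed)
    raw = random_raw(m, n, seed=seed + 100)
    coding = make_locus_coding(raw, "centered_scaled")
    coded = coding.code_matrix(raw)
    alpha = rng.standard_normal(coding.n) * 0.3
    mu = rng.standard_normal()
    y = rng.standard_normal(m) * 2.0
    e = y - mu - coded @ alpha
    return raw, coding, coded, alpha, mu, y, e


class TestConditionalMeans:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_original_matches_conditional_phenotype_oracle(self, seed):
        """Residual-updating mean equals the definition via explicitly
        corrected phenotypes: mean = x'y* / (x'x + lambda)."""
        raw, coding, coded, alpha, mu, y, e = _instance(seed=seed)
        lam = 1.7
        for j in range(coding.n):
            ystar = y - mu - coded @ alpha + coded[:, j] * alpha[j]
            oracle = float(coded[:, j] @ ystar) / (coding.xtx[j] + lam)
            _, _, mean = kernels.conditional_mean_original(
                e, coded[:, j], coding.xtx[j], alpha[j], lam
            )
            assert mean == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 3, 4])
    def test_improved_equals_original(self, seed):
        raw, coding, coded, alpha, mu, y, e = _instance(m=23, seed=seed)
        codes = raw.matrix[:, coding.kept].astype(np.int64)
        lam = 0.9
        for j in range(coding.n):
            _, _, mo = kernels.conditional_mean_original(
                e, coded[:, j], coding.xtx[j], alpha[j], lam
            )
            _, _, mi = kernels.conditional_mean_improved(
                e, codes[:, j], tuple(coding.gamma[j]), coding.xtx[j], alpha[j], lam
            )
            assert mi == pytest.approx(mo, rel=1e-12)

    def test_zero_numerator_when_orthogonal(self):
        raw, coding, coded, alpha, mu, y, e = _instance()
        x = coded[:, 0]
        e_orth = np.random.default_rng(1).standard_normal(len(x))
        e_orth -= x * (x @ e_orth) / (x @ x)
        _, _, mean = kernels.conditional_mean_original(e_orth, x, coding.xtx[0], 0.0, 2.0)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_large_lambda_shrinks_to_zero(self):
        raw, coding, coded, alpha, mu, y, e = _instance()
        means = [
            abs(
                kernels.conditional_mean_original(
                    e, coded[:, 0], coding.xtx[0], alpha[0], lam
                )[2]
            )
            for lam in (1.0, 1e3, 1e6, 1e9)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))
        assert means[-1] < 1e-8

    def test_centered_coding_kills_constant_residuals(self):
        raw = random_raw(30, 1, seed=9)
        coding = make_locus_coding(raw, "centered")
        codes = raw.matrix[:, coding.kept].astype(np.int64)[:, 0]
        e = np.full(raw.m, 3.7)
        lam = 2.0
        a_old = 0.8
        num, den, mean = kernels.conditional_mean_improved(
            e, codes, tuple(coding.gamma[0]), coding.xtx[0], a_old, lam
        )
        assert mean == pytest.approx(coding.xtx[0] * a_old / (coding.xtx[0] + lam), rel=1e-10)

    def test_nonpositive_denominator_errors(self):
        raw, coding, coded, alpha, mu, y, e = _instance()
        with pytest.raises(ValueError, match="denominator"):
            kernels.conditional_mean_original(
                e, coded[:, 0], coding.xtx[0], 0.0, -2 * coding.xtx[0]
            )


class TestResidualUpdate:
    def test_no_change_when_effect_unchanged(self):
        raw, coding, coded, alpha, mu, y, e = _instance()
        before = e.copy()
        codes = raw.matrix[:, coding.kept].astype(np.int64)
        kernels.residual_update(e, codes[:, 0], tuple(coding.gamma[0]), 0.4, 0.4)
        assert np.array_equal(e, before)

    def test_raw_coding_genotype2_delta(self):
        # single individual with genotype 2 under raw coding, delta = 0.5
        e = np.array([1.0])
        kernels.residual_update(e, np.array([2]), (0.0, 1.0, 2.0), 0.0, 0.5)
        assert e[0] == pytest.approx(0.0)

    def test_matches_scratch_recompute(self):
        raw, coding, coded, alpha, mu, y, e = _instance(m=17, n=4, seed=6)
        codes = raw.matrix[:, coding.kept].astype(np.int64)
        new_alpha = alpha.copy()
        rng = np.random.default_rng(2)
        for j in range(coding.n):
            a_new = rng.standard_normal()
            kernels.residual_update(e, codes[:, j], tuple(coding.gamma[j]), new_alpha[j], a_new)
            new_alpha[j] = a_new
        scratch = kernels.recompute_residuals(y, mu, coded, new_alpha)
        np.testing.assert_allclose(e, scratch, atol=1e-12)


def _block_setup(m=10, s=2, seed=0):
    raw, coding, coded, alpha, mu, y, e = _instance(m=m, n=s, seed=seed)
    index = encode_group_codes(raw.subset_loci(coding.kept), assign_blocks(coding.n, s))
    return raw, coding, coded, alpha, e, index


class TestBlockKernels:
    def test_initialization_conserves_residual_sum(self):
        raw, coding, coded, alpha, e, index = _block_setup(m=30, s=3, seed=1)
        state = kernels.block_initialize(e, index, 0)
        assert state.F.sum() == pytest.approx(e.sum(), rel=1e-10)
        assert np.all(state.dE == 0.0)

    def test_nine_sums_for_two_snp_block(self):
        raw, coding, coded, alpha, e, index = _block_setup(m=50, s=2, seed=2)
        state = kernels.block_initialize(e, index, 0)
        assert len(state.F) == 9

    def test_single_group_block_concentrates_sum(self):
        from rhsgibbs.coding import RawGenotypes

        raw = RawGenotypes(np.ones((6, 2), dtype=int))
        index = encode_group_codes(raw, assign_blocks(2, 2))
        e = np.arange(6.0)
        state = kernels.block_initialize(e, index, 0)
        # group code for (1,1) is 1 + 1 + 3 = 5 -> zero-based 4
        assert state.F[4] == pytest.approx(e.sum())
        assert np.count_nonzero(state.F) == 1

    def test_first_locus_equals_improved(self):
        raw, coding, coded, alpha, e, index = _block_setup(m=25, s=3, seed=3)
        codes = raw.matrix[:, coding.kept].astype(np.int64)
        state = kernels.block_initialize(e, index, 0)
        j = index.blocks[0][0]
        num_rhs = kernels.block_locus_numerator(
            state, index, 0, tuple(coding.gamma[j]), coding.xtx[j], alpha[j]
        )
        num_impr = kernels.numerator_improved(
            e, codes[:, j], tuple(coding.gamma[j]), coding.xtx[j], alpha[j]
        )
        assert num_rhs == pytest.approx(num_impr, rel=1e-12)

    @pytest.mark.parametrize("s,seed", [(2, 0), (2, 5), (3, 1), (4, 2)])
    def test_block_sweep_equals_improved_trajectory(self, s, seed):
        """A full RHS-block sweep produces the same conditional means and the
        same final residuals as sequential improved residual updating."""
        raw, coding, coded, alpha, e, index = _block_setup(m=20, s=s, seed=seed)
        codes = raw.matrix[:, coding.kept].astype(np.int64)
        lam = 1.3
        rng = np.random.default_rng(seed + 50)
        draws = rng.standard_normal(coding.n) * 0.2

        e_impr = e.copy()
        alpha_impr = alpha.copy()
        means_impr = []
        for t, j in enumerate(index.blocks[0]):
            _, _, mean = kernels.conditional_mean_improved(
                e_impr, codes[:, j], tuple(coding.gamma[j]), coding.xtx[j], alpha_impr[j], lam
            )
            means_impr.append(mean)
            a_new = mean + draws[t]
            kernels.residual_update(
                e_impr, codes[:, j], tuple(coding.gamma[j]), alpha_impr[j], a_new
            )
            alpha_impr[j] = a_new

        e_rhs = e.copy()
        alpha_rhs = alpha.copy()
        state = kernels.block_initialize(e_rhs, index, 0)
        means_rhs = []
        for t, j in enumerate(index.blocks[0]):
            _, _, mean = kernels.block_locus_update(
                state, index, t, tuple(coding.gamma[j]), coding.xtx[j], alpha_rhs[j], lam
            )
            means_rhs.append(mean)
            a_new = mean + draws[t]
            kernels.update_block_state(
                state, index, t, tuple(coding.gamma[j]), alpha_rhs[j], a_new
            )
            alpha_rhs[j] = a_new
        kernels.block_finalize(state, index, e_rhs)

        np.testing.assert_allclose(means_rhs, means_impr, rtol=1e-10)
        np.testing.assert_allclose(e_rhs, e_impr, atol=1e-12)

    def test_second_locus_equals_original_after_explicit_update(self):
        raw, coding, coded, alpha, e, index = _block_setup(m=10, s=2, seed=4)
        codes = raw.matrix[:, coding.kept].astype(np.int64)
        lam = 0.8
        j0, j1 = index.blocks[0]
        state = kernels.block_initialize(e.copy(), index, 0)
        _, _, mean0 = kernels.block_locus_update(
            state, index, 0, tuple(coding.gamma[j0]), coding.xtx[j0], alpha[j0], lam
        )
        a0_new = mean0 + 0.1
        kernels.update_block_state(state, index, 0, tuple(coding.gamma[j0]), alpha[j0], a0_new)
        _, _, mean1 = kernels.block_locus_update(
            state, index, 1, tuple(coding.gamma[j1]), coding.xtx[j1], alpha[j1], lam
        )
        # oracle: explicitly apply locus-0's residual update, then original kernel
        e_expl = e.copy()
        kernels.residual_update(e_expl, codes[:, j0], tuple(coding.gamma[j0]), alpha[j0], a0_new)
        _, _, oracle = kernels.conditional_mean_original(
            e_expl, coded[:, j1], coding.xtx[j1], alpha[j1], lam
        )
        assert mean1 == pytest.approx(oracle, rel=1e-10)

    def test_delta_e_matrix_for_two_loci(self):
        """After both loci of an s=2 block, the per-group changes equal the
        rank-one-plus-rank-one change matrix evaluated directly."""
        raw, coding, coded, alpha, e, index = _block_setup(m=15, s=2, seed=8)
        j0, j1 = index.blocks[0]
        g0, g1 = coding.gamma[j0], coding.gamma[j1]
        da0, da1 = 0.37, -0.21
        state = kernels.block_initialize(e, index, 0)
        kernels.update_block_state(state, index, 0, tuple(g0), alpha[j0], alpha[j0] + da0)
        kernels.update_block_state(state, index, 1, tuple(g1), alpha[j1], alpha[j1] + da1)
        delta = np.add.outer(g1 * da1, g0 * da0)  # rows: genotype at locus 1
        geno = index.geno_of_group[0]
        expected = delta[geno[:, 1], geno[:, 0]]
        np.testing.assert_allclose(state.dE, expected, atol=1e-14)

    def test_updates_commute_additively(self):
        raw, coding, coded, alpha, e, index = _block_setup(m=12, s=2, seed=9)
        j0 = index.blocks[0][0]
        g = tuple(coding.gamma[j0])
        s1 = kernels.block_initialize(e.copy(), index, 0)
        kernels.update_block_state(s1, index, 0, g, 0.0, 0.2)
        kernels.update_block_state(s1, index, 0, g, 0.2, 0.5)
        s2 = kernels.block_initialize(e.copy(), index, 0)
        kernels.update_block_state(s2, index, 0, g, 0.0, 0.5)
        np.testing.assert_allclose(s1.dE, s2.dE, atol=1e-14)

    def test_finalize_bookkeeping_identity(self):
        raw, coding, coded, alpha, e, index = _block_setup(m=20, s=2, seed=10)
        j0 = index.blocks[0][0]
        state = kernels.block_initialize(e, index, 0)
        kernels.update_block_state(state, index, 0, tuple(coding.gamma[j0]), 0.0, 0.3)
        total_before = e.sum()
        expected_drop = float(index.group_counts[0] @ state.dE)
        kernels.block_finalize(state, index, e)
        assert e.sum() == pytest.approx(total_before - expected_drop, rel=1e-10)


class TestOpCounters:
    @pytest.mark.parametrize("m", [10, 100, 1000])
    def test_improved_numerator_uses_exactly_four_multiplications(self, m):
        raw, coding, coded, alpha, mu, y, e = _instance(m=m, n=2, seed=1)
        codes = raw.matrix[:, coding.kept].astype(np.int64)
        c = kernels.OpCounters()
        kernels.numerator_improved(e, codes[:, 0], tuple(coding.gamma[0]), coding.xtx[0], alpha[0], c)
        assert c.multiplications == 4

    def test_original_numerator_uses_m_plus_one_multiplications(self):
        m = 37
        raw, coding, coded, alpha, mu, y, e = _instance(m=m, n=2, seed=1)
        c = kernels.OpCounters()
        kernels.numerator_original(e, coded[:, 0], coding.xtx[0], alpha[0], c)
        assert c.multiplications == m + 1

    @pytest.mark.parametrize("s", [2, 3])
    def test_inner_locus_ops_independent_of_m(self, s):
        counts = {}
        for m in (20, 40):
            raw, coding, coded, alpha, e, index = _block_setup(m=m, s=s, seed=11)
            state = kernels.block_initialize(e, index, 0)
            j0 = index.blocks[0][0]
            kernels.update_block_state(state, index, 0, tuple(coding.gamma[j0]), 0.0, 0.1)
            c = kernels.OpCounters()
            j1 = index.blocks[0][1]
            kernels.block_locus_update(
                state, index, 1, tuple(coding.gamma[j1]), coding.xtx[j1], alpha[j1], 1.0, c
            )
            kernels.update_block_state(
                state, index, 1, tuple(coding.gamma[j1]), alpha[j1], 0.2, c
            )
            counts[m] = c.as_dict()
        assert counts[20] == counts[40]

    def test_counters_reset(self):
        c = kernels.OpCounters(multiplications=5, additions_subtractions=2, divisions=1)
        c.reset()
        assert c.as_dict() == {
            "multiplications": 0,
            "additions_subtractions": 0,
            "divisions": 0,
        }
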