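"""Ghost sampling, the kappa/tau filter, and the marginal comparator."""

import numpy as np
import pandas as pd
import pytest

from knockblock.ghost_inference import (
    align_zscores,
    bonferroni_marginal,
    count_independent,
    group_stats,
    knockoff_filter,
    marginal_z,
    read_zscores,
    sample_knockoff_z,
)
from knockblock.grouping import build_groups
from knockblock.knockoff_optim import assemble_D, solve_maxent

from conftest import random_correlation


class TestMarginalZ:
    def test_self_regression_gives_sqrt_n(self, rng):
        n = 400
        X = rng.standard_normal((n, 3))
        X = (X - X.mean(0)) / X.std(0)
        z = marginal_z(X, X[:, 1])
        assert z[1] == pytest.approx(np.sqrt(n), rel=1e-12)

    def test_joint_sample_permutation_invariance(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(
            marginal_z(X, y), marginal_z(X[perm], y[perm]), atol=1e-12
        )

    def test_null_scores_are_standard_normal(self, rng):
        """Independent y: empirical variance of z across 500 null columns."""
        n, p = 10_000, 500
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        z = marginal_z(X, y)
        assert 0.9 < z.var() < 1.1
        with pytest.raises(ValueError, match="rows"):
            marginal_z(X, y[:-1])


class TestSampleKnockoffZ:
    def test_zero_D_returns_z_exactly(self, rng):
        sigma = random_correlation(6, rng)
        z = rng.standard_normal(6)
        z_knock = sample_knockoff_z(z, sigma, np.zeros((6, 6)), m=5, seed=1)
        for k in range(5):
            np.testing.assert_array_equal(z_knock[:, k], z)

    def test_seed_reproducibility(self, rng):
        sigma = random_correlation(5, rng)
        D = 0.5 * np.eye(5)
        z = rng.standard_normal(5)
        a = sample_knockoff_z(z, sigma, D, m=3, seed=42)
        b = sample_knockoff_z(z, sigma, D, m=3, seed=42)
        np.testing.assert_array_equal(a, b)
        c = sample_knockoff_z(z, sigma, D, m=3, seed=43)
        assert not np.array_equal(a, c)

    def test_identity_case_decorrelates_fully(self):
        """Sigma = I, D = I, m = 1: Cov(z, z~) = 0, Var(z~) = I."""
        p, B = 4, 100_000
        rng = np.random.default_rng(7)
        z = rng.standard_normal((B, p))
        z_knock = sample_knockoff_z(z, np.eye(p), np.eye(p), m=1, seed=8)[:, :, 0]
        cross = z.T @ z_knock / B
        assert np.abs(cross).max() < 4.0 / np.sqrt(B) * 3
        var = z_knock.var(axis=0)
        np.testing.assert_allclose(var, 1.0, atol=0.05)

    def test_exchangeability_moments(self, rng):
        """Cov(z, z~k) = Sigma - D, Cov(z~j, z~k) = Sigma - D, Var(z~k) = Sigma."""
        p, m, B = 8, 3, 60_000
        sigma = random_correlation(p, rng, jitter=0.6)
        gs = build_groups(sigma)
        S, _ = solve_maxent(sigma[np.ix_(gs.keys, gs.keys)], gs.key_groups, m=m)
        D = assemble_D(sigma, gs.keys, S, m=m)
        L = np.linalg.cholesky(sigma)
        z = rng.standard_normal((B, p)) @ L.T
        zk = sample_knockoff_z(z, sigma, D, m=m, seed=3)
        target = sigma - D
        se = 3.5 / np.sqrt(B)  # rough scale for correlation-sized moments
        cross = np.einsum("bi,bjk->ijk", z, zk) / B
        for k in range(m):
            assert np.abs(cross[:, :, k] - target).max() < 6 * se
        pair = np.einsum("bik,bjl->ijkl", zk, zk) / B
        for j in range(m):
            for k in range(m):
                expected = sigma if j == k else target
                assert np.abs(pair[:, :, j, k] - expected).max() < 6 * se

    def test_corrupted_bundle_detected(self, rng):
        sigma = random_correlation(4, rng)
        D_bad = 3.0 * np.eye(4)  # violates ((m+1)/m) Sigma - D >= 0 badly
        with pytest.raises(ValueError, match="infeasible|corrupt"):
            sample_knockoff_z(np.zeros(4), sigma, D_bad, m=5, seed=0)


class TestGroupStats:
    def test_singleton_groups_single_knockoff(self, rng):
        z = rng.standard_normal(4)
        zk = rng.standard_normal((4, 1))
        T = group_stats(z, zk, np.arange(1, 5))
        np.testing.assert_allclose(T[:, 0], z**2)
        np.testing.assert_allclose(T[:, 1], zk[:, 0] ** 2)

    def test_zero_scores_and_homogeneity(self, rng):
        z = rng.standard_normal(6)
        zk = rng.standard_normal((6, 5))
        membership = np.array([1, 1, 2, 2, 3, 3])
        assert group_stats(np.zeros(6), np.zeros((6, 5)), membership).sum() == 0
        T1 = group_stats(z, zk, membership)
        T2 = group_stats(2 * z, zk, membership)
        np.testing.assert_allclose(T2[:, 0], 4 * T1[:, 0])


class TestKnockoffFilter:
    def test_single_strong_group_selected(self):
        """One dominant group among nulls is selected when 1/m <= q."""
        T = np.zeros((10, 6))
        T[0, 0] = 100.0
        res = knockoff_filter(T, q=0.2, m=5)
        assert res.selected[0] and res.selected.sum() == 1
        assert res.threshold <= 100.0

    def test_vanishing_q_selects_nothing(self):
        T = np.abs(np.random.default_rng(0).standard_normal((30, 6)))
        res = knockoff_filter(T, q=1e-9, m=5)
        assert res.selected.sum() == 0 and np.isinf(res.threshold)

    def test_never_selects_knockoff_winner(self, rng):
        T = np.abs(rng.standard_normal((200, 6)))
        res = knockoff_filter(T, q=0.5, m=5)
        assert not np.any(res.selected & (res.kappa != 0))

    def test_invariant_to_knockoff_column_relabeling(self, rng):
        T = np.abs(rng.standard_normal((50, 6))) * 3
        res = knockoff_filter(T, q=0.2, m=5)
        perm = np.concatenate([[0], 1 + rng.permutation(5)])
        res_p = knockoff_filter(T[:, perm], q=0.2, m=5)
        np.testing.assert_array_equal(res.selected, res_p.selected)
        np.testing.assert_array_equal(res.tau, res_p.tau)

    def test_ties_break_toward_knockoff(self):
        T = np.array([[5.0, 5.0, 1.0, 1.0, 1.0, 1.0]])
        res = knockoff_filter(T, q=0.5, m=5)
        assert res.kappa[0] == 1  # conservative: the tie is not an original win

    def test_null_fdp_controlled(self):
        """Exchangeable null T columns: mean FDP stays near or below q."""
        rng = np.random.default_rng(12345)
        q, m, reps = 0.2, 5, 500
        fdps = []
        for _ in range(reps):
            T = rng.chisquare(df=3, size=(40, m + 1))
            res = knockoff_filter(T, q=q, m=m)
            n_sel = res.selected.sum()
            fdps.append(1.0 if n_sel else 0.0)  # every selection is false
        mean_fdp = np.mean(fdps)
        se = np.std(fdps, ddof=1) / np.sqrt(reps)
        assert mean_fdp <= q + 2 * se


class TestComparators:
    def test_bonferroni_tail_arithmetic(self):
        z = np.array([0.0, 5.45, 6.0, -6.0])
        sel = bonferroni_marginal(z, alpha=5e-8)
        np.testing.assert_array_equal(sel, [2, 3])

    def test_bonferroni_monotone_in_abs_z(self, rng):
        z = rng.normal(0, 3, size=200)
        sel = set(bonferroni_marginal(z, alpha=1e-3))
        cut = min(np.abs(z[list(sel)])) if sel else np.inf
        for j in range(200):
            if abs(z[j]) > cut:
                assert j in sel

    def test_count_independent_greedy_merge(self):
        chrom = np.array(["1", "1", "1"])
        pos = np.array([1_000_000, 1_500_000, 3_000_000])
        assert count_independent(chrom, pos) == 2
        assert count_independent(np.array(["1"]), np.array([5])) == 1
        two = count_independent(np.array(["1", "2"]), np.array([100, 100]))
        assert two == 2


class TestZScoreAlignment:
    def test_exact_flip_and_drop(self, tmp_path):
        variants = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "pos": [100, 200, 300],
                "id": ["a", "b", "c"],
                "ref": ["A", "A", "A"],
                "alt": ["G", "G", "G"],
            }
        )
        zfile = tmp_path / "z.tsv"
        zfile.write_text(
            "CHR\tPOS\tREF\tALT\tZ\n"
            "1\t100\tA\tG\t2.0\n"
            "1\t200\tG\tA\t-1.5\n"  # allele flip: sign negated
            "1\t999\tA\tG\t3.0\n"  # no match for pos 300
        )
        z, kept, n_flip, n_drop = align_zscores(variants, read_zscores(zfile))
        np.testing.assert_array_equal(z, [2.0, 1.5])
        np.testing.assert_array_equal(kept, [0, 1])
        assert n_flip == 1 and n_drop == 1
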