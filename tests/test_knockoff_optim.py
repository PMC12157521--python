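"""Maximum-entropy solver and D-matrix assembly."""

import numpy as np
import pytest

from knockblock.grouping import build_groups
from knockblock.knockoff_optim import (
    assemble_D,
    check_feasibility,
    maxent_objective,
    solve_maxent,
)

from conftest import random_correlation


def grid_oracle_diag2(sigma, m, lo=1e-3, hi=1.5, steps=301, rounds=4):
    """Iteratively refined grid search over diagonal (s1, s2)."""
    A = (m + 1) / m * sigma
    b1, b2 = (lo, hi), (lo, hi)
    best = None
    for _ in range(rounds):
        s1 = np.linspace(*b1, steps)
        s2 = np.linspace(*b2, steps)
        S1, S2 = np.meshgrid(s1, s2, indexing="ij")
        m11, m22 = A[0, 0] - S1, A[1, 1] - S2
        det = m11 * m22 - A[0, 1] ** 2
        ok = (m11 > 0) & (det > 0) & (S1 > 0) & (S2 > 0)
        obj = np.where(ok, np.log(np.where(ok, det, 1.0)) + m * (np.log(S1) + np.log(S2)), -np.inf)
        i, j = np.unravel_index(np.argmax(obj), obj.shape)
        best = (s1[i], s2[j])
        w1, w2 = (b1[1] - b1[0]) / steps, (b2[1] - b2[0]) / steps
        b1 = (max(lo, best[0] - 2 * w1), best[0] + 2 * w1)
        b2 = (max(lo, best[1] - 2 * w2), best[1] + 2 * w2)
    return np.array(best)


def grid_oracle_group2(sigma, m, steps=101, rounds=4):
    """Refined grid over a full within-group 2x2 S = [[s1, o], [o, s2]]."""
    A = (m + 1) / m * sigma
    b1 = b2 = (1e-3, 1.5)
    bo = (-1.0, 1.0)
    best = None
    for _ in range(rounds):
        s1 = np.linspace(*b1, steps)
        s2 = np.linspace(*b2, steps)
        o = np.linspace(*bo, steps)
        S1, S2, O = np.meshgrid(s1, s2, o, indexing="ij")
        detS = S1 * S2 - O**2
        m11, m22, m12 = A[0, 0] - S1, A[1, 1] - S2, A[0, 1] - O
        detM = m11 * m22 - m12**2
        ok = (S1 > 0) & (detS > 0) & (m11 > 0) & (detM > 0)
        obj = np.where(
            ok,
            np.log(np.where(ok, detM, 1.0)) + m * np.log(np.where(ok, detS, 1.0)),
            -np.inf,
        )
        i, j, k = np.unravel_index(np.argmax(obj), obj.shape)
        best = (s1[i], s2[j], o[k])
        widths = [(b[1] - b[0]) / steps for b in (b1, b2, bo)]
        b1 = (max(1e-3, best[0] - 2 * widths[0]), best[0] + 2 * widths[0])
        b2 = (max(1e-3, best[1] - 2 * widths[1]), best[1] + 2 * widths[1])
        bo = (best[2] - 2 * widths[2], best[2] + 2 * widths[2])
    return np.array(best)


def grid_oracle_diag3(sigma, m, steps=61, rounds=5):
    """Refined grid over diagonal (s1, s2, s3) with explicit 3x3 minors."""
    A = (m + 1) / m * sigma
    bounds = [(1e-3, 1.5)] * 3
    best = None
    for _ in range(rounds):
        axes = [np.linspace(*b, steps) for b in bounds]
        S1, S2, S3 = np.meshgrid(*axes, indexing="ij")
        d1 = A[0, 0] - S1
        d2 = A[1, 1] - S2
        d3 = A[2, 2] - S3
        a, b, c = A[0, 1], A[0, 2], A[1, 2]
        minor2 = d1 * d2 - a**2
        det3 = d1 * (d2 * d3 - c**2) - a * (a * d3 - c * b) + b * (a * c - b * d2)
        ok = (d1 > 0) & (minor2 > 0) & (det3 > 0) & (S1 > 0) & (S2 > 0) & (S3 > 0)
        obj = np.where(
            ok,
            np.log(np.where(ok, det3, 1.0))
            + m * (np.log(S1) + np.log(S2) + np.log(S3)),
            -np.inf,
        )
        i, j, k = np.unravel_index(np.argmax(obj), obj.shape)
        best = (axes[0][i], axes[1][j], axes[2][k])
        widths = [(b[1] - b[0]) / steps for b in bounds]
        bounds = [
            (max(1e-3, x - 2 * w), x + 2 * w) for x, w in zip(best, widths)
        ]
    return np.array(best)


class TestSolveMaxent:
    def test_scalar_stationarity(self):
        """Sigma = [1], m = 5: d/ds [log(6/5 - s) + 5 log s] = 0 at s = 1."""
        S, trace = solve_maxent(np.array([[1.0]]), np.array([1]), m=5)
        assert S[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert trace == sorted(trace)

    @pytest.mark.parametrize("rho", [0.1, 0.3, 0.6, -0.4])
    def test_two_singletons_match_grid_oracle(self, rho):
        sigma = np.array([[1.0, rho], [rho, 1.0]])
        S, _ = solve_maxent(sigma, np.array([1, 2]), m=5)
        oracle = grid_oracle_diag2(sigma, m=5)
        np.testing.assert_allclose(np.diag(S), oracle, atol=1e-3)
        assert S[0, 1] == 0.0  # cross-group entries exactly zero

    def test_within_group_pair_matches_grid_oracle(self):
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        S, _ = solve_maxent(sigma, np.array([1, 1]), m=5)
        s1, s2, o = grid_oracle_group2(sigma, m=5)
        np.testing.assert_allclose([S[0, 0], S[1, 1], S[0, 1]], [s1, s2, o], atol=1e-3)

    def test_three_singletons_match_grid_oracle(self, rng):
        sigma = random_correlation(3, rng, jitter=0.5)
        S, _ = solve_maxent(sigma, np.array([1, 2, 3]), m=5)
        oracle = grid_oracle_diag3(sigma, m=5)
        np.testing.assert_allclose(np.diag(S), oracle, atol=1e-3)

    def test_group_relaxation_never_hurts(self):
        """A fully free 2x2 S attains at least the singleton-group optimum."""
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        S_free, _ = solve_maxent(sigma, np.array([1, 1]), m=5)
        S_diag, _ = solve_maxent(sigma, np.array([1, 2]), m=5)
        assert maxent_objective(S_free, sigma, 5) >= maxent_objective(S_diag, sigma, 5) - 1e-9

    def test_identity_sigma_gives_identity_S(self):
        S, _ = solve_maxent(np.eye(4), np.arange(1, 5), m=5)
        np.testing.assert_allclose(S, np.eye(4), atol=1e-6)

    def test_monotone_trace_and_kkt_on_random_instances(self, rng):
        """Trace never decreases; stationarity m S^-1 = (A - S)^-1 on the
        free (within-group) entries at the optimum."""
        for _ in range(25):
            p = int(rng.integers(2, 7))
            sigma = random_correlation(p, rng, jitter=0.4)
            groups = rng.integers(1, 3, size=p)
            groups = np.unique(groups, return_inverse=True)[1] + 1
            S, trace = solve_maxent(sigma, groups, m=5, tol=1e-14, max_iter=20000)
            assert all(b >= a - 1e-8 * max(1, abs(a)) for a, b in zip(trace, trace[1:]))
            A = 6 / 5 * sigma
            grad = 5 * np.linalg.inv(S) - np.linalg.inv(A - S)
            pattern = groups[:, None] == groups[None, :]
            assert np.abs(grad[pattern]).max() < 1e-4

    def test_non_pd_input_rejected(self):
        sigma = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            solve_maxent(sigma, np.array([1, 2]))


class TestAssembleD:
    def test_all_keys_returns_S_exactly(self, rng):
        sigma = random_correlation(5, rng, jitter=0.5)
        S, _ = solve_maxent(sigma, np.arange(1, 6), m=5)
        D = assemble_D(sigma, np.arange(5), S, m=5)
        np.testing.assert_array_equal(D, 0.5 * (S + S.T))

    def test_identity_sigma_single_key(self):
        """Sigma = I, R = {0}: A = 0, so D = diag(S, 1) from the block formula."""
        D = assemble_D(np.eye(2), np.array([0]), np.array([[1.0]]), m=5)
        np.testing.assert_allclose(D, np.eye(2), atol=1e-12)

    def test_random_blocks_satisfy_constraints(self, rng):
        for _ in range(20):
            p = int(rng.integers(4, 30))
            sigma = random_correlation(p, rng, jitter=0.3)
            gs = build_groups(sigma, cutoff=0.5, c=0.5)
            S, _ = solve_maxent(
                sigma[np.ix_(gs.keys, gs.keys)], gs.key_groups, m=5
            )
            D = assemble_D(sigma, gs.keys, S, m=5)
            report = check_feasibility(sigma, D, m=5)
            assert report.min_eig_D >= -1e-8
            assert report.min_eig_slack >= -1e-8

    def test_infeasible_S_raises_with_eigenvalue(self, rng):
        sigma = random_correlation(4, rng)
        S_bad = 10.0 * np.eye(4)
        with pytest.raises(ValueError, match="min eig"):
            assemble_D(sigma, np.arange(4), S_bad, m=5)


class TestCheckFeasibility:
    def test_zero_and_saturated_D(self, rng):
        sigma = random_correlation(6, rng)
        r0 = check_feasibility(sigma, np.zeros((6, 6)), m=5)
        assert r0.min_eig_D >= 0 and r0.min_eig_slack >= 0
        r1 = check_feasibility(sigma, 6 / 5 * sigma, m=5)
        assert abs(r1.min_eig_slack) < 1e-12
        with pytest.raises(ValueError, match="shape"):
            check_feasibility(sigma, np.zeros((5, 5)), m=5)
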