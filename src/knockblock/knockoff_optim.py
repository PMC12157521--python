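"""Maximum-entropy group-knockoff optimization.

For a block correlation matrix ``Sigma`` restricted to the group-key
variables R, the knockoff decorrelation matrix ``S`` maximizes

    log det( ((m+1)/m) Sigma_RR - S ) + m log det(S)

over symmetric ``S`` that is block-diagonal with respect to the group
structure, subject to both ``S`` and ``((m+1)/m) Sigma_RR - S`` being
positive semi-definite.  ``m`` is the number of knockoff copies per
feature (default 5).  Larger entries of ``S`` decorrelate knockoffs from
the originals and raise power; the entropy objective balances this against
the joint feasibility constraint.

The solver is cyclic coordinate ascent: diagonal entries have a closed-form
univariate maximizer; off-diagonal within-group entries use a bounded
line search over the interval keeping both log-det barriers finite.  Both
rank-one/rank-two determinant updates keep a sweep at O(r^2) per
coordinate via Sherman-Morrison/Woodbury inverse updates.

From the key-level optimum, the full-dimensional sampling matrix ``D`` is
assembled in (R, C) order as

    D = [[S,      S A      ],          A = Sigma_RR^-1 Sigma_RC
         [A' S,   D_22     ]],
    D_22 = Sigma_CC - Sigma_CR Sigma_RR^-1 Sigma_RC + A' S A,

which solves the same maximum-entropy problem for the full block and
satisfies ``D >= 0`` and ``((m+1)/m) Sigma - D >= 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "KnockoffParams",
    "FeasibilityReport",
    "maxent_objective",
    "solve_maxent",
    "assemble_D",
    "check_feasibility",
]

PSD_TOL = 1e-8  # eigenvalue tolerance for all feasibility checks


@dataclass
class FeasibilityReport:
    """Minimum eigenvalues of D and ((m+1)/m) Sigma - D."""

    min_eig_D: float
    min_eig_slack: float
    m: int

    @property
    def feasible(self) -> bool:
        return self.min_eig_D >= -PSD_TOL and self.min_eig_slack >= -PSD_TOL


@dataclass
class KnockoffParams:
    """Solved knockoff parameters for one LD block."""

    S: np.ndarray
    D: np.ndarray
    m: int
    objective_trace: list[float] = field(default_factory=list)
    feasibility: FeasibilityReport | None = None


def maxent_objective(S: np.ndarray, sigma_RR: np.ndarray, m: int) -> float:
    """log det(((m+1)/m) Sigma_RR - S) + m log det(S); -inf outside the domain."""
    A = ((m + 1) / m) * sigma_RR
    sign1, ld1 = np.linalg.slogdet(A - S)
    sign2, ld2 = np.linalg.slogdet(S)
    if sign1 <= 0 or sign2 <= 0:
        return -np.inf
    return float(ld1 + m * ld2)


def _sym_inverse(M: np.ndarray) -> np.ndarray:
    c, low = sla.cho_factor(M, lower=True)
    return sla.cho_solve((c, low), np.eye(M.shape[0]))


# The sweep kernels keep each inverse as a Fortran-ordered array whose
# *lower* triangle is authoritative, and update it in place with BLAS
# symmetric rank-1 calls (dsyr) — no per-coordinate allocations.

def _lower_col(a: np.ndarray, j: int) -> np.ndarray:
    """Column j of a symmetric matrix stored in the lower triangle, O(r)."""
    col = np.empty(a.shape[0])
    col[:j] = a[j, :j]
    col[j:] = a[j:, j]
    return col


def _rank1_inv_update(Minv: np.ndarray, j: int, delta: float) -> None:
    """Sherman-Morrison update of Minv (lower triangle) for M + delta e_j e_j'."""
    col = _lower_col(Minv, j)
    denom = 1.0 + delta * col[j]
    sla.blas.dsyr(-delta / denom, col, a=Minv, lower=1, overwrite_a=1)


def _rank2_inv_update(Minv: np.ndarray, j: int, k: int, delta: float) -> None:
    """Update Minv (lower triangle) for M + delta*(e_j e_k' + e_k e_j').

    The perturbation splits into delta*(u u' - v v') with
    u = (e_j + e_k)/sqrt(2), v = (e_j - e_k)/sqrt(2); two sequential
    Sherman-Morrison steps handle it exactly.
    """
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    w = (_lower_col(Minv, j) + _lower_col(Minv, k)) * inv_sqrt2  # Minv u
    denom = 1.0 + delta * (w[j] + w[k]) * inv_sqrt2
    sla.blas.dsyr(-delta / denom, w, a=Minv, lower=1, overwrite_a=1)
    w2 = (_lower_col(Minv, j) - _lower_col(Minv, k)) * inv_sqrt2  # Minv1 v
    denom2 = 1.0 - delta * (w2[j] - w2[k]) * inv_sqrt2
    sla.blas.dsyr(delta / denom2, w2, a=Minv, lower=1, overwrite_a=1)


def _feasible_root_interval(qa: float, qb: float) -> tuple[float, float]:
    """Open interval around 0 where qa*d^2 + qb*d + 1 > 0 (value 1 at d=0)."""
    lo, hi = -np.inf, np.inf
    if abs(qa) < 1e-300:
        if qb > 0:
            lo = -1.0 / qb
        elif qb < 0:
            hi = -1.0 / qb
        return lo, hi
    disc = qb * qb - 4.0 * qa
    if disc <= 0:
        # no real roots: qa > 0, positive everywhere
        return lo, hi
    r1 = (-qb - np.sqrt(disc)) / (2.0 * qa)
    r2 = (-qb + np.sqrt(disc)) / (2.0 * qa)
    r1, r2 = min(r1, r2), max(r2, r1)
    if qa < 0:
        # concave: positive between the roots
        return r1, r2
    # convex with real roots; 0 lies outside [r1, r2]
    if r1 > 0:
        return -np.inf, r1
    return r2, np.inf


def solve_maxent(
    sigma_RR: np.ndarray,
    key_groups: np.ndarray,
    m: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, list[float]]:
    """Coordinate-ascent solution of the maximum-entropy objective.

    Parameters
    ----------
    sigma_RR:
        Symmetric positive-definite correlation submatrix on the keys.
    key_groups:
        Group label per key; ``S`` is constrained block-diagonal over these.
    m:
        Knockoff copies per feature.
    tol:
        Relative objective-change stopping threshold per sweep.
    max_iter:
        Maximum number of full sweeps.

    Returns ``(S, objective_trace)`` with a monotone non-decreasing trace.
    """
    sigma_RR = np.asarray(sigma_RR, dtype=np.float64)
    r = sigma_RR.shape[0]
    key_groups = np.asarray(key_groups)
    if key_groups.shape[0] != r:
        raise ValueError("key_groups length must match sigma_RR")
    eigmin = float(np.linalg.eigvalsh(sigma_RR)[0])
    if eigmin <= 0:
        raise ValueError(
            f"sigma_RR must be positive definite (min eigenvalue {eigmin:.3e}); "
            "apply the eigenvalue floor upstream"
        )
    scale = (m + 1) / m
    A = scale * sigma_RR

    # strictly feasible diagonal start: s0 I with s0 < min(1, scale*eigmin)
    s0 = 0.9 * min(1.0, scale * eigmin)
    S = np.eye(r) * s0

    # coordinate list: all diagonals, plus within-group off-diagonals
    coords: list[tuple[int, int]] = [(j, j) for j in range(r)]
    for g in np.unique(key_groups):
        idx = np.flatnonzero(key_groups == g)
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                coords.append((int(idx[a]), int(idx[b])))

    obj = maxent_objective(S, sigma_RR, m)
    trace = [obj]
    margin = 1e-10
    refactor_every = 10  # exact SM/Woodbury updates; refactor for hygiene
    Sinv = Minv = None
    for sweep in range(max_iter):
        if sweep % refactor_every == 0:
            Sinv = np.asfortranarray(_sym_inverse(S))
            Minv = np.asfortranarray(_sym_inverse(A - S))  # slack inverse
            obj = max(obj, maxent_objective(S, sigma_RR, m))
        for j, k in coords:
            if j == k:
                u = Sinv[j, j]
                v = Minv[j, j]
                delta = (m * u - v) / ((m + 1) * u * v)
                lo = -1.0 / u + margin * max(1.0, 1.0 / u)
                hi = 1.0 / v - margin * max(1.0, 1.0 / v)
                delta = min(max(delta, lo), hi)
                if delta == 0.0:
                    continue
                S[j, j] += delta
                # log-det factors of the two barriers under the rank-1 step
                obj += m * np.log1p(delta * u) + np.log1p(-delta * v)
                _rank1_inv_update(Sinv, j, delta)
                _rank1_inv_update(Minv, j, -delta)
            else:
                # coords have j < k; read from the authoritative lower triangle
                b1 = Sinv[k, j]
                a1 = Sinv[j, j] * Sinv[k, k]
                b2 = Minv[k, j]
                a2 = Minv[j, j] * Minv[k, k]
                # det factors: q1(d) = (1+d b1)^2 - d^2 a1 for S,
                #              q2(d) = (1-d b2)^2 - d^2 a2 for the slack
                lo1, hi1 = _feasible_root_interval(b1 * b1 - a1, 2.0 * b1)
                lo2, hi2 = _feasible_root_interval(b2 * b2 - a2, -2.0 * b2)
                lo = max(lo1, lo2)
                hi = min(hi1, hi2)
                if not np.isfinite(lo) or not np.isfinite(hi):
                    # widest sensible search range when a barrier is one-sided
                    span = 10.0
                    lo = max(lo, -span)
                    hi = min(hi, span)
                width = hi - lo
                lo += 1e-9 * width
                hi -= 1e-9 * width
                if hi <= lo:
                    continue

                def neg_gain(d: float) -> float:
                    q1 = (1.0 + d * b1) ** 2 - d * d * a1
                    q2 = (1.0 - d * b2) ** 2 - d * d * a2
                    if q1 <= 0 or q2 <= 0:
                        return np.inf
                    return -(m * np.log(q1) + np.log(q2))

                res = minimize_scalar(neg_gain, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-12})
                delta = float(res.x)
                if not np.isfinite(res.fun) or -res.fun <= 0.0:
                    continue  # no improvement over d = 0
                S[j, k] += delta
                S[k, j] += delta
                obj += -float(res.fun)
                _rank2_inv_update(Sinv, j, k, delta)
                _rank2_inv_update(Minv, j, k, -delta)
        if obj < trace[-1]:  # numerical guard; coordinate steps are ascent steps
            obj = trace[-1]
        prev = trace[-1]
        trace.append(obj)
        if sweep > 0 and abs(obj - prev) <= tol * max(1.0, abs(prev)):
            break
    else:
        gap = float(np.linalg.eigvalsh(A - S)[0])
        logger.warning(
            "maxent solver hit max_iter=%d (final slack min eigenvalue %.3e)",
            max_iter, gap,
        )

    # enforce strict feasibility at return by shrinking toward the start
    S = _backtrack_feasible(S, A, s0)
    return S, trace


def _backtrack_feasible(S: np.ndarray, A: np.ndarray, s0: float) -> np.ndarray:
    S0 = np.eye(S.shape[0]) * s0
    gamma = 1.0
    for _ in range(60):
        cand = gamma * S + (1.0 - gamma) * S0
        if (
            np.linalg.eigvalsh(cand)[0] >= -PSD_TOL
            and np.linalg.eigvalsh(A - cand)[0] >= -PSD_TOL
        ):
            if gamma < 1.0:
                logger.info("maxent: backtracked to gamma=%.4f for feasibility", gamma)
            return cand
        gamma *= 0.9
    raise RuntimeError("could not restore feasibility of S by backtracking")


def assemble_D(
    sigma: np.ndarray, keys: np.ndarray, S: np.ndarray, m: int = 5
) -> np.ndarray:
    """Assemble the full-dimensional knockoff sampling matrix from S.

    ``keys`` are 0-based indices of the group-key variables R within the
    block; the remaining columns form C.  The result is permuted back to
    the original variant order and verified to satisfy ``D >= 0`` and
    ``((m+1)/m) Sigma - D >= 0`` within eigenvalue tolerance.
    """
    sigma = np.asarray(sigma, dtype=np.float64)
    p = sigma.shape[0]
    keys = np.asarray(keys, dtype=np.int64)
    comp = np.setdiff1d(np.arange(p), keys)
    if S.shape != (keys.size, keys.size):
        raise ValueError(f"S is {S.shape}, expected {(keys.size, keys.size)}")

    if comp.size == 0:
        D = np.array(S, dtype=np.float64, copy=True)
    else:
        sig_RR = sigma[np.ix_(keys, keys)]
        sig_RC = sigma[np.ix_(keys, comp)]
        c, low = sla.cho_factor(sig_RR, lower=True)
        A_mat = sla.cho_solve((c, low), sig_RC)  # Sigma_RR^-1 Sigma_RC
        D_RR = S
        D_RC = S @ A_mat
        D_CC = (
            sigma[np.ix_(comp, comp)]
            - sig_RC.T @ A_mat
            + A_mat.T @ S @ A_mat
        )
        D = np.empty((p, p))
        D[np.ix_(keys, keys)] = D_RR
        D[np.ix_(keys, comp)] = D_RC
        D[np.ix_(comp, keys)] = D_RC.T
        D[np.ix_(comp, comp)] = D_CC
    D = 0.5 * (D + D.T)

    report = check_feasibility(sigma, D, m)
    if not report.feasible:
        raise ValueError(
            "assembled D violates the knockoff constraints: "
            f"min eig(D) = {report.min_eig_D:.3e}, "
            f"min eig(((m+1)/m) Sigma - D) = {report.min_eig_slack:.3e}"
        )
    return D


def check_feasibility(sigma: np.ndarray, D: np.ndarray, m: int) -> FeasibilityReport:
    """Diagnostic: minimum eigenvalues of D and ((m+1)/m) Sigma - D."""
    if sigma.shape != D.shape:
        raise ValueError(f"shape mismatch: sigma {sigma.shape}, D {D.shape}")
    min_eig_D = float(np.linalg.eigvalsh(0.5 * (D + D.T))[0])
    slack = ((m + 1) / m) * sigma - D
    min_eig_slack = float(np.linalg.eigvalsh(0.5 * (slack + slack.T))[0])
    return FeasibilityReport(min_eig_D=min_eig_D, min_eig_slack=min_eig_slack, m=m)
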