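"""Knockoff inference from marginal GWAS Z-scores and an LD bundle.

Given variant-aligned marginal Z-scores ``z`` for one block and the
bundle's ``(Sigma, D, m)``, ghost sampling draws ``m`` exchangeable
knockoff copies of ``z`` without touching individual-level data:

    z_k = (I - D Sigma^-1) z + e_k,
    Cov(e_j, e_j) = 2D - D Sigma^-1 D,
    Cov(e_j, e_k) = D - D Sigma^-1 D   (j != k).

The joint covariance of ``(e_1, ..., e_m)`` has the Kronecker form
``I_m (x) D + 1_m 1_m' (x) W`` with ``W = D - D Sigma^-1 D``; an
orthogonal rotation in copy space block-diagonalizes it into one
``D + mW`` factor and ``m - 1`` independent ``D`` factors, so sampling
needs only p x p factorizations.

Group importance statistics (by default the within-group sum of squared
Z-scores) feed the multiple-knockoff kappa/tau filter, which selects
groups at a target FDR.  A Bonferroni marginal comparator and the 1 Mb
independent-locus counter are provided for benchmarking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ZScorePanel",
    "FilterResult",
    "DiscoverySet",
    "marginal_z",
    "sample_knockoff_z",
    "group_stats",
    "knockoff_filter",
    "bonferroni_marginal",
    "count_independent",
    "read_zscores",
    "align_zscores",
]

PSD_SAMPLING_TOL = 1e-6  # relative eigenvalue tolerance before declaring corruption


@dataclass
class ZScorePanel:
    """Marginal Z-scores aligned to one bundle block, plus knockoff copies."""

    variants: pd.DataFrame
    z: np.ndarray
    z_knock: np.ndarray | None = None
    seed: int | None = None


@dataclass
class FilterResult:
    """Output of the kappa/tau multiple-knockoff filter over G groups."""

    selected: np.ndarray  # boolean, length G
    kappa: np.ndarray  # argmax column per group (0 = original)
    tau: np.ndarray  # max minus median of the remaining copies
    threshold: float  # selection threshold on tau (inf if none attainable)
    target_fdr: float


@dataclass
class DiscoverySet:
    """Selected groups with genomic context, one row per discovery."""

    table: pd.DataFrame = field(repr=False)
    threshold: float = np.inf
    target_fdr: float = 0.1

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# marginal score statistic
# ---------------------------------------------------------------------------

def marginal_z(X: np.ndarray, y_tilde: np.ndarray) -> np.ndarray:
    """Score-statistic Z-scores ``z_j = X_j' y / sqrt(n)``.

    ``X`` must be column-standardized and ``y_tilde`` the
    covariate-residualized, standardized phenotype; the ``sqrt(n)``
    normalizer makes null scores N(0, 1).
    """
    y_tilde = np.asarray(y_tilde, dtype=np.float64).ravel()
    if X.shape[0] != y_tilde.size:
        raise ValueError(
            f"X has {X.shape[0]} rows but phenotype has {y_tilde.size} entries"
        )
    z = X.T @ y_tilde / np.sqrt(X.shape[0])
    if not np.isfinite(z).all():
        raise ValueError("non-finite Z-scores")
    return z


# ---------------------------------------------------------------------------
# ghost-knockoff sampling
# ---------------------------------------------------------------------------

def _psd_factor(M: np.ndarray, label: str) -> np.ndarray:
    """Symmetric square root with small negative eigenvalues clipped to 0."""
    M = 0.5 * (M + M.T)
    eigval, eigvec = np.linalg.eigh(M)
    scale = max(1.0, float(eigval[-1]))
    if eigval[0] < -PSD_SAMPLING_TOL * scale:
        raise ValueError(
            f"{label} has min eigenvalue {eigval[0]:.3e}; the (Sigma, D, m) "
            "bundle is infeasible or corrupted"
        )
    return eigvec * np.sqrt(np.clip(eigval, 0.0, None))


def sample_knockoff_z(
    z: np.ndarray,
    sigma: np.ndarray,
    D: np.ndarray,
    m: int = 5,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``m`` exchangeable ghost-knockoff copies of ``z``.

    ``z`` may be a single length-p vector (returns ``p x m``) or a
    ``B x p`` batch of independent draws (returns ``B x p x m``); the
    batch form shares one covariance factorization.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    Z = z[None, :] if single else z
    B, p = Z.shape

    sigma_inv_D = np.linalg.solve(sigma, D)  # Sigma^-1 D
    mean = Z - Z @ sigma_inv_D  # rows: (I - D Sigma^-1) z
    W = D - D @ sigma_inv_D  # D - D Sigma^-1 D (may be indefinite alone)
    L_shared = _psd_factor(D + m * W, "D + m (D - D Sigma^-1 D)")
    L_copy = _psd_factor(D, "D")

    # orthogonal copy-space basis with first column 1/sqrt(m)
    Q = np.linalg.qr(
        np.column_stack([np.ones(m) / np.sqrt(m), np.eye(m)[:, : m - 1]])
    )[0]
    Q[:, 0] = np.sign(Q[0, 0]) * Q[:, 0]  # fix sign so Q[:,0] = 1/sqrt(m)

    u = rng.standard_normal((B, m, p))
    u0 = u[:, 0, :] @ L_shared.T
    rest = u[:, 1:, :] @ L_copy.T if m > 1 else np.empty((B, 0, p))
    comps = np.concatenate([u0[:, None, :], rest], axis=1)  # B x m x p
    e = np.einsum("km,bmp->bkp", Q, comps)  # rotate back to copy space
    z_knock = mean[:, None, :] + e  # B x m x p
    z_knock = np.moveaxis(z_knock, 1, 2)  # B x p x m
    return z_knock[0] if single else z_knock


# ---------------------------------------------------------------------------
# group statistics and the multiple-knockoff filter
# ---------------------------------------------------------------------------

def group_stats(
    z: np.ndarray,
    z_knock: np.ndarray,
    membership: np.ndarray,
    importance: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Per-group importance matrix T of shape G x (m+1).

    Column 0 holds the original scores; columns 1..m the knockoff copies.
    The default importance of a variant is its squared Z-score, summed
    within groups; pass ``importance`` to plug in another per-variant
    transform of the Z-vector.
    """
    membership = np.asarray(membership, dtype=np.int64)
    if z.shape[0] != membership.size or z_knock.shape[0] != membership.size:
        raise ValueError("z / z_knock not aligned with membership")
    imp = importance if importance is not None else np.square
    all_z = np.column_stack([z, z_knock])  # p x (m+1)
    per_variant = imp(all_z)
    G = int(membership.max())
    T = np.zeros((G, all_z.shape[1]))
    np.add.at(T, membership - 1, per_variant)
    return T


def knockoff_filter(T: np.ndarray, q: float, m: int) -> FilterResult:
    """Multiple-knockoff kappa/tau selection at target FDR ``q``.

    ``kappa_g`` is the column achieving the row maximum (ties broken
    toward a knockoff column, conservatively); ``tau_g`` is the maximum
    minus the median of the remaining ``m`` values.  The data-dependent
    threshold is the smallest ``t > 0`` with

        (1/m + (1/m) #{kappa != 0, tau >= t}) / max(1, #{kappa = 0, tau >= t}) <= q.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"target FDR must lie in (0, 1), got {q}")
    T = np.asarray(T, dtype=np.float64)
    if T.shape[1] != m + 1:
        raise ValueError(f"T has {T.shape[1]} columns, expected m+1 = {m + 1}")
    knock_max = T[:, 1:].max(axis=1)
    kappa = np.where(T[:, 0] > knock_max, 0, 1 + np.argmax(T[:, 1:], axis=1))
    sorted_desc = -np.sort(-T, axis=1)
    tau = sorted_desc[:, 0] - np.median(sorted_desc[:, 1:], axis=1)

    threshold = np.inf
    for t in np.sort(np.unique(tau[tau > 0])):
        n_knock = int(np.sum((kappa != 0) & (tau >= t)))
        n_orig = int(np.sum((kappa == 0) & (tau >= t)))
        fdp_hat = (1.0 / m + n_knock / m) / max(1, n_orig)
        if fdp_hat <= q:
            threshold = float(t)
            break
    selected = (kappa == 0) & (tau >= threshold)
    return FilterResult(
        selected=selected, kappa=kappa, tau=tau, threshold=threshold, target_fdr=q
    )


# ---------------------------------------------------------------------------
# comparators
# ---------------------------------------------------------------------------

def bonferroni_marginal(z: np.ndarray, alpha: float = 5e-8) -> np.ndarray:
    """Indices of variants with two-sided normal p-value strictly below alpha."""
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=np.float64)))
    return np.flatnonzero(p < alpha)


def count_independent(
    chrom: np.ndarray, pos: np.ndarray, window: float = 1_000_000
) -> int:
    """Count independent loci: greedy left-to-right merge within ``window``.

    A discovery anchors a new locus iff it is at least ``window`` base
    pairs from the previous locus anchor on the same chromosome, or lies
    on a new chromosome.  Positions must be sorted within chromosome.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.float64)
    if chrom.size == 0:
        return 0
    count = 0
    last_chrom, anchor = None, -np.inf
    for c, x in zip(chrom, pos):
        if c != last_chrom:
            last_chrom, anchor = c, x
            count += 1
        elif x < anchor:
            raise ValueError("positions must be sorted within chromosome")
        elif x - anchor >= window:
            anchor = x
            count += 1
    return count


# ---------------------------------------------------------------------------
# Z-score file handling and alignment
# ---------------------------------------------------------------------------

ZFILE_COLUMNS = ["CHR", "POS", "REF", "ALT", "Z"]


def read_zscores(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated Z-score table with header CHR POS REF ALT Z."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "REF": str, "ALT": str})
    missing = [c for c in ZFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Z-score file {path} lacks columns {missing}")
    df["POS"] = df["POS"].astype(np.int64)
    return df


def align_zscores(
    variants: pd.DataFrame, ztable: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Align a Z-score table to a block's variant list.

    Matching is exact on (chrom, pos, ref, alt).  An allele flip
    (ref/alt swapped) is accepted with the Z sign negated.  Any other
    mismatch drops the variant.  Returns ``(z, kept_index, n_flipped,
    n_dropped)`` where ``kept_index`` indexes the block's variants.
    """
    lookup = {
        (str(r.CHR), int(r.POS), r.REF, r.ALT): float(r.Z)
        for r in ztable.itertuples()
    }
    z_vals, kept = [], []
    n_flipped = n_dropped = 0
    for j, r in enumerate(variants.itertuples()):
        key = (str(r.chrom), int(r.pos), r.ref, r.alt)
        flipped = (str(r.chrom), int(r.pos), r.alt, r.ref)
        if key in lookup:
            z_vals.append(lookup[key])
            kept.append(j)
        elif flipped in lookup:
            z_vals.append(-lookup[flipped])
            kept.append(j)
            n_flipped += 1
        else:
            n_dropped += 1
    if n_flipped:
        logger.info("align_zscores: %d allele flips (Z sign negated)", n_flipped)
    if n_dropped:
        logger.warning(
            "align_zscores: dropped %d of %d block variants with no Z-score match",
            n_dropped, len(variants),
        )
    return (
        np.asarray(z_vals, dtype=np.float64),
        np.asarray(kept, dtype=np.int64),
        n_flipped,
        n_dropped,
    )
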