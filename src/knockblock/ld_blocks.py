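"""Quasi-independent LD block discovery and per-block correlation estimation.

The genome-wide correlation matrix is approximated as block-diagonal:
variants in different blocks are treated as independent.  Blocks are found
per chromosome by a dynamic program that minimizes the total squared
cross-block correlation, counting only pairs with ``r^2 >= thr_r2`` and
forbidding any split that separates a pair with ``r^2 > max_r2``.  Block
sizes are constrained to ``[min_size, max_size]`` where feasible.

Within each block the correlation matrix is estimated from the
covariate-residualized standardized genotypes as ``Sigma = X'X / n``, its
eigenvalues floored at 1e-5 for numerical stability, and the result
rescaled to an exactly unit diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BlockBoundaries",
    "CovariateMatrix",
    "LDBlock",
    "split_blocks",
    "split_cost",
    "residual_adjust",
    "estimate_sigma",
    "read_block_table",
    "write_block_table",
]


@dataclass
class BlockBoundaries:
    """Ordered half-open column ranges ``[start, stop)`` covering all variants."""

    blocks: list[tuple[int, int]]
    chroms: list[str]

    def __post_init__(self) -> None:
        if len(self.blocks) != len(self.chroms):
            raise ValueError("one chromosome label per block required")
        for (s0, e0), (s1, _) in zip(self.blocks, self.blocks[1:]):
            if e0 != s1:
                raise ValueError(f"blocks not contiguous at [{s0},{e0}) -> start {s1}")
        if self.blocks and self.blocks[0][0] != 0:
            raise ValueError("first block must start at column 0")

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


@dataclass
class CovariateMatrix:
    """Covariates for LD adjustment; an intercept column is added if absent."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] == 1 and self.values.shape[1] > 1 and not self.names:
            self.values = self.values.T
        if not self.names:
            self.names = [f"covar_{j}" for j in range(self.values.shape[1])]
        # add intercept if no constant column present
        col_sd = self.values.std(axis=0)
        if not (col_sd == 0).any():
            self.values = np.column_stack(
                [np.ones(self.values.shape[0]), self.values]
            )
            self.names = ["intercept"] + self.names


@dataclass
class LDBlock:
    """A contiguous variant range with its adjusted correlation matrix."""

    start: int
    stop: int
    chrom: str
    sigma: np.ndarray
    variants: pd.DataFrame = field(repr=False)

    @property
    def size(self) -> int:
        return self.stop - self.start


# ---------------------------------------------------------------------------
# block splitting
# ---------------------------------------------------------------------------

def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared correlations assuming columns standardized with divisor n."""
    n = X.shape[0]
    r = (X.T @ X) / n
    return r * r


def split_cost(
    r2: np.ndarray, boundaries: list[int], thr_r2: float
) -> float:
    """Sum of cross-block squared correlations counting pairs with r2 >= thr_r2.

    ``boundaries`` are the interior cut points (a cut at ``t`` separates
    columns ``< t`` from columns ``>= t``).
    """
    p = r2.shape[0]
    labels = np.zeros(p, dtype=int)
    for t in boundaries:
        labels[t:] += 1
    w = np.where(r2 >= thr_r2, r2, 0.0)
    iu = np.triu_indices(p, k=1)
    cross = labels[iu[0]] != labels[iu[1]]
    return float(w[iu][cross].sum())


def _split_one_chrom(
    w: np.ndarray,
    forbidden: np.ndarray,
    min_size: int,
    max_size: int,
) -> list[int] | None:
    """DP over cut points maximizing within-block weight (== minimizing cross).

    Returns interior boundaries, or None when no size-feasible partition
    avoiding forbidden cuts exists.  Ties in cost are broken toward fewer
    blocks, then toward lexicographically earliest boundaries (determinism).
    """
    p = w.shape[0]
    # prefix[i][j] rectangle sums for within-block weight of [a, b):
    # within(a,b) = (S[b,b] - S[a,b] - S[b,a] + S[a,a]) / 2 minus diagonal (=0)
    S = np.zeros((p + 1, p + 1))
    S[1:, 1:] = w.cumsum(axis=0).cumsum(axis=1)

    def within(a: int, b: int) -> float:
        return 0.5 * (S[b, b] - 2 * S[a, b] + S[a, a])

    NEG = -np.inf
    best = np.full(p + 1, NEG)
    nblk = np.full(p + 1, 10**9)
    prev = np.full(p + 1, -1, dtype=int)
    best[0] = 0.0
    nblk[0] = 0
    for i in range(1, p + 1):
        lo = max(0, i - max_size)
        hi = i - min_size
        if i == p and hi < 0:
            hi = i - 1  # allow a smaller terminal remainder block
        for s in range(lo, hi + 1):
            if best[s] == NEG:
                continue
            if s > 0 and forbidden[s]:
                continue
            cand = best[s] + within(s, i)
            if cand > best[i] + 1e-12 or (
                abs(cand - best[i]) <= 1e-12 and nblk[s] + 1 < nblk[i]
            ):
                best[i] = cand
                nblk[i] = nblk[s] + 1
                prev[i] = s
    if best[p] == NEG:
        return None
    cuts: list[int] = []
    i = p
    while prev[i] > 0:
        cuts.append(int(prev[i]))
        i = prev[i]
    return sorted(cuts)


def split_blocks(
    X: np.ndarray,
    variants: pd.DataFrame,
    thr_r2: float = 0.01,
    max_r2: float = 0.3,
    min_size: int = 500,
    max_size: int = 1000,
) -> BlockBoundaries:
    """Find quasi-independent LD blocks per chromosome.

    Parameters follow the LD-splitting convention: ``thr_r2`` is the
    smallest squared correlation that contributes to the split cost,
    ``max_r2`` the largest squared correlation that may ever be cut, and
    ``min_size``/``max_size`` bound block sizes.  The optimizer is an exact
    dynamic program over contiguous partitions; if no feasible partition
    exists for a chromosome it falls back to a single block with a warning.
    """
    if min_size > max_size:
        raise ValueError(f"min_size ({min_size}) > max_size ({max_size})")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    p = X.shape[1]
    if len(variants) != p:
        raise ValueError("variant table does not match matrix width")
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    # variants must be position-sorted within each chromosome, chromosomes contiguous
    starts = [0] + [j for j in range(1, p) if chrom[j] != chrom[j - 1]]
    if len(set(chrom[starts])) != len(starts):
        raise ValueError("variants of one chromosome must be contiguous")
    for a, b in zip(starts, starts[1:] + [p]):
        if np.any(np.diff(pos[a:b]) < 0):
            raise ValueError(f"variants on chromosome {chrom[a]} not sorted by position")

    blocks: list[tuple[int, int]] = []
    chroms: list[str] = []
    for a, b in zip(starts, starts[1:] + [p]):
        pc = b - a
        if pc < min_size:
            cuts: list[int] | None = []
        else:
            r2 = _pairwise_r2(X[:, a:b])
            w = np.where(r2 >= thr_r2, r2, 0.0)
            np.fill_diagonal(w, 0.0)
            # a cut at t is forbidden if some pair j < t <= k has r2 > max_r2
            forbidden = np.zeros(pc + 1, dtype=bool)
            jj, kk = np.nonzero(np.triu(r2, k=1) > max_r2)
            delta = np.zeros(pc + 2, dtype=np.int64)
            np.add.at(delta, jj + 1, 1)
            np.add.at(delta, kk + 1, -1)
            forbidden[: pc + 1] = delta[: pc + 1].cumsum() > 0
            cuts = _split_one_chrom(w, forbidden, min_size, max_size)
        if cuts is None:
            logger.warning(
                "chromosome %s: no feasible split under min_size=%d, max_size=%d, "
                "max_r2=%g; using a single block of %d variants",
                chrom[a], min_size, max_size, max_r2, pc,
            )
            cuts = []
        edges = [0] + cuts + [pc]
        for s, e in zip(edges, edges[1:]):
            blocks.append((a + s, a + e))
            chroms.append(str(chrom[a]))
    return BlockBoundaries(blocks=blocks, chroms=chroms)


# ---------------------------------------------------------------------------
# covariate adjustment and correlation estimation
# ---------------------------------------------------------------------------

def residual_adjust(X: np.ndarray, C: CovariateMatrix | None) -> np.ndarray:
    """Project covariates out of each genotype column.

    Applies the residual-maker matrix ``I - C (C'C)^-1 C'`` to ``X``.  With
    no covariates the input is returned unchanged.
    """
    if C is None:
        return X
    cv = C.values
    if cv.shape[0] != X.shape[0]:
        raise ValueError(
            f"covariate rows ({cv.shape[0]}) != genotype rows ({X.shape[0]})"
        )
    rank = np.linalg.matrix_rank(cv)
    if rank < cv.shape[1]:
        raise ValueError(
            f"covariate matrix is rank deficient (rank {rank} < {cv.shape[1]} "
            "columns); remove collinear covariates"
        )
    # residuals via least squares; no explicit projection matrix
    coef, *_ = np.linalg.lstsq(cv, X, rcond=None)
    return X - cv @ coef


def estimate_sigma(X_adj: np.ndarray, eig_floor: float = 1e-5) -> np.ndarray:
    """Correlation estimate with eigenvalue floor and unit-diagonal rescale.

    ``Sigma = X'X / n`` on the (residualized, standardized) block columns;
    eigenvalues below ``eig_floor`` are clipped up to it, the matrix is
    reconstructed, and finally rescaled as ``D^-1/2 Sigma D^-1/2`` so the
    diagonal is exactly 1.  The rescale can pull the smallest eigenvalue
    slightly below the floor; downstream validation checks >= 1e-6.
    """
    n = X_adj.shape[0]
    if n <= 1:
        raise ValueError("need n > 1 samples")
    if not np.isfinite(X_adj).all():
        raise ValueError("non-finite entries in adjusted genotype matrix")
    sigma = (X_adj.T @ X_adj) / n
    sigma = 0.5 * (sigma + sigma.T)
    eigval, eigvec = np.linalg.eigh(sigma)
    if eigval[0] < eig_floor:
        eigval = np.maximum(eigval, eig_floor)
        sigma = (eigvec * eigval) @ eigvec.T
        sigma = 0.5 * (sigma + sigma.T)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    np.fill_diagonal(sigma, 1.0)
    return sigma


# ---------------------------------------------------------------------------
# block table I/O (chrom, start_index, stop_index, n_variants)
# ---------------------------------------------------------------------------

def write_block_table(boundaries: BlockBoundaries, path: str | Path) -> None:
    """Write boundaries as 4-column TSV: chrom, start_index, stop_index, n_variants."""
    df = pd.DataFrame(
        {
            "chrom": boundaries.chroms,
            "start_index": [s for s, _ in boundaries.blocks],
            "stop_index": [e for _, e in boundaries.blocks],
            "n_variants": [e - s for s, e in boundaries.blocks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_block_table(path: str | Path) -> BlockBoundaries:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start_index", "stop_index"}
    if not required.issubset(df.columns):
        raise ValueError(f"block table must have columns {sorted(required)}")
    return BlockBoundaries(
        blocks=[(int(s), int(e)) for s, e in zip(df["start_index"], df["stop_index"])],
        chroms=[str(c) for c in df["chrom"]],
    )
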