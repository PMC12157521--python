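"""Variant grouping and group-key selection within an LD block.

Conditional-independence hypotheses are tested at the level of groups of
tightly correlated variants.  Groups come from average-linkage hierarchical
clustering on the distance ``1 - |r|``, cut so that merged leaves have
average absolute correlation at least the cutoff (0.5 by default).

Within each group a small set of *group-key* variables is chosen to carry
the cross-group dependence: greedy forward selection adds members until the
average squared multiple correlation of the remaining members on the
selected set reaches ``c`` (0.5 by default).  The knockoff optimization is
then solved on the key submatrix only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["GroupStructure", "cluster_groups", "select_group_keys", "build_groups"]


@dataclass
class GroupStructure:
    """Group labels, key indices, and attained explained variance for a block.

    ``membership`` holds 1-based contiguous group labels ordered by first
    member position; ``keys`` is the sorted union of per-group key indices
    (0-based into the block); ``c_achieved`` maps group label -> average
    R^2 of its non-key members on the keys at the stopping step.
    """

    membership: np.ndarray
    keys: np.ndarray
    c_achieved: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.int64)
        self.keys = np.asarray(self.keys, dtype=np.int64)
        labels = np.unique(self.membership)
        if labels.size and (labels[0] != 1 or labels[-1] != labels.size):
            raise ValueError("group labels must be contiguous starting at 1")
        key_groups = set(self.membership[self.keys].tolist())
        if key_groups != set(labels.tolist()):
            raise ValueError("every group must contain at least one key variable")

    @property
    def n_groups(self) -> int:
        return int(self.membership.max()) if self.membership.size else 0

    @property
    def key_groups(self) -> np.ndarray:
        """Group label of each key, aligned with ``keys``."""
        return self.membership[self.keys]

    def to_frame(self, variants: pd.DataFrame | None = None) -> pd.DataFrame:
        """Dump as a table (variant id, group label, is_key) for inspection."""
        df = pd.DataFrame(
            {
                "group": self.membership,
                "is_key": np.isin(np.arange(self.membership.size), self.keys),
            }
        )
        if variants is not None:
            df.insert(0, "id", variants["id"].to_numpy())
        return df


def cluster_groups(sigma: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Average-linkage clustering of variants at an absolute-correlation cutoff.

    The dendrogram on distance ``d(j,k) = 1 - |sigma_jk|`` is cut at height
    ``1 - cutoff`` (inclusive), so any merged pair of clusters has average
    absolute correlation >= ``cutoff``.  Returns 1-based labels relabeled
    by first member position.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    p = sigma.shape[0]
    if p == 1:
        return np.ones(1, dtype=np.int64)
    dist = 1.0 - np.abs(sigma)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=1.0 - cutoff, criterion="distance")
    return _relabel_by_first_member(raw)


def _relabel_by_first_member(labels: np.ndarray) -> np.ndarray:
    order: dict[int, int] = {}
    out = np.empty(labels.size, dtype=np.int64)
    for j, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
        out[j] = order[lab]
    return out


def _r2_given(sigma: np.ndarray, j: int, selected: list[int]) -> float:
    """Squared multiple correlation of variant j on the selected set.

    Unit-variance convention: R^2(j | S) = sigma_jS Sigma_SS^-1 sigma_Sj.
    """
    s = sigma[np.ix_(selected, selected)]
    v = sigma[selected, j]
    return float(v @ np.linalg.solve(s, v))


def select_group_keys(
    sigma: np.ndarray, membership: np.ndarray, c: float = 0.5
) -> tuple[np.ndarray, dict[int, float]]:
    """Greedy forward selection of group-key variables.

    Per group: start empty and repeatedly add the member maximizing the
    average R^2 of the still-unselected members given the selected set;
    stop once that average reaches ``c`` or the group is exhausted.
    Singleton groups contribute their single member.  Returns the sorted
    union of keys and the attained per-group averages.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must lie in [0, 1], got {c}")
    membership = np.asarray(membership, dtype=np.int64)
    keys: list[int] = []
    c_achieved: dict[int, float] = {}
    for g in np.unique(membership):
        members = np.flatnonzero(membership == g).tolist()
        if len(members) == 1:
            keys.append(members[0])
            c_achieved[int(g)] = 1.0
            continue
        selected: list[int] = []
        achieved = 0.0
        while True:
            remaining = [j for j in members if j not in selected]
            if not remaining:
                achieved = 1.0
                break
            best_j, best_avg = -1, -np.inf
            for cand in remaining:
                trial = selected + [cand]
                others = [j for j in members if j not in trial]
                if not others:
                    avg = 1.0
                else:
                    avg = float(
                        np.mean([_r2_given(sigma, j, trial) for j in others])
                    )
                if avg > best_avg:  # ties toward lower index (iteration order)
                    best_j, best_avg = cand, avg
            selected.append(best_j)
            achieved = best_avg
            if best_avg >= c:
                break
        keys.extend(selected)
        c_achieved[int(g)] = achieved
    return np.array(sorted(keys), dtype=np.int64), c_achieved


def build_groups(
    sigma: np.ndarray, cutoff: float = 0.5, c: float = 0.5
) -> GroupStructure:
    """Cluster a block and select its group keys in one call."""
    membership = cluster_groups(sigma, cutoff=cutoff)
    keys, c_achieved = select_group_keys(sigma, membership, c=c)
    return GroupStructure(membership=membership, keys=keys, c_achieved=c_achieved)
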