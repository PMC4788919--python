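"""Clustering of lead-SNP effect patterns across traits.

Two QTL acting through the same physiological pathway are expected to
show similar per-trait effect profiles.  The pairwise Pearson correlation
of lead-SNP effects (signed t-values by default) across traits is turned
into the distance d = 1 - r and clustered agglomeratively; the tree is
cut at k groups.

Because the sign of a SNP's effect vector depends on the arbitrary A/B
allele labelling, each lead's effect row is first re-signed so that its
largest-magnitude trait effect is positive.  After this normalisation the
sign of the correlation is meaningful and d = 1 - r (rather than
1 - |r|) is the appropriate distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def normalize_allele_sign(effects: pd.DataFrame) -> pd.DataFrame:
    """Remove the arbitrary A/B allele labelling from effect rows.

    The anchor row (largest effect-vector norm) is re-signed so that its
    largest-|value| entry is positive; every other row is then aligned
    greedily, flipping it when its strongest correlation with the
    already-aligned rows is negative.  Rows nearly orthogonal to all
    aligned rows keep their own max-entry-positive orientation.
    Correlation-based alignment is robust where a per-row max-entry rule
    is not: two members of one pattern group anchored on different traits
    would otherwise end up anti-correlated.
    """
    arr = effects.to_numpy(dtype=float).copy()
    n = len(arr)

    def max_entry_sign(row: np.ndarray) -> float:
        s = np.sign(row[np.argmax(np.abs(row))])
        return s if s != 0 else 1.0

    if n == 1:
        return effects.mul([max_entry_sign(arr[0])], axis=0)
    corr = np.corrcoef(arr)
    norms = np.linalg.norm(arr, axis=1)
    signs = np.zeros(n)
    seed = int(np.argmax(norms))
    signs[seed] = max_entry_sign(arr[seed])
    aligned = [seed]
    remaining = set(range(n)) - {seed}
    while remaining:
        # next row: strongest absolute correlation with any aligned row
        best, best_row, best_partner = -1.0, None, None
        for i in sorted(remaining):
            j = max(aligned, key=lambda a: abs(corr[i, a]))
            if abs(corr[i, j]) > best:
                best, best_row, best_partner = abs(corr[i, j]), i, j
        if best < 0.3:  # effectively orthogonal to everything aligned
            signs[best_row] = max_entry_sign(arr[best_row])
        else:
            signs[best_row] = signs[best_partner] * np.sign(
                corr[best_row, best_partner]
            ) or 1.0
        aligned.append(best_row)
        remaining.discard(best_row)
    return effects.mul(signs, axis=0)


def lead_effect_correlations(
    effects: pd.DataFrame, sign_normalize: bool = True
) -> pd.DataFrame:
    """Lead x lead Pearson correlation of per-trait effect patterns.

    ``effects`` is leads x traits (t-values or betas).  Constant rows are
    rejected (their correlation is undefined).
    """
    if effects.isna().any().any():
        raise ValueError("effect pattern matrix must be complete")
    if (effects.std(axis=1, ddof=0) == 0).any():
        bad = effects.index[effects.std(axis=1, ddof=0) == 0][0]
        raise ValueError(f"lead {bad!r} has a constant effect pattern")
    if sign_normalize:
        effects = normalize_allele_sign(effects)
    corr = np.corrcoef(effects.to_numpy(dtype=float))
    return pd.DataFrame(corr, index=effects.index, columns=effects.index)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # lead snp_id -> group label (1..k)
    k: int
    linkage_method: str
    dendrogram_order: list[str]
    newick: str

    def groups(self) -> dict[int, list[str]]:
        return {
            g: list(self.labels.index[self.labels == g])
            for g in sorted(self.labels.unique())
        }


def _to_newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.get_left(), names)
    right = _to_newick(node.get_right(), names)
    dl = max(node.dist - node.get_left().dist, 0.0)
    dr = max(node.dist - node.get_right().dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_leads(
    corr: pd.DataFrame, k: int = 5, linkage: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of leads on distance 1 - r, cut at k.

    Returns group labels, the dendrogram leaf order (for heatmap
    rendering) and a Newick export of the tree.
    """
    n = len(corr)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    arr = corr.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if np.nanmax(np.abs(arr)) > 1 + 1e-8:
        raise ValueError("correlations must lie in [-1, 1]")
    dist = np.clip(1.0 - arr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if n == 1:
        labels = pd.Series([1], index=corr.index)
        return ClusterAssignment(labels=labels, k=1, linkage_method=linkage,
                                 dendrogram_order=list(corr.index),
                                 newick=f"{corr.index[0]};")
    Z = hierarchy.linkage(condensed, method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = [corr.index[i] for i in hierarchy.leaves_list(Z)]
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, list(corr.index)) + ";"
    labels = pd.Series(flat, index=corr.index, name="group")
    return ClusterAssignment(labels=labels, k=k, linkage_method=linkage,
                             dendrogram_order=order, newick=newick)
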