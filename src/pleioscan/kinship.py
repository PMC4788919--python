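"""Pedigree-based additive relationship matrix (the A matrix).

Built with the tabular method over the full pedigree: processing animals
parents-before-offspring,

    A[i,i] = 1 + 0.5 * A[s,d]
    A[i,j] = 0.5 * (A[j,s] + A[j,d])      for every earlier animal j,

with an unknown parent contributing zero relationship.  The matrix is the
covariance structure of the polygenic random effect in the mixed model,
``a ~ N(0, A * sigma_a^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pleioscan.data import UNKNOWN_PARENT, check_pedigree


@dataclass
class AMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("A matrix shape does not match id list")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def subset(self, ids) -> np.ndarray:
        """Dense A restricted to the given animals, in the given order."""
        try:
            idx = np.array([self._index[a] for a in ids])
        except KeyError as err:
            raise KeyError(f"animal {err.args[0]!r} not in pedigree") from None
        return self.values[np.ix_(idx, idx)]

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0


def _topological_order(ped: pd.DataFrame) -> list[int]:
    """Parents-before-offspring order; raises naming a cycle if one exists."""
    ids = list(ped["animal"])
    index = {a: i for i, a in enumerate(ids)}
    parents = {}
    for row in ped.itertuples(index=False):
        ps = [p for p in (row.sire, row.dam)
              if p != UNKNOWN_PARENT and p in index]
        parents[row.animal] = ps
    indeg = {a: len(parents[a]) for a in ids}
    children: dict[str, list[str]] = {a: [] for a in ids}
    for a, ps in parents.items():
        for p in ps:
            children[p].append(a)
    queue = [a for a in ids if indeg[a] == 0]
    order: list[int] = []
    while queue:
        a = queue.pop()
        order.append(index[a])
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) < len(ids):
        stuck = next(a for a in ids if indeg[a] > 0)
        cycle = [stuck]
        node = parents[stuck][0]
        while node != stuck and len(cycle) <= len(ids):
            cycle.append(node)
            node = parents[node][0] if parents[node] else node
        raise ValueError(
            "pedigree contains a cycle involving: " + " -> ".join(cycle)
        )
    return order


def build_amatrix(ped: pd.DataFrame) -> AMatrix:
    """Additive relationship matrix over all pedigree members.

    Parents referenced but absent from the pedigree are treated as
    unknown.  Inbreeding is accumulated exactly via the tabular
    recursion.
    """
    check_pedigree(ped)
    order = _topological_order(ped)
    ids = [ped["animal"].iloc[i] for i in order]
    index = {a: i for i, a in enumerate(ids)}
    sires = [ped["sire"].iloc[i] for i in order]
    dams = [ped["dam"].iloc[i] for i in order]
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s = index.get(sires[i], -1)
        d = index.get(dams[i], -1)
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
        elif s >= 0 or d >= 0:
            p = max(s, d)
            A[i, i] = 1.0
            A[i, :i] = 0.5 * A[p, :i]
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return AMatrix(ids=ids, values=A)
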