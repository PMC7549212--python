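"""Dominant-marker (RAPD) band analysis: polymorphism classification,
Jaccard distances and UPGMA dendrograms.

Band calling from gels is out of scope; the module starts from the 0/1
presence/absence matrix. Shared absences are excluded from the Jaccard
coefficient (the standard convention for dominant markers). UPGMA uses the
classic size-weighted average linkage with merge height d/2 and a
deterministic smallest-index tie-break, and its output trees are ultrametric
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "BandClassification",
    "Dendrogram",
    "classify_bands",
    "jaccard_distance",
    "jaccard_distance_matrix",
    "upgma",
    "write_newick",
]


@dataclass(frozen=True)
class BandMatrix:
    """Individuals x bands presence/absence matrix with design labels.

    ``values`` is a DataFrame indexed by individual ID (e.g. C1..C30,
    I1..I30) with band IDs ``<primer>_<n>`` as columns; ``populations`` maps
    each individual to its population label and ``primers`` each band to its
    primer.
    """

    values: pd.DataFrame
    populations: pd.Series
    primers: Mapping[str, str]

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("band matrix entries must be 0/1")
        if not self.values.index.equals(self.populations.index):
            raise ValueError("populations must be indexed by individual ID")
        missing = set(self.values.columns) - set(self.primers)
        if missing:
            raise ValueError(f"bands without a primer label: {sorted(missing)}")

    @property
    def individuals(self) -> List[str]:
        return list(self.values.index)

    @property
    def bands(self) -> List[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class BandClassification:
    """Per-band monomorphic/polymorphic status per group and overall."""

    per_group: pd.DataFrame          # bands x groups, entries {"monomorphic","polymorphic"}
    overall: pd.Series               # bands -> status
    per_primer_polymorphic: Dict[str, int]

    @property
    def n_polymorphic(self) -> int:
        return int((self.overall == "polymorphic").sum())


def classify_bands(matrix: BandMatrix,
                   grouping: Optional[pd.Series] = None) -> BandClassification:
    """Classify each band as monomorphic or polymorphic.

    A band is monomorphic within a group iff its frequency there is exactly
    0 or 1 (it "commonly appears", or is commonly absent, in that group).
    A band is polymorphic overall iff it is polymorphic in at least one
    group, or fixed at different states in different groups.
    """
    groups = matrix.populations if grouping is None else grouping
    labels = sorted(groups.unique())
    per_group = {}
    fixed_state: Dict[str, Dict[str, float]] = {}
    for g in labels:
        sub = matrix.values.loc[groups == g]
        if sub.empty:
            raise ValueError(f"group {g!r} has no individuals")
        freq = sub.mean(axis=0)
        per_group[g] = np.where((freq == 0) | (freq == 1),
                                "monomorphic", "polymorphic")
        fixed_state[g] = freq.to_dict()
    per_group_df = pd.DataFrame(per_group, index=matrix.values.columns)

    overall = []
    for band in matrix.values.columns:
        statuses = per_group_df.loc[band]
        if (statuses == "polymorphic").any():
            overall.append("polymorphic")
        else:
            fixed = {fixed_state[g][band] for g in labels}
            overall.append("polymorphic" if len(fixed) > 1 else "monomorphic")
    overall_s = pd.Series(overall, index=matrix.values.columns)

    per_primer: Dict[str, int] = {}
    for band, status in overall_s.items():
        primer = matrix.primers[band]
        per_primer.setdefault(primer, 0)
        if status == "polymorphic":
            per_primer[primer] += 1
    return BandClassification(per_group_df, overall_s, per_primer)


def jaccard_distance(v1: Sequence[int], v2: Sequence[int]) -> float:
    """Jaccard distance 1 - a/(a+b+c) on binary band vectors.

    a = shared presences, b/c = presences unique to either vector; shared
    absences are ignored. Undefined (raises) when both vectors are all-zero.
    """
    x = np.asarray(v1, dtype=bool)
    y = np.asarray(v2, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    union = np.logical_or(x, y).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined for two all-zero vectors")
    a = np.logical_and(x, y).sum()
    return 1.0 - a / union


def jaccard_distance_matrix(matrix: BandMatrix) -> pd.DataFrame:
    """All-pairs Jaccard distances between individuals."""
    ids = matrix.individuals
    arr = matrix.values.to_numpy(dtype=bool)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(arr[i], arr[j])
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class _Node:
    height: float
    leaf: Optional[str] = None
    children: Tuple["_Node", "_Node"] = None  # type: ignore[assignment]

    def leaves(self) -> List[str]:
        if self.leaf is not None:
            return [self.leaf]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    """Ultrametric merge tree over individuals.

    ``merges`` follows the scipy linkage convention: row k merges clusters
    ``merges[k, 0]`` and ``merges[k, 1]`` (ids < n are leaves) at cophenetic
    distance ``merges[k, 2]`` (= 2 x node height) into cluster n + k with
    ``merges[k, 3]`` members.
    """

    labels: List[str]
    merges: np.ndarray
    root: _Node = field(repr=False)

    @property
    def leaf_order(self) -> List[str]:
        return self.root.leaves()

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2 x height of the joining node)."""
        n = len(self.labels)
        coph = np.zeros((n, n))
        members: Dict[int, List[int]] = {i: [i] for i in range(n)}
        for k, (a, b, dist, _size) in enumerate(self.merges):
            left, right = members.pop(int(a)), members.pop(int(b))
            for i in left:
                for j in right:
                    coph[i, j] = coph[j, i] = dist
            members[n + k] = left + right
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)


def upgma(distance_matrix: pd.DataFrame) -> Dendrogram:
    """Classic UPGMA agglomeration of a symmetric distance matrix.

    The closest pair merges first; distances to the new cluster are the
    size-weighted arithmetic mean of the members' distances; the merge is
    placed at height d/2. Exact ties are broken by the smallest (row, col)
    cluster-index pair, so the result is deterministic.
    """
    labels = list(distance_matrix.index)
    d = distance_matrix.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("distance matrix must be non-negative, zero-diagonal")
    n = len(labels)
    if n == 1:
        root = _Node(height=0.0, leaf=labels[0])
        return Dendrogram(labels, np.empty((0, 4)), root)

    dist: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    size = {i: 1 for i in range(n)}
    nodes: Dict[int, _Node] = {i: _Node(0.0, leaf=labels[i]) for i in range(n)}
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    next_id = n
    for k in range(n - 1):
        best = min(((dist[(min(i, j), max(i, j))], i, j)
                    for idx, i in enumerate(active)
                    for j in active[idx + 1:]),
                   key=lambda t: (t[0], min(t[1], t[2]), max(t[1], t[2])))
        dmin, a, b = best
        a, b = min(a, b), max(a, b)
        new = _Node(height=dmin / 2.0, children=(nodes[a], nodes[b]))
        nodes[next_id] = new
        merges[k] = (a, b, dmin, size[a] + size[b])
        for c in active:
            if c in (a, b):
                continue
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            dnew = (size[a] * da + size[b] * db) / (size[a] + size[b])
            dist[(min(c, next_id), max(c, next_id))] = dnew
        size[next_id] = size[a] + size[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(labels, merges, nodes[next_id - 1])


def _newick(node: _Node, parent_height: float) -> str:
    length = parent_height - node.height
    if node.leaf is not None:
        return f"{node.leaf}:{length:g}"
    inner = ",".join(_newick(c, node.height) for c in node.children)
    return f"({inner}):{length:g}"


def write_newick(dendrogram: Dendrogram) -> str:
    """Serialise the dendrogram as a Newick string with branch lengths."""
    root = dendrogram.root
    if root.leaf is not None:
        return f"{root.leaf};"
    inner = ",".join(_newick(c, root.height) for c in root.children)
    return f"({inner});"
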