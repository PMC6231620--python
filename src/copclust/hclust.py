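"""Agglomerative clustering on a precomputed dissimilarity matrix.

Clusters are merged bottom-up: at each step the pair of clusters at minimal
inter-cluster distance is merged, and distances from the new cluster to all
others are updated in one pass with the Lance-Williams recurrence

    d(k, i∪j) = α_i d(k,i) + α_j d(k,j) + β d(i,j) + γ |d(k,i) − d(k,j)|,

whose coefficients encode the linkage.  The Ward variant here applies the
classical Ward coefficients directly to the supplied dissimilarities (the
convention R calls ``ward.D``), which is the natural extension when the input
is a copula distance rather than a squared Euclidean one; a squared-input
variant is available via ``square_input=True``.

Merge ties are broken deterministically: among pairs attaining the minimum,
the first in row-major order over the current cluster list (i.e. the
lexicographically smallest index pair) is merged.

The number of clusters is chosen by maximising the average silhouette width
over a candidate range, computed from the same dissimilarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix, InvalidInputError

__all__ = [
    "MergeTree",
    "ClusterLabels",
    "SilhouetteReport",
    "LINKAGES",
    "agglomerate",
    "agglomerate_naive",
    "cut_tree",
    "silhouette",
    "select_n_clusters",
    "to_newick",
]

LINKAGES = ("single", "complete", "average", "centroid", "ward")


@dataclass(frozen=True)
class MergeTree:
    """Agglomeration history: n−1 merges in scipy-style node numbering.

    Leaves are nodes 0..n−1; the cluster created by merge ``k`` (0-based) is
    node ``n + k``.  Each merge record is (left, right, height, size).
    """

    n: int
    merges: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n - 1:
            raise InvalidInputError(f"expected {self.n - 1} merges, got {len(self.merges)}")
        object.__setattr__(self, "merges", tuple(tuple(m) for m in self.merges))

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


@dataclass(frozen=True)
class ClusterLabels:
    """Assignment of every series id to a cluster index 1..J."""

    labels: dict[str, int]
    J: int

    def __post_init__(self) -> None:
        occupied = set(self.labels.values())
        if occupied != set(range(1, self.J + 1)):
            raise InvalidInputError(f"cluster indices must occupy 1..{self.J}, got {sorted(occupied)}")

    def groups(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.J)]
        for sid, c in self.labels.items():
            out[c - 1].add(sid)
        return out


@dataclass(frozen=True)
class SilhouetteReport:
    """Per-series silhouette widths s(i) and their average Sil(J)."""

    widths: dict[str, float]
    average: float
    J: int


_LW_FIXED = {
    # alpha_i, alpha_j, beta, gamma for coefficients that do not depend on sizes
    "single": (0.5, 0.5, 0.0, -0.5),
    "complete": (0.5, 0.5, 0.0, 0.5),
}


def _lw_coefficients(linkage: str, ni: int, nj: int, nk: int):
    if linkage in _LW_FIXED:
        return _LW_FIXED[linkage]
    if linkage == "average":
        return ni / (ni + nj), nj / (ni + nj), 0.0, 0.0
    if linkage == "centroid":
        s = ni + nj
        return ni / s, nj / s, -ni * nj / s**2, 0.0
    if linkage == "ward":
        s = ni + nj + nk
        return (ni + nk) / s, (nj + nk) / s, -nk / s, 0.0
    raise InvalidInputError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")


def _argmin_pair(D: np.ndarray) -> tuple[int, int]:
    """First (row-major) off-diagonal minimum of the active matrix."""
    M = D.copy()
    np.fill_diagonal(M, np.inf)
    i, j = np.unravel_index(int(np.argmin(M)), M.shape)
    return (i, j) if i < j else (j, i)


def agglomerate(D: DistanceMatrix, linkage: str = "ward",
                square_input: bool = False) -> MergeTree:
    """Build the merge tree by Lance-Williams recursion.

    The original distance matrix is consulted only once, to initialise the
    working matrix; all subsequent inter-cluster distances come from the
    recurrence.  With ``square_input`` the recursion runs on squared
    dissimilarities and reports the square roots of the resulting heights
    (the ``ward.D2`` dialect).
    """
    if linkage not in LINKAGES:
        raise InvalidInputError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = D.n
    if n < 2:
        raise InvalidInputError("need at least 2 series to cluster")
    W = D.values.astype(float).copy()
    if square_input:
        W = W**2

    nodes = list(range(n))           # active cluster node ids, in creation order
    sizes = [1] * n
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        i, j = _argmin_pair(W)
        height = W[i, j]
        size = sizes[i] + sizes[j]
        merges.append((nodes[i], nodes[j],
                       float(np.sqrt(height)) if square_input else float(height), size))
        # Lance-Williams update of distances to the merged cluster, written
        # into slot i; slot j is removed.
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        for k in keep:
            ai, aj, beta, gamma = _lw_coefficients(linkage, sizes[i], sizes[j], sizes[k])
            W[i, k] = W[k, i] = (ai * W[k, i] + aj * W[k, j] + beta * W[i, j]
                                 + gamma * abs(W[k, i] - W[k, j]))
        sel = keep[:]
        sel.insert(sum(k < i for k in keep), i)  # merged cluster stays at slot i
        W = W[np.ix_(sel, sel)]
        nodes = [nodes[k] if k != i else n + step for k in sel]
        sizes = [sizes[k] if k != i else size for k in sel]
    return MergeTree(n=n, merges=tuple(merges))


def agglomerate_naive(D: DistanceMatrix, linkage: str = "single") -> MergeTree:
    """Reference agglomeration that recomputes every inter-cluster distance
    from the original matrix at every step (no recurrence).

    Supports the linkages with a direct set-level definition (single=min,
    complete=max, average=mean over all cross pairs).  Exists to validate
    :func:`agglomerate`; quadratic-times-steps cost.
    """
    defs = {"single": np.min, "complete": np.max, "average": np.mean}
    if linkage not in defs:
        raise InvalidInputError(f"naive oracle supports {sorted(defs)}, not {linkage!r}")
    reduce = defs[linkage]
    n = D.n
    base = D.values
    members: list[list[int]] = [[i] for i in range(n)]
    nodes = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        m = len(nodes)
        W = np.full((m, m), np.inf)
        for a in range(m):
            for b in range(a + 1, m):
                W[a, b] = W[b, a] = reduce(base[np.ix_(members[a], members[b])])
        i, j = _argmin_pair(W)
        merges.append((nodes[i], nodes[j], float(W[i, j]),
                       len(members[i]) + len(members[j])))
        members[i] = members[i] + members[j]
        nodes[i] = n + step
        del members[j], nodes[j]
    return MergeTree(n=n, merges=tuple(merges))


def cut_tree(tree: MergeTree, J: int, ids) -> ClusterLabels:
    """Partition into J clusters by undoing the last J−1 merges.

    Cluster indices are renumbered 1..J in order of first appearance of a
    member series.
    """
    n = tree.n
    if not 1 <= J <= n:
        raise InvalidInputError(f"J={J} out of range 1..{n}")
    ids = list(ids)
    if len(ids) != n:
        raise InvalidInputError("ids length must equal number of leaves")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in range(n - J):
        left, right, _, _ = tree.merges[k]
        new = n + k
        parent[find(left)] = new
        parent[find(right)] = new

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf, sid in enumerate(ids):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[sid] = roots[r]
    return ClusterLabels(labels=labels, J=J)


def silhouette(D: DistanceMatrix, labels: ClusterLabels) -> SilhouetteReport:
    """Silhouette widths s(i) = (b(i) − a(i)) / max(a(i), b(i)).

    a(i) is the mean distance to the other members of i's cluster, b(i) the
    smallest mean distance to any other cluster.  Singleton clusters get
    s(i) = 0 (a(i) is undefined there).
    """
    if labels.J < 2:
        raise InvalidInputError("silhouette needs at least 2 clusters")
    if set(labels.labels) != set(D.ids):
        raise InvalidInputError("labels do not match the distance matrix ids")
    lab = np.array([labels.labels[sid] for sid in D.ids])
    widths: dict[str, float] = {}
    for i, sid in enumerate(D.ids):
        own = (lab == lab[i])
        own[i] = False
        if not own.any():
            widths[sid] = 0.0
            continue
        a = D.values[i, own].mean()
        b = min(D.values[i, lab == c].mean() for c in range(1, labels.J + 1) if c != lab[i])
        denom = max(a, b)
        widths[sid] = 0.0 if denom == 0.0 else float((b - a) / denom)
    avg = float(np.mean(list(widths.values())))
    return SilhouetteReport(widths=widths, average=avg, J=labels.J)


def select_n_clusters(D: DistanceMatrix, tree: MergeTree,
                      J_min: int = 2, J_max: int | None = None
                      ) -> tuple[int, dict[int, float]]:
    """Pick J* maximising the average silhouette Sil(J) over J_min..J_max.

    Default range is 2..min(10, n−1).  Ties go to the smallest J.
    Returns (J*, {J: Sil(J)}).
    """
    n = D.n
    if J_max is None:
        J_max = min(10, n - 1)
    if not 2 <= J_min <= J_max <= n - 1:
        raise InvalidInputError(f"need 2 <= J_min <= J_max <= {n - 1}, got [{J_min}, {J_max}]")
    profile = {J: silhouette(D, cut_tree(tree, J, D.ids)).average
               for J in range(J_min, J_max + 1)}
    best = max(profile, key=lambda J: (profile[J], -J))
    return best, profile


def to_newick(tree: MergeTree, ids) -> str:
    """Serialise the dendrogram as a Newick string with branch lengths.

    A child's branch length is its parent's merge height minus its own height
    (leaves sit at height 0); height inversions (possible under centroid
    linkage) are floored at 0.
    """
    ids = list(ids)
    n = tree.n
    height = {k: 0.0 for k in range(n)}
    for k, (_, _, h, _) in enumerate(tree.merges):
        height[n + k] = h
    children = {n + k: (l, r) for k, (l, r, _, _) in enumerate(tree.merges)}

    def render(node: int, parent_h: float) -> str:
        branch = max(parent_h - height[node], 0.0)
        if node < n:
            return f"{ids[node]}:{branch:.10g}"
        l, r = children[node]
        return f"({render(l, height[node])},{render(r, height[node])}):{branch:.10g}"

    root = 2 * n - 2
    l, r = children[root]
    h = height[root]
    return f"({render(l, h)},{render(r, h)});"
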