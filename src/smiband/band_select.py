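"""Agglomerative band clustering and representative selection.

Bands are merged bottom-up in the dissimilarity space: start from B
singletons and repeatedly fuse the pair of clusters at minimal linkage
distance (average = mean of all cross-pair dissimilarities, single = min,
complete = max).  Cutting the resulting tree at ``k`` clusters and taking,
from each cluster, the band with the smallest total dissimilarity to its
fellow members — the member sharing the most information with the rest —
yields the selected subset.

The merge order is fully deterministic: among pairs whose linkage distance
ties at the minimum, the pair whose combined membership has the
lexicographically smallest ``(min member index, max member index)`` is
merged first.  Average-linkage distances are maintained as exact sums of
original cross-pair dissimilarities (divided by the pair count on demand),
which keeps tie detection stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .infometrics import DissimilarityMatrix, WeightFunction, pairwise_dissimilarity

__all__ = [
    "Merge",
    "Dendrogram",
    "ClusterAssignment",
    "BandSubset",
    "agglomerative_cluster",
    "cut_tree",
    "representative_bands",
    "select_bands",
]

LINKAGES = ("average", "single", "complete")

# relative tolerance used only to group floating-point-equal candidates
# when hunting the minimum linkage pair; heights themselves are exact
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: nodes ``a`` and ``b`` fuse at ``height``."""

    a: int
    b: int
    height: float
    size: int


@dataclass(frozen=True)
class Dendrogram:
    """Merge history over bands.

    Leaves are node ids ``0 .. B-1``; the merge at step ``t`` creates node
    ``B + t``.  There are exactly ``B - 1`` merges.
    """

    merges: tuple[Merge, ...]
    leaf_count: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.leaf_count - 1:
            raise ValueError("a dendrogram over B leaves must contain B-1 merges")
        used: set[int] = set()
        for t, m in enumerate(self.merges):
            for child in (m.a, m.b):
                if child in used:
                    raise ValueError(f"node {child} used as a child twice")
                if child >= self.leaf_count + t:
                    raise ValueError(f"merge {t} references not-yet-created node {child}")
                used.add(child)

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def to_newick(self, names: Sequence[str] | None = None) -> str:
        """Serialize as a Newick tree with merge heights as branch lengths."""
        B = self.leaf_count
        if names is None:
            names = [f"b{i}" for i in range(B)]
        label: dict[int, str] = {i: str(names[i]) for i in range(B)}
        birth: dict[int, float] = {i: 0.0 for i in range(B)}
        for t, m in enumerate(self.merges):
            node = B + t
            parts = []
            for child in (m.a, m.b):
                parts.append(f"{label[child]}:{m.height - birth[child]:.6g}")
            label[node] = "(" + ",".join(parts) + ")"
            birth[node] = m.height
        return label[B + len(self.merges) - 1] + ";"


@dataclass(frozen=True)
class ClusterAssignment:
    """Band index -> cluster id in ``0 .. k-1``; ids ordered by smallest member."""

    cluster_of: np.ndarray
    k: int

    def __post_init__(self) -> None:
        ids = np.unique(self.cluster_of)
        if len(ids) != self.k or ids.min() != 0 or ids.max() != self.k - 1:
            raise ValueError("cluster ids must be exactly 0..k-1, all nonempty")

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_of == cluster_id)


@dataclass(frozen=True)
class BandSubset:
    """The selected representative bands, sorted ascending."""

    indices: tuple[int, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("band indices must be distinct")
        if tuple(sorted(self.indices)) != tuple(self.indices):
            raise ValueError("band indices must be sorted ascending")

    def __len__(self) -> int:
        return len(self.indices)


def _as_matrix(D) -> np.ndarray:
    V = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.all(np.isfinite(V)):
        raise ValueError("dissimilarity matrix must be finite")
    if not np.array_equal(V, V.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if V.shape[0] < 2:
        raise ValueError("need at least 2 bands to cluster")
    return V


def agglomerative_cluster(D, linkage: str = "average") -> Dendrogram:
    """Agglomerate bands bottom-up under the chosen linkage.

    Accepts a :class:`~smiband.infometrics.DissimilarityMatrix` or a plain
    symmetric array.  Cluster-pair distances are maintained incrementally:
    for average linkage the *sum* of original cross-pair dissimilarities is
    propagated (``S(K, A+B) = S(K, A) + S(K, B)``) and divided by the pair
    count only when compared, so ties on rational values are detected
    exactly; single/complete propagate the min/max.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    V = _as_matrix(D)
    B = V.shape[0]
    n_nodes = 2 * B - 1

    # stat[i, j]: sum (average) or min/max (single/complete) of cross distances
    stat = np.full((n_nodes, n_nodes), np.nan)
    stat[:B, :B] = V
    size = np.zeros(n_nodes, dtype=np.int64)
    size[:B] = 1
    min_m = np.full(n_nodes, -1, dtype=np.int64)
    max_m = np.full(n_nodes, -1, dtype=np.int64)
    min_m[:B] = max_m[:B] = np.arange(B)

    active: list[int] = list(range(B))
    merges: list[Merge] = []

    for step in range(B - 1):
        ids = np.array(active)
        sub = stat[np.ix_(ids, ids)]
        if linkage == "average":
            sub = sub / np.outer(size[ids], size[ids])
        np.fill_diagonal(sub, np.inf)
        m = sub.min()
        tol = _TIE_RTOL * max(1.0, abs(m))
        cand_i, cand_j = np.nonzero(sub <= m + tol)
        best = None
        best_key = None
        for ci, cj in zip(cand_i, cand_j):
            if ci >= cj:
                continue
            a, b = ids[ci], ids[cj]
            key = (
                min(min_m[a], min_m[b]),
                max(max_m[a], max_m[b]),
                min(min_m[a], min_m[b]),
                max(min_m[a], min_m[b]),
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (a, b, float(sub[ci, cj]))
        a, b, height = best  # type: ignore[misc]
        new = B + step
        size[new] = size[a] + size[b]
        min_m[new] = min(min_m[a], min_m[b])
        max_m[new] = max(max_m[a], max_m[b])
        for kid in active:
            if kid in (a, b):
                continue
            if linkage == "average":
                s = stat[kid, a] + stat[kid, b]
            elif linkage == "single":
                s = min(stat[kid, a], stat[kid, b])
            else:
                s = max(stat[kid, a], stat[kid, b])
            stat[kid, new] = stat[new, kid] = s
        active.remove(a)
        active.remove(b)
        active.append(new)
        merges.append(Merge(a=min(a, b), b=max(a, b), height=height, size=int(size[new])))

    return Dendrogram(merges=tuple(merges), leaf_count=B)


def cut_tree(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Apply only the first ``B - k`` merges, leaving exactly ``k`` clusters.

    Cluster ids are assigned in order of each cluster's smallest band index.
    """
    B = dend.leaf_count
    if not 1 <= k <= B:
        raise ValueError(f"k must be in [1, {B}], got {k}")
    comp: dict[int, list[int]] = {i: [i] for i in range(B)}
    for t in range(B - k):
        m = dend.merges[t]
        comp[B + t] = comp.pop(m.a) + comp.pop(m.b)
    clusters = sorted(comp.values(), key=min)
    cluster_of = np.empty(B, dtype=np.int64)
    for cid, members in enumerate(clusters):
        cluster_of[members] = cid
    return ClusterAssignment(cluster_of=cluster_of, k=k)


def representative_bands(assign: ClusterAssignment, D) -> BandSubset:
    """Pick, per cluster, the band minimising total dissimilarity to the rest.

    That band shares the most information with its fellow cluster members.
    Singletons represent themselves; ties go to the lowest band index.
    """
    V = _as_matrix(D)
    if len(assign.cluster_of) != V.shape[0]:
        raise ValueError("assignment and matrix cover different band counts")
    reps = []
    for cid in range(assign.k):
        members = assign.members(cid)
        if len(members) == 1:
            reps.append(int(members[0]))
            continue
        sums = V[np.ix_(members, members)].sum(axis=1)
        reps.append(int(members[int(np.argmin(sums))]))  # argmin -> first = lowest index
    return BandSubset(indices=tuple(sorted(reps)))


def select_bands(
    cube,
    k: int,
    metric: str = "smi",
    bins: int | None = None,
    linkage: str = "average",
    weight: WeightFunction | None = None,
    global_range: bool = False,
) -> BandSubset:
    """Full pipeline: dissimilarity matrix -> dendrogram -> cut -> representatives.

    Deterministic given the cube and configuration; provenance (metric,
    linkage, bins, k) is recorded on the returned subset.
    """
    if not 1 <= k <= cube.band_count:
        raise ValueError(f"k must be in [1, {cube.band_count}], got {k}")
    dm = pairwise_dissimilarity(
        cube, metric=metric, bins=bins, weight=weight, global_range=global_range
    )
    dend = agglomerative_cluster(dm, linkage=linkage)
    assign = cut_tree(dend, k)
    subset = representative_bands(assign, dm)
    return BandSubset(
        indices=subset.indices,
        provenance={
            "metric": dm.metric_name,
            "linkage": linkage,
            "bins": dm.bins,
            "k": k,
        },
    )
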