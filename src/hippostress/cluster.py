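"""UPGMA clustering of fold-change profiles.

Similarity between two genes is the absolute centered correlation
(|Pearson r| of mean-centered profiles), so anti-correlated expression
patterns count as similar.  Agglomeration runs on the distance
d = 1 - s with true UPGMA linkage: the distance between two clusters
is the arithmetic mean over all cross-pairs of original items
(size-weighted Lance-Williams update).  Clusters are maximal subtrees
whose internal merge similarities all exceed ``r_main`` (default
0.55, strict); subclusters are maximal subtrees with merges at or
above ``r_sub`` (default 0.75, inclusive) containing at least two
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "absolute_centered_correlation",
    "similarity_matrix",
    "upgma",
    "cut_clusters",
    "label_clusters",
]


def absolute_centered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson correlation| of the two mean-centered vectors, in [0, 1].

    Vectors must have equal length >= 3 and must not be constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("similarity undefined for a constant vector")
    return float(min(abs(xc @ yc) / denom, 1.0))


@dataclass
class SimilarityMatrix:
    """Symmetric item x item similarity in [0, 1], unit diagonal."""

    ids: list[str]
    values: np.ndarray
    excluded: list[str] = field(default_factory=list)  # constant-profile items

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any((v < -1e-12) | (v > 1 + 1e-12)):
            raise ValueError("similarities must lie in [0, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, 0.0, 1.0)


def similarity_matrix(profiles: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise absolute centered correlation of the rows of ``profiles``.

    Rows with constant profiles have no defined correlation; they are
    excluded with a warning and reported on the result.
    """
    arr = profiles.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 0
    excluded = list(profiles.index[~keep])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} constant profile(s) from clustering",
                      RuntimeWarning, stacklevel=2)
    kept = arr[keep]
    if kept.shape[0] < 2:
        raise ValueError("need at least 2 non-constant profiles")
    sim = np.abs(np.corrcoef(kept))
    return SimilarityMatrix(list(profiles.index[keep]), np.clip(sim, 0.0, 1.0),
                            excluded=excluded)


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    Leaves are numbered 0..n-1 in the order of ``ids``; the k-th merge
    creates node n+k.  Each merge records (left node, right node,
    similarity at merge, resulting cluster size).
    """

    ids: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def leaves_under(self, node: int) -> list[int]:
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                left, right, _, _ = self.merges[v - n]
                stack.extend((left, right))
        return sorted(out)

    def cophenetic_similarity(self) -> np.ndarray:
        """Similarity at which each leaf pair is first joined."""
        n = self.n_leaves
        coph = np.ones((n, n))
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for k, (left, right, sim, _) in enumerate(self.merges):
            li, ri = members.pop(left), members.pop(right)
            for a in li:
                for b in ri:
                    coph[a, b] = coph[b, a] = sim
            members[n + k] = li + ri
        return coph

    def to_newick(self) -> str:
        """Newick serialization with branch lengths on the 1-s distance scale."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        label = {i: str(self.ids[i]).replace(" ", "_") for i in range(n)}
        for k, (left, right, sim, _) in enumerate(self.merges):
            h = 1.0 - sim
            node = n + k
            lt = f"{label[left]}:{max(h - height[left], 0.0):.6g}"
            rt = f"{label[right]}:{max(h - height[right], 0.0):.6g}"
            label[node] = f"({lt},{rt})"
            height[node] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return label[root] + ";"


def upgma(sim: SimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomeration on d = 1 - s.

    At each step the pair of active clusters with the smallest distance
    merges; ties break on the smallest (row, column) position in the
    current cluster ordering (creation order: leaves first, then new
    nodes).  The distance from a merged cluster to any other is the
    size-weighted mean of the two parts (equals the mean over all
    cross-pairs of original items).
    """
    n = len(sim.ids)
    if n < 2:
        raise ValueError("need at least 2 items")
    dist = 1.0 - sim.values.astype(float)
    active: list[int] = list(range(n))  # node ids in creation order
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]
    size = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                u, v = active[ai], active[aj]
                key = (u, v) if u < v else (v, u)
                dd = d[key]
                if best is None or dd < best[0]:
                    best = (dd, (ai, aj), (u, v))
                # ties break on the smallest (row, col) position, which the
                # scan order already visits first, so no action needed
        dd, (ai, aj), (u, v) = best
        new_size = size[u] + size[v]
        merges.append((u, v, 1.0 - dd, new_size))
        # Lance-Williams size-weighted update = mean over original cross-pairs
        for w in active:
            if w in (u, v):
                continue
            ku = (u, w) if u < w else (w, u)
            kv = (v, w) if v < w else (w, v)
            dnew = (size[u] * d[ku] + size[v] * d[kv]) / new_size
            key = (w, next_node)
            d[key] = dnew
        size[next_node] = new_size
        active = [w for w in active if w not in (u, v)] + [next_node]
        next_node += 1
    return Dendrogram(list(sim.ids), merges)


@dataclass
class ClusterAssignment:
    """Gene -> cluster (numeric label) and optional subcluster ('7a')."""

    assignment: pd.DataFrame  # index gene; columns: cluster, subcluster
    r_main: float = 0.55
    r_sub: float = 0.75

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment["cluster"] == cluster])

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.assignment["cluster"].unique())


def _maximal_subtrees(dend: Dendrogram, root_nodes: list[int], keep) -> list[list[int]]:
    """Maximal subtrees (within the given roots) whose internal merges all
    satisfy ``keep(similarity)``; returns leaf-id groups."""
    n = dend.n_leaves
    pure: dict[int, bool] = {}

    def is_pure(node: int) -> bool:
        if node in pure:
            return pure[node]
        if node < n:
            pure[node] = True
        else:
            left, right, sim, _ = dend.merges[node - n]
            pure[node] = keep(sim) and is_pure(left) and is_pure(right)
        return pure[node]

    groups: list[list[int]] = []

    def collect(node: int) -> None:
        if is_pure(node):
            groups.append(dend.leaves_under(node))
        else:
            left, right, _, _ = dend.merges[node - n]
            collect(left)
            collect(right)

    for root in root_nodes:
        collect(root)
    return groups


def cut_clusters(dend: Dendrogram, r_main: float = 0.55, r_sub: float = 0.75) -> ClusterAssignment:
    """Threshold cuts of the dendrogram.

    Clusters: maximal subtrees all of whose internal merge similarities
    are strictly greater than ``r_main`` (singletons allowed).
    Subclusters: within each cluster, maximal subtrees with merges at
    or above ``r_sub`` containing >= 2 genes.
    """
    n = dend.n_leaves
    root = n + len(dend.merges) - 1 if dend.merges else 0
    clusters = _maximal_subtrees(dend, [root], lambda s: s > r_main)

    # map each cluster's leaf set back to its subtree root for the sub-cut
    leafset_to_node: dict[frozenset, int] = {frozenset([i]): i for i in range(n)}
    for k, (left, right, _, _) in enumerate(dend.merges):
        leafset_to_node[frozenset(dend.leaves_under(n + k))] = n + k

    records = {}
    for ci, leaves in enumerate(clusters):
        node = leafset_to_node[frozenset(leaves)]
        subs = [g for g in _maximal_subtrees(dend, [node], lambda s: s >= r_sub)
                if len(g) >= 2]
        sub_of = {}
        for si, sub_leaves in enumerate(subs):
            for leaf in sub_leaves:
                sub_of[leaf] = si
        for leaf in leaves:
            records[dend.ids[leaf]] = {"raw_cluster": ci, "raw_subcluster": sub_of.get(leaf, -1)}
    df = pd.DataFrame.from_dict(records, orient="index")
    assignment = label_clusters(df)
    return ClusterAssignment(assignment, r_main=r_main, r_sub=r_sub)


def label_clusters(raw: pd.DataFrame) -> pd.DataFrame:
    """Number clusters 1..K by descending size, ties by the alphabetically
    first member; letter subclusters a, b, ... by descending size with
    the same tie-break."""

    def order_key(genes: list[str]) -> tuple[int, str]:
        return (-len(genes), min(str(g) for g in genes))

    out = pd.DataFrame(index=raw.index, columns=["cluster", "subcluster"])
    cluster_groups = sorted(
        ((cid, list(idx)) for cid, idx in raw.groupby("raw_cluster").groups.items()),
        key=lambda kv: order_key(kv[1]),
    )
    for new_label, (cid, genes) in enumerate(cluster_groups, start=1):
        sub = raw.loc[genes]
        out.loc[genes, "cluster"] = new_label
        sub_groups = sorted(
            ((sid, list(idx)) for sid, idx in sub.groupby("raw_subcluster").groups.items()
             if sid != -1),
            key=lambda kv: order_key(kv[1]),
        )
        out.loc[genes, "subcluster"] = ""
        for si, (sid, sgenes) in enumerate(sub_groups):
            out.loc[sgenes, "subcluster"] = f"{new_label}{chr(ord('a') + si)}"
    out["cluster"] = out["cluster"].astype(int)
    return out
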