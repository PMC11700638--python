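"""Two-stage WPGMA hierarchical clustering of emotions on cosine distances.

WPGMA ("weighted average" linkage, MATLAB's ``'weighted'`` method) merges the
closest pair of clusters at each step and updates the distance of the merged
cluster to every other as the simple mean of the two constituent distances:
``d(k, i∪j) = (d(k,i) + d(k,j)) / 2``.  Ties are broken deterministically by
the smallest ``(index_a, index_b)`` cluster-id pair.  Clusters are read off
the tree by cutting at a fraction (default 70%) of the maximum merge height,
counting only merges strictly below the threshold.

The two-stage analysis clusters category-mean vectors first, then the member
words of each category independently, with the same distance, linkage and cut
fraction throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping

import numpy as np

from .embeddings import cosine_similarity


@dataclass
class DistanceMatrix:
    """Pairwise cosine distances d = 1 - cosine, condensed upper-triangle."""

    ids: list[str]
    condensed: np.ndarray

    def full(self) -> np.ndarray:
        n = len(self.ids)
        out = np.zeros((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = self.condensed[k]
                k += 1
        return out


@dataclass
class LinkageTree:
    """Merge history in the standard linkage convention: row t merges
    clusters ``a`` and ``b`` (original items are 0..n-1, merged clusters get
    ids n, n+1, ...) at ``height`` into a cluster of ``size`` leaves."""

    ids: list[str]
    merges: np.ndarray  # (n-1, 4): a, b, height, size
    method: str = "wpgma"

    @property
    def n_items(self) -> int:
        return len(self.ids)


def distance_matrix(vectors: Mapping[str, np.ndarray]) -> DistanceMatrix:
    """Cosine distance 1 - cos for every pair; zero vectors are refused."""
    ids = list(vectors)
    if len(ids) < 2:
        raise ValueError("need at least 2 vectors")
    mat = [np.asarray(vectors[i], dtype=np.float64) for i in ids]
    for name, v in zip(ids, mat):
        if np.linalg.norm(v) == 0.0:
            raise ValueError(f"zero vector for id {name!r}")
    cond = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            cond.append(1.0 - cosine_similarity(mat[i], mat[j]))
    return DistanceMatrix(ids=ids, condensed=np.array(cond))


def wpgma(dist: DistanceMatrix) -> LinkageTree:
    """Agglomerate by the WPGMA recurrence with deterministic tie-breaking."""
    n = len(dist.ids)
    # cluster id -> leaf count; pairwise distances keyed by (min_id, max_id)
    sizes = {i: 1 for i in range(n)}
    d: dict[tuple[int, int], float] = {}
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist.condensed[k])
            k += 1
    merges = np.zeros((n - 1, 4))
    next_id = n
    active = set(range(n))
    for step in range(n - 1):
        best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), height = best
        new = next_id
        next_id += 1
        for other in active:
            if other in (a, b):
                continue
            da = d.pop((min(a, other), max(a, other)))
            db = d.pop((min(b, other), max(b, other)))
            d[(other, new)] = (da + db) / 2.0
        del d[(a, b)]
        active.discard(a)
        active.discard(b)
        active.add(new)
        sizes[new] = sizes[a] + sizes[b]
        merges[step] = (a, b, height, sizes[new])
    return LinkageTree(ids=list(dist.ids), merges=merges)


def _leaf_sets(tree: LinkageTree) -> dict[int, set[int]]:
    n = tree.n_items
    leaves = {i: {i} for i in range(n)}
    for t, (a, b, _h, _s) in enumerate(tree.merges):
        leaves[n + t] = leaves[int(a)] | leaves[int(b)]
    return leaves


def cut_tree(tree: LinkageTree, fraction: float = 0.7, inclusive: bool = False) -> np.ndarray:
    """Flat clusters at a threshold of ``fraction`` × the maximum merge height.

    Only merges with height strictly below the threshold join items (the
    MATLAB cutoff semantics); ``inclusive=True`` switches to ``<=``.  Labels
    are integers aligned with ``tree.ids``, numbered by each cluster's
    smallest member index.  ``fraction`` → 0 gives singletons; values above 1
    give a single cluster.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    n = tree.n_items
    if n == 1:
        return np.zeros(1, dtype=int)
    threshold = fraction * float(tree.merges[:, 2].max())
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    leaves = _leaf_sets(tree)
    for t, (a, b, h, _s) in enumerate(tree.merges):
        joins = h <= threshold if inclusive else h < threshold
        if joins:
            ra = find(min(leaves[int(a)]))
            rb = find(min(leaves[int(b)]))
            parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(i) for i in range(n)})
    root_label = {r: lbl for lbl, r in enumerate(roots)}
    return np.array([root_label[find(i)] for i in range(n)], dtype=int)


def leaf_order(tree: LinkageTree) -> list[int]:
    """Deterministic left-to-right dendrogram leaf order: at every internal
    node the child whose subtree holds the smaller minimum original index is
    drawn first."""
    n = tree.n_items
    leaves = _leaf_sets(tree)

    def order(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(tree.merges[node - n][0]), int(tree.merges[node - n][1])
        first, second = (a, b) if min(leaves[a]) <= min(leaves[b]) else (b, a)
        return order(first) + order(second)

    return order(2 * n - 2) if n > 1 else [0]


def to_newick(tree: LinkageTree) -> str:
    """Newick serialization with branch lengths from merge heights (each
    child branch spans half the height difference, UPGMA-style)."""
    n = tree.n_items
    heights = {i: 0.0 for i in range(n)}
    for t, row in enumerate(tree.merges):
        heights[n + t] = float(row[2])

    def name(i: int) -> str:
        label = tree.ids[i]
        return label.replace("(", "_").replace(")", "_").replace(",", "_").replace(":", "_").replace(";", "_").replace(" ", "_")

    def render(node: int) -> str:
        if node < n:
            return name(node)
        a, b = int(tree.merges[node - n][0]), int(tree.merges[node - n][1])
        h = heights[node]
        la = max(h - heights[a], 0.0) / 2.0
        lb = max(h - heights[b], 0.0) / 2.0
        return f"({render(a)}:{la:.10g},{render(b)}:{lb:.10g})"

    return render(2 * n - 2) + ";" if n > 1 else name(0) + ";"


def linkage_csv(tree: LinkageTree, sink: IO[str] | str | Path) -> None:
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            linkage_csv(tree, fh)
        return
    sink.write("cluster_a,cluster_b,height,size\n")
    for a, b, h, s in tree.merges:
        sink.write(f"{int(a)},{int(b)},{h!r},{int(s)}\n")


@dataclass
class TwoStageResult:
    """Stage-1 tree over category means plus independent per-category
    subtrees over member-word vectors."""

    top_tree: LinkageTree
    top_labels: np.ndarray
    top_order: list[int]
    subtrees: dict[str, LinkageTree | None] = field(default_factory=dict)
    sublabels: dict[str, np.ndarray] = field(default_factory=dict)
    suborders: dict[str, list[int]] = field(default_factory=dict)


def two_stage(
    category_vectors: Mapping[str, np.ndarray],
    per_emotion_vectors: Mapping[str, Mapping[str, np.ndarray]],
    fraction: float = 0.7,
) -> TwoStageResult:
    """Stage 1 clusters category means; stage 2 clusters each category's
    member words independently, with the same distance/linkage/cut."""
    top_tree = wpgma(distance_matrix(category_vectors))
    result = TwoStageResult(
        top_tree=top_tree,
        top_labels=cut_tree(top_tree, fraction=fraction),
        top_order=leaf_order(top_tree),
    )
    for cat, members in per_emotion_vectors.items():
        if len(members) < 2:
            result.subtrees[cat] = None
            result.sublabels[cat] = np.zeros(len(members), dtype=int)
            result.suborders[cat] = list(range(len(members)))
            continue
        sub = wpgma(distance_matrix(members))
        result.subtrees[cat] = sub
        result.sublabels[cat] = cut_tree(sub, fraction=fraction)
        result.suborders[cat] = leaf_order(sub)
    return result
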