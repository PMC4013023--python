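"""UPGMA agglomeration of dissimilarity matrices into dendrograms.

Merge heights are the raw average cross-pair dissimilarities (not halved), so
a node's height is directly comparable to printed cophenetic distances.  Ties
are broken deterministically by the lexicographically smallest label set, so
the tree is reproducible and independent of input label order — the study
fixture contains exact ties (identical occurrence vectors at distance zero).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MergeNode", "Dendrogram", "upgma", "cophenetic_height", "cophenetic_matrix"]


@dataclass(frozen=True)
class MergeNode:
    """One binary merge: children are leaf indices (< n_leaves) or node ids."""

    id: int
    left: int
    right: int
    height: float
    members: frozenset[str]
    left_members: frozenset[str]
    right_members: frozenset[str]


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree over labelled leaves.

    ``nodes`` are in merge order (root last) and number ``len(leaves) - 1``.
    Children are oriented so the earlier-formed (lower) subtree is ``left``;
    leaf order read off the tree left-to-right therefore puts groups that
    split off near the root first.
    """

    leaves: tuple[str, ...]
    nodes: tuple[MergeNode, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if len(self.leaves) > 1 and len(self.nodes) != len(self.leaves) - 1:
            raise ValueError(
                f"{len(self.leaves)} leaves require {len(self.leaves) - 1} internal "
                f"nodes, got {len(self.nodes)}"
            )
        prev = 0.0
        for node in self.nodes:
            if node.height < prev - 1e-12:
                raise ValueError("UPGMA merge heights must be non-decreasing")
            prev = max(prev, node.height)
            if node.left_members | node.right_members != node.members or (
                node.left_members & node.right_members
            ):
                raise ValueError("children must partition the parent member set")

    @property
    def root(self) -> MergeNode:
        return self.nodes[-1]

    def node_by_members(self, members: frozenset[str]) -> MergeNode:
        for node in self.nodes:
            if node.members == members:
                return node
        raise KeyError(f"no internal node with members {sorted(members)}")

    def leaf_order(self) -> tuple[str, ...]:
        """Leaves in dendrogram (left-to-right) order."""
        if not self.nodes:
            return self.leaves
        order: list[str] = []

        def walk(child_id: int) -> None:
            if child_id < len(self.leaves):
                order.append(self.leaves[child_id])
            else:
                node = self.nodes[child_id - len(self.leaves)]
                walk(node.left)
                walk(node.right)

        walk(self.root.id)
        return tuple(order)

    def merge_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": n.id,
                "left": ";".join(sorted(n.left_members)),
                "right": ";".join(sorted(n.right_members)),
                "height": n.height,
            }
            for n in self.nodes
        ]
        return pd.DataFrame(rows)


def _as_matrix(dissimilarity, labels):
    if isinstance(dissimilarity, pd.DataFrame):
        if labels is None:
            labels = tuple(str(c) for c in dissimilarity.columns)
        D = dissimilarity.to_numpy(dtype=float)
    else:
        D = np.asarray(dissimilarity, dtype=float)
        if labels is None:
            raise ValueError("labels are required with a bare array")
        labels = tuple(labels)
    k = len(labels)
    if D.shape != (k, k):
        raise ValueError(f"distance matrix shape {D.shape} does not match {k} labels")
    if not np.isfinite(D).all():
        raise ValueError("distances must be finite")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return D, labels


def upgma(dissimilarity, labels=None) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric dissimilarity matrix.

    Inter-cluster distance is the arithmetic mean of all cross-pair leaf
    distances; the merge height is that mean.  Equal-distance candidate
    merges are resolved in favour of the pair whose combined, sorted label
    tuple is lexicographically smallest.
    """
    D, labels = _as_matrix(dissimilarity, labels)
    k = len(labels)
    if k == 1:
        return Dendrogram(labels, ())

    # cluster id -> (member leaf indices, formation height)
    clusters: dict[int, tuple[frozenset[int], float]] = {
        i: (frozenset([i]), 0.0) for i in range(k)
    }
    # mean cross-pair distance between active clusters
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): D[i, j] for i, j in itertools.combinations(range(k), 2)
    }
    label_key = {
        cid: tuple(sorted(labels[m] for m in members)) for cid, (members, _) in clusters.items()
    }
    nodes: list[MergeNode] = []
    next_id = k
    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(sorted(clusters), 2):
            d = dist[frozenset((x, y))]
            key = tuple(sorted(label_key[x] + label_key[y]))
            if best is None or d < best[0] - 1e-15 or (
                abs(d - best[0]) <= 1e-15 and key < best[3]
            ):
                best = (d, x, y, key)
        d, x, y, _ = best
        # orient: earlier-formed child left; break formation ties by label
        (mx, hx), (my, hy) = clusters[x], clusters[y]
        if (hy, label_key[y]) < (hx, label_key[x]):
            x, y = y, x
            (mx, hx), (my, hy) = clusters[x], clusters[y]
        members = mx | my
        nodes.append(
            MergeNode(
                id=next_id,
                left=x,
                right=y,
                height=float(d),
                members=frozenset(labels[i] for i in members),
                left_members=frozenset(labels[i] for i in mx),
                right_members=frozenset(labels[i] for i in my),
            )
        )
        del clusters[x], clusters[y]
        for z, (mz, _) in clusters.items():
            dz = float(np.mean([D[i, j] for i in members for j in mz]))
            dist[frozenset((next_id, z))] = dz
        clusters[next_id] = (members, float(d))
        label_key[next_id] = tuple(sorted(labels[i] for i in members))
        next_id += 1
    return Dendrogram(labels, tuple(nodes))


def cophenetic_height(tree: Dendrogram, group_a, group_b) -> float:
    """Merge height of the node whose two children are exactly these groups."""
    a, b = frozenset(group_a), frozenset(group_b)
    for node in tree.nodes:
        if {node.left_members, node.right_members} == {a, b}:
            return node.height
    raise KeyError(
        f"no node joins {sorted(a)} with {sorted(b)}"
    )


def cophenetic_matrix(tree: Dendrogram) -> pd.DataFrame:
    """Pairwise cophenetic distances implied by the dendrogram."""
    labels = list(tree.leaves)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for node in tree.nodes:
        for la in node.left_members:
            for lb in node.right_members:
                out.loc[la, lb] = out.loc[lb, la] = node.height
    return out
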