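"""Distance-tree construction from number strings.

The tree-building distance is the *sum-difference*: the L1 (Manhattan)
distance between two number strings, summed over all aligned positions
(gap positions contribute ``|value - 0|``).  Trees are grown agglomeratively:
at each step the pair of current profiles with the smallest sum-difference is
merged, the merge distance is recorded on the new internal node, and the two
profiles are replaced by their position-wise arithmetic mean.  Merging is
unweighted — the two current profiles are averaged regardless of how many
leaves they already contain (WPGMA-like, not centroid-weighted).

For display the tree is laid out ultrametrically: a merge at distance d
places the new node at height d/2, and each child edge spans the height
difference (floored at 0 when merge distances are not monotone).  The raw
merge distance is kept verbatim on the node so labels can print it.

Trees can also be built from a precomputed distance matrix (e.g. 1 − mean
pairwise correlation); the same agglomerative loop applies, with merged
clusters at the arithmetic mean of their members' distances (WPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .properties import EncodedSequence

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "sum_difference",
    "pairwise_sumdiff_matrix",
    "build_sumdiff_tree",
    "build_tree_from_distances",
    "similarity_to_distance",
    "to_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: Tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(d < 0):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "\t" + "\t".join(repr(float(v)) for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceMatrix":
        """Parse labelled TSV; PHYLIP square format (leading count line)
        is also accepted."""
        lines = [ln for ln in text.splitlines() if ln.strip()]
        first = lines[0].split()
        if len(first) == 1 and first[0].isdigit():
            # PHYLIP square: count line, then label + n values per row
            rows = [ln.split() for ln in lines[1:]]
            labels = tuple(r[0] for r in rows)
            d = np.array([[float(v) for v in r[1:]] for r in rows])
        else:
            labels = tuple(lines[0].lstrip("\t").split("\t"))
            rows = [ln.split("\t") for ln in lines[1:]]
            d = np.array([[float(v) for v in r[1:]] for r in rows])
        return cls(labels, d)


@dataclass
class TreeNode:
    """A node of a rooted binary merge tree."""

    label: Optional[str] = None
    children: Tuple["TreeNode", "TreeNode"] | Tuple[()] = ()
    merge_distance: float = 0.0  # raw distance recorded at this merge
    height: float = 0.0  # ultrametric height (merge_distance / 2)
    edge_length: float = 0.0  # length of the edge to the parent
    merge_order: int = -1  # 0-based position of this merge in the sequence

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]


@dataclass
class PhyloTree:
    """A rooted binary merge tree with recorded merge distances."""

    root: TreeNode

    def leaf_labels(self) -> List[str]:
        return [lf.label for lf in self.root.leaves()]

    def merge_distances(self) -> List[float]:
        """Merge distances in merge order."""
        out = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            out.append((node.merge_order, node.merge_distance))
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return [d for _, d in sorted(out)]

    def newick(self) -> str:
        return to_newick(self)


def sum_difference(a: EncodedSequence | Sequence[float], b) -> float:
    """L1 distance between two number strings: Σ_i |a_i − b_i|."""
    av = a.as_array() if isinstance(a, EncodedSequence) else np.asarray(a, float)
    bv = b.as_array() if isinstance(b, EncodedSequence) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape[0]} vs {bv.shape[0]}")
    return float(np.abs(av - bv).sum())


def pairwise_sumdiff_matrix(encoded: Sequence[EncodedSequence]) -> DistanceMatrix:
    """All pairwise sum-differences between the given number strings."""
    labels = tuple(e.taxon for e in encoded)
    mat = np.array([e.values for e in encoded], dtype=float)
    d = np.abs(mat[:, None, :] - mat[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


def _assign_edge_lengths(node: TreeNode) -> None:
    for ch in node.children:
        ch.edge_length = max(node.height - ch.height, 0.0)
        _assign_edge_lengths(ch)


def build_sumdiff_tree(encoded: Sequence[EncodedSequence]) -> PhyloTree:
    """Agglomerate number strings by smallest sum-difference.

    Repeatedly merges the closest pair of current profiles, recording the
    sum-difference at the new node and replacing the pair with their
    position-wise mean, until one cluster remains.  Ties pick the lowest
    (row, column) pair in the current ordering.
    """
    encoded = list(encoded)
    if len(encoded) < 2:
        raise ValueError("need at least 2 sequences to build a tree")
    lengths = {len(e) for e in encoded}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {lengths}")
    props = {e.property_name for e in encoded}
    if len(props) > 1:
        raise ValueError(f"sequences mix properties: {sorted(props)}")

    profiles: List[np.ndarray] = [e.as_array() for e in encoded]
    nodes: List[TreeNode] = [TreeNode(label=e.taxon) for e in encoded]
    order = 0

    while len(nodes) > 1:
        best: Tuple[int, int] | None = None
        best_d = np.inf
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                dij = float(np.abs(profiles[i] - profiles[j]).sum())
                if dij < best_d:
                    best_d, best = dij, (i, j)
        i, j = best
        merged = TreeNode(
            children=(nodes[i], nodes[j]),
            merge_distance=best_d,
            height=best_d / 2.0,
            merge_order=order,
        )
        order += 1
        new_profile = (profiles[i] + profiles[j]) / 2.0
        for k in sorted((i, j), reverse=True):
            del nodes[k], profiles[k]
        nodes.append(merged)
        profiles.append(new_profile)

    _assign_edge_lengths(nodes[0])
    return PhyloTree(nodes[0])


def build_tree_from_distances(m: DistanceMatrix) -> PhyloTree:
    """WPGMA agglomeration of a precomputed distance matrix.

    Same loop as :func:`build_sumdiff_tree`, but with no profiles to
    average the merged cluster's distance to each other cluster is the
    arithmetic mean of its two members' distances.
    """
    n = len(m.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    d = m.d.copy()
    nodes: List[TreeNode] = [TreeNode(label=lab) for lab in m.labels]
    active = list(range(n))
    # grow d as merges append new rows/columns
    d = np.pad(d, ((0, n - 1), (0, n - 1)), constant_values=0.0)
    next_idx = n
    while len(active) > 1:
        best = None
        best_d = np.inf
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                if d[a, b] < best_d:
                    best_d, best = d[a, b], (ii, jj)
        ii, jj = best
        a, b = active[ii], active[jj]
        merged = TreeNode(
            children=(nodes[a], nodes[b]),
            merge_distance=best_d,
            height=best_d / 2.0,
            merge_order=next_idx - n,
        )
        nodes.append(merged)
        for k in active:
            if k not in (a, b):
                d[next_idx, k] = d[k, next_idx] = (d[a, k] + d[b, k]) / 2.0
        active = [k for k in active if k not in (a, b)] + [next_idx]
        next_idx += 1

    root = nodes[active[0]]
    _assign_edge_lengths(root)
    return PhyloTree(root)


def similarity_to_distance(r: float) -> float:
    """Map a correlation-like similarity in [−1, 1] to a distance 1 − r."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"similarity {r} outside [-1, 1]")
    return 1.0 - r


def to_newick(t: PhyloTree) -> str:
    """Serialize with branch lengths (ultrametric layout, see module docs)."""

    def fmt(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(fmt(ch, True) for ch in node.children) + ")"
        if with_length:
            s += f":{node.edge_length:g}"
        return s

    return fmt(t.root, False) + ";"
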