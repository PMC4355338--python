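"""Cladogram construction: identity -> distance -> UPGMA -> Newick.

The tree is a visualization of the identity matrix, not a model-based
phylogeny: distances are 100 - percent identity and clustering is UPGMA
(average linkage), so the result is ultrametric and every root-to-leaf
path has the same length. Equal-distance merges are resolved toward the
lexicographically smallest pair of cluster labels, making the topology
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import IdentityMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v


@dataclass
class CladeNode:
    """Node of a rooted binary ultrametric tree."""

    height: float
    label: str | None = None
    children: list["CladeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["CladeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class CladeTree:
    root: CladeNode

    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.root.leaves()]


def identity_to_distance(m: IdentityMatrix) -> DistanceMatrix:
    """d(i, j) = 100 - identity(i, j); the diagonal becomes 0."""
    d = 100.0 - np.asarray(m.identity, dtype=float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.labels), d)


def upgma(d: DistanceMatrix) -> CladeTree:
    """Average-linkage agglomeration; merge height is half the distance.

    Ties choose the pair whose sorted (representative-label) pair is
    lexicographically smallest; a cluster's representative is its smallest
    leaf label.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least two labels")
    nodes = {i: CladeNode(0.0, label=d.labels[i]) for i in range(n)}
    reps = {i: d.labels[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(nodes) > 1:
        best_key = None
        best = None
        for (i, j), dij in dist.items():
            key = (dij, tuple(sorted((reps[i], reps[j]))))
            if best_key is None or key < best_key:
                best_key, best = key, (i, j)
        i, j = best
        dij = dist[(i, j)]
        a, b = sorted((i, j), key=lambda k: reps[k])
        new = CladeNode(dij / 2.0, children=[nodes[a], nodes[b]])
        si, sj = sizes[i], sizes[j]
        new_dists = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dists[k] = (si * dik + sj * djk) / (si + sj)
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        del nodes[i], nodes[j], reps[i], reps[j], sizes[i], sizes[j]
        nodes[next_id] = new
        reps[next_id] = min(lf.label for lf in new.leaves())
        sizes[next_id] = si + sj
        for k, v in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    (root,) = nodes.values()
    return CladeTree(root)


def _fmt(x: float) -> str:
    s = f"{x:.10g}"
    if "." not in s and "e" not in s and "E" not in s:
        s += ".0"
    return s


def write_newick(t: CladeTree) -> str:
    """Serialize with branch lengths parent height - child height."""

    def render(node: CladeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.label
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{_fmt(parent_height - node.height)}"

    return "(" + ",".join(render(c, t.root.height) for c in t.root.children) + ");"


def ascii_tree(t: CladeTree) -> str:
    """Quick-look ASCII rendering (leaves left, root right not drawn to scale)."""
    lines: list[str] = []

    def walk(node: CladeNode, prefix: str, is_last: bool) -> None:
        connector = "`-- " if is_last else "|-- "
        tag = node.label if node.is_leaf else f"+ h={node.height:g}"
        lines.append(prefix + connector + tag)
        ext = "    " if is_last else "|   "
        for k, child in enumerate(node.children):
            walk(child, prefix + ext, k == len(node.children) - 1)

    lines.append(f"root h={t.root.height:g}")
    for k, child in enumerate(t.root.children):
        walk(child, "", k == len(t.root.children) - 1)
    return "\n".join(lines)
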