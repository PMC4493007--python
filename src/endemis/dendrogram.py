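"""Rooted dendrograms, UPGMA clustering and Newick round-tripping.

The tree type is shared by every downstream stage: UPGMA phenograms carry
ultrametric node heights (the average dissimilarity at which two clusters
merged), while consensus cladograms have height ``None`` on internal nodes
and may contain polytomies.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np

from .errors import ParseError, ValidationError

__all__ = ["Node", "Dendrogram", "upgma", "upgma_from_matrix", "to_newick", "from_newick"]


@dataclass(eq=False)
class Node:
    """A node of a rooted tree.

    Leaves have a ``label`` and height 0; internal nodes have ``children``
    (two for UPGMA output, possibly more for consensus trees) and a merge
    ``height`` which is ``None`` on cladograms.
    """

    label: Optional[str] = None
    height: Optional[float] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf({self.label!r})"
        return f"Node(h={self.height}, n_children={len(self.children)})"


class Dendrogram:
    """A rooted tree over uniquely labelled leaves."""

    def __init__(self, root: Node):
        self.root = root
        labels = [leaf.label for leaf in self.leaves()]
        if any(lab is None for lab in labels):
            raise ValidationError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        """Iterative post-order traversal (safe for very deep trees)."""
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        """Leaf labels in left-to-right tree order."""
        return [n.label for n in self.leaves()]

    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_labels())

    def clusters(self, include_trivial: bool = False) -> dict[frozenset, Node]:
        """Leaf sets of internal nodes (optionally also leaves and root)."""
        below: dict[int, frozenset] = {}
        out: dict[frozenset, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                cl = frozenset([node.label])
            else:
                cl = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = cl
            if include_trivial or (not node.is_leaf):
                out[cl] = node
        return out

    def node_leaf_sets(self) -> dict[int, frozenset]:
        """Map ``id(node)`` -> leaf set below the node, for every node."""
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        return below

    # -- comparisons -------------------------------------------------------
    def cophenetic(self, labels: Sequence[str]) -> np.ndarray:
        """Matrix of heights at which each leaf pair first co-occurs."""
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        out = np.zeros((n, n))
        below: dict[int, list[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = [node.label]
                continue
            groups = [below[id(c)] for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            out[idx[a], idx[b]] = out[idx[b], idx[a]] = node.height
            below[id(node)] = [l for g in groups for l in g]
        return out

    def equals(self, other: "Dendrogram", tol: float = 1e-9) -> bool:
        """Structural equality: same clusters, and same heights within tol."""
        mine = self.clusters(include_trivial=True)
        theirs = other.clusters(include_trivial=True)
        if set(mine) != set(theirs):
            return False
        for cl, node in mine.items():
            h1, h2 = node.height, theirs[cl].height
            if (h1 is None) != (h2 is None):
                return False
            if h1 is not None and abs(h1 - h2) > tol:
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dendrogram(n_leaves={len(self.leaves())})"


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma_from_matrix(labels: Sequence[str], values: np.ndarray) -> Dendrogram:
    """UPGMA (average linkage) on an arbitrary symmetric distance matrix.

    At every step the pair of clusters with the smallest average pairwise
    distance is merged; the new node's height is that average, and the
    distance from the merged cluster to any other follows the size-weighted
    (Lance-Williams) average update, equivalent to the arithmetic mean over
    all member pairs.

    Ties on the minimal distance are broken deterministically: the candidate
    pair whose lexicographically smallest member label is smallest wins,
    then the pair with the smaller second label.
    """
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if n < 2:
        raise ValidationError("UPGMA needs at least two labels")
    if values.shape != (n, n):
        raise ValidationError(f"matrix shape {values.shape} does not match {n} labels")
    if np.isnan(values).any():
        raise ValidationError("distance matrix contains NaN entries")
    if len(set(labels)) != n:
        raise ValidationError("duplicate labels")

    D = values.copy()
    np.fill_diagonal(D, np.inf)
    nodes: list[Optional[Node]] = [Node(label=lab, height=0.0) for lab in labels]
    sizes = np.ones(n)
    # smallest member label of each active cluster, for tie-breaking
    minlab: list[Optional[str]] = [str(lab) for lab in labels]
    active = list(range(n))

    while len(active) > 1:
        sub = D[np.ix_(active, active)]
        d_min = sub.min()
        ties = np.argwhere(np.isclose(sub, d_min, rtol=0.0, atol=0.0))
        best = None
        best_key = None
        for ti, tj in ties:
            if ti >= tj:
                continue
            i, j = active[ti], active[tj]
            key = tuple(sorted((minlab[i], minlab[j])))
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j)
        i, j = best
        if minlab[j] < minlab[i]:
            i, j = j, i  # canonical child order: smaller label first
        merged = Node(height=float(D[i, j]), children=[nodes[i], nodes[j]])
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * D[i, :] + nj * D[j, :]) / (ni + nj)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        nodes[i] = merged
        sizes[i] = ni + nj
        minlab[i] = min(minlab[i], minlab[j])
        nodes[j] = None
        active.remove(j)

    return Dendrogram(nodes[active[0]])


def upgma(d) -> Dendrogram:
    """UPGMA on a :class:`~endemis.dissimilarity.DissimilarityMatrix`."""
    return upgma_from_matrix(list(d.labels), d.values)


# ---------------------------------------------------------------------------
# Newick serialisation
# ---------------------------------------------------------------------------

def _needs_quoting(label: str) -> bool:
    special = set("()[]{}/\\,;:=*'\"`+<> ")
    return any(ch in special for ch in label)


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram) -> str:
    """Serialise a tree to Newick.

    Ultrametric heights are encoded as branch lengths (parent height minus
    child height); cladogram nodes (height ``None``) are written without
    branch lengths. Polytomies are preserved.
    """
    def write(node: Node, parent_height: Optional[float], out: io.StringIO) -> None:
        if node.is_leaf:
            out.write(_format_label(node.label))
            h = 0.0
        else:
            out.write("(")
            for k, child in enumerate(node.children):
                if k:
                    out.write(",")
                write(child, node.height, out)
            out.write(")")
            h = node.height
        if parent_height is not None and h is not None:
            out.write(f":{parent_height - h!r}")

    buf = io.StringIO()
    write(tree.root, None, buf)
    buf.write(";")
    return buf.getvalue()


def from_newick(text: str) -> Dendrogram:
    """Parse a Newick string into a :class:`Dendrogram`.

    Branch lengths, when present, are interpreted as ultrametric depth
    increments: leaf height is 0 and an internal node's height is a child's
    height plus the child's branch length. Trees without branch lengths
    parse as cladograms (heights ``None``).
    """
    if not text or not text.strip():
        raise ParseError("empty Newick string")
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> tuple[Node, Optional[float]]:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if label is None:
                raise ParseError("leaf without a label")
            return Node(label=str(label), height=0.0), 0.0
        children = []
        height: Optional[float] = None
        for dchild in dnode.child_nodes():
            cnode, cheight = convert(dchild)
            children.append(cnode)
            if dchild.edge.length is not None and cheight is not None:
                h = cheight + float(dchild.edge.length)
                height = h if height is None else max(height, h)
        return Node(height=height, children=children), height

    root, _ = convert(dt.seed_node)
    if root.is_leaf:
        raise ParseError("Newick describes a single leaf, not a tree")
    return Dendrogram(root)
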