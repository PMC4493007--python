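"""Strict and majority-rule consensus of dendrograms over the same leaves.

Consensus establishes a robustness hierarchy: clusters present in every
input tree (strict) are the most reliable, those present in a majority are
next, and leaves whose placement conflicts across all inputs surface as
unresolved. The consensus is computed on *rooted* clusters (leaf sets of
internal nodes), since the input phenograms are rooted by construction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .boc import BocPartition, assign_branch_orders, extract_boc_clusters
from .dendrogram import Dendrogram, Node
from .errors import AlignmentError, ValidationError

__all__ = ["ConsensusTree", "consensus_tree", "consensus_floristic_units"]


@dataclass
class ConsensusTree:
    """Consensus cladogram plus per-cluster support fractions."""

    tree: Dendrogram
    support: dict
    rule: str


def consensus_tree(trees: Sequence[Dendrogram], rule: str = "majority") -> ConsensusTree:
    """Strict (all trees) or majority (> 50% of trees) rooted consensus.

    The retained clusters of rooted trees sharing a leaf set are pairwise
    compatible (nested or disjoint), so they assemble into a unique tree,
    generally containing polytomies. Internal nodes carry no heights.
    """
    if rule not in ("strict", "majority"):
        raise ValidationError(f"unknown consensus rule {rule!r}")
    if len(trees) < 2:
        raise ValidationError("consensus needs at least two trees")
    leaf_set = trees[0].leaf_set()
    for t in trees[1:]:
        if t.leaf_set() != leaf_set:
            diff = t.leaf_set() ^ leaf_set
            raise AlignmentError(f"leaf-set mismatch: {sorted(diff)[:10]}")

    n = len(trees)
    counts: dict = {}
    for t in trees:
        for cl in set(t.clusters()):  # each cluster counted once per tree
            counts[cl] = counts.get(cl, 0) + 1
    threshold = n if rule == "strict" else n / 2.0
    if rule == "strict":
        retained = {cl: c / n for cl, c in counts.items() if c == n}
    else:
        retained = {cl: c / n for cl, c in counts.items() if c > threshold}
    retained[leaf_set] = retained.get(leaf_set, 1.0)  # root always present

    # sanity: retained clusters of rooted trees must be pairwise compatible
    kept = sorted(retained, key=len, reverse=True)
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            inter = kept[i] & kept[j]
            if inter and inter != kept[i] and inter != kept[j]:
                raise ValidationError(
                    "incompatible consensus clusters (should be impossible for "
                    "rooted inputs)")

    # assemble the unique tree containing exactly the retained clusters
    nodes = {cl: Node(children=[]) for cl in kept}
    # order clusters so children enumerate deterministically (by first leaf
    # in the first tree's leaf order)
    pos = {lab: i for i, lab in enumerate(trees[0].leaf_labels())}
    parent_of: dict = {}
    for cl in kept:
        if cl == leaf_set:
            continue
        best = None
        for cand in kept:
            if cl < cand and (best is None or len(cand) < len(best)):
                best = cand
        parent_of[cl] = best
    leaf_parent: dict = {}
    for lab in leaf_set:
        best = None
        for cand in kept:
            if lab in cand and (best is None or len(cand) < len(best)):
                best = cand
        leaf_parent[lab] = best

    children_sets: dict = {cl: [] for cl in kept}
    for cl, par in parent_of.items():
        children_sets[par].append(cl)
    for lab, par in leaf_parent.items():
        children_sets[par].append(lab)

    def min_pos(item) -> int:
        if isinstance(item, frozenset):
            return min(pos[l] for l in item)
        return pos[item]

    for cl in kept:
        members = sorted(children_sets[cl], key=min_pos)
        for member in members:
            if isinstance(member, frozenset):
                nodes[cl].children.append(nodes[member])
            else:
                nodes[cl].children.append(Node(label=member, height=0.0))

    tree = Dendrogram(nodes[leaf_set])
    return ConsensusTree(tree=tree, support=retained, rule=rule)


def consensus_floristic_units(majority: ConsensusTree, sub_level: int = 3,
                              coe_level: int = 4) -> tuple:
    """Two-level cut of the majority tree: (sub-unit, unit) partitions.

    The smaller clusters (modified third-order cut by default) are the
    sub-centres; the larger, nearly basal clusters (fourth order on the same
    modified ordering by default) are the centres. Every sub-centre nests
    inside a centre or falls into its unassigned set.
    """
    t = majority.tree
    if len(t.leaves()) < 2:
        raise ValidationError("consensus tree is trivial")
    labels = assign_branch_orders(t, "modified3")
    sub = extract_boc_clusters(t, labels, sub_level)
    coe = extract_boc_clusters(t, labels, coe_level)
    return sub, coe
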