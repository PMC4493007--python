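"""Centres of endemism: accounting, refinement, expansion and evaluation.

A floristic unit is a named set of cells at one of three levels (sub-centre,
centre, region). A taxon is *endemic* to a unit when its entire recorded
range - computed on the full occurrence matrix, single-cell taxa included -
lies inside the unit's cells. The operations here turn the raw candidate
clusters produced by branch-order cutting into defensible units:

1. ``refine_units``    - drop endemic-free units, prune cells that carry
   none of a unit's endemics, drop single-cell units supported only by
   single-cell taxa;
2. ``expand_units``    - greedily add unassigned cells wherever doing so
   completes additional ranges (maximisation of endemism), with documented
   tie-breaks;
3. ``create_units_from_orphan_taxa`` - found new units where whole ranges
   lie outside every existing unit;
4. ``bridge_to_biogeographic_regions`` - assign the remaining endemic-free
   cells to their compositionally closest unit, yielding spatially complete
   regions;
5. ``evaluate_analysis`` / ``rank_analyses`` - the four optimality criteria
   (endemics, taxa, units, cells) and rank-sum comparison across analyses;
6. ``recluster_units_to_brs`` - treat centres as pseudo-OGUs and recluster
   them (weighting, dissimilarity, UPGMA, consensus, standard second-order
   cut) into higher-level regions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Set

import networkx as nx
import numpy as np

from .boc import BocPartition, assign_branch_orders, extract_boc_clusters
from .consensus import consensus_tree
from .dendrogram import Dendrogram, upgma
from .dissimilarity import build_dissimilarity_matrix
from .errors import ConfigurationError, ValidationError
from .occurrence import CellGrid, OccurrenceMatrix
from .weighting import assign_weights

__all__ = [
    "FloristicUnit",
    "FloristicUnitSet",
    "EndemismTable",
    "AnalysisScore",
    "endemics_of_unit",
    "units_from_partition",
    "refine_units",
    "expand_units",
    "create_units_from_orphan_taxa",
    "bridge_to_biogeographic_regions",
    "evaluate_analysis",
    "rank_analyses",
    "recluster_units_to_brs",
    "endemism_table",
    "report_suspicious_units",
]

LEVELS = ("SubCoE", "CoE", "BR")


@dataclass
class FloristicUnit:
    cells: Set[str]
    level: str = "CoE"
    parent: Optional[str] = None


@dataclass
class FloristicUnitSet:
    """Disjoint named cell sets per level, plus unassigned cells and flags."""

    units: Dict[str, FloristicUnit] = field(default_factory=dict)
    unassigned_cells: Set[str] = field(default_factory=set)
    cell_flags: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.check_disjoint()

    def check_disjoint(self) -> None:
        by_level: Dict[str, Set[str]] = {}
        for uid, unit in self.units.items():
            seen = by_level.setdefault(unit.level, set())
            overlap = seen & unit.cells
            if overlap:
                raise ValidationError(
                    f"units of level {unit.level} overlap on cells {sorted(overlap)[:5]}")
            seen |= unit.cells
        for uid, unit in self.units.items():
            if unit.parent is not None and unit.parent in self.units:
                if not unit.cells <= self.units[unit.parent].cells:
                    raise ValidationError(
                        f"unit {uid} not nested in its parent {unit.parent}")

    def at_level(self, level: str) -> Dict[str, FloristicUnit]:
        return {u: v for u, v in self.units.items() if v.level == level}

    def assigned_cells(self, level: Optional[str] = None) -> Set[str]:
        out: Set[str] = set()
        for unit in self.units.values():
            if level is None or unit.level == level:
                out |= unit.cells
        return out

    def copy(self) -> "FloristicUnitSet":
        return FloristicUnitSet(
            units={u: FloristicUnit(set(v.cells), v.level, v.parent)
                   for u, v in self.units.items()},
            unassigned_cells=set(self.unassigned_cells),
            cell_flags=dict(self.cell_flags),
        )

    def to_dict(self) -> dict:
        out = {u: {"level": v.level, "cells": sorted(v.cells), "parent": v.parent}
               for u, v in sorted(self.units.items())}
        out["unassigned"] = sorted(self.unassigned_cells)
        return out


@dataclass
class EndemismTable:
    """Per-unit endemics/taxa/cell counts, recomputable from the full matrix."""

    rows: Dict[str, dict]

    def to_records(self) -> list:
        return [{"unit": u, **row} for u, row in sorted(self.rows.items())]


@dataclass
class AnalysisScore:
    """Four optimality criteria of one analysis, with competition ranks."""

    name: str
    n_endemics: int
    n_taxa: int
    n_units: int
    n_cells: int
    ranks: Optional[dict] = None
    rank_sum: Optional[int] = None
    final_rank: Optional[int] = None

    @property
    def criteria(self) -> tuple:
        return (self.n_endemics, self.n_taxa, self.n_units, self.n_cells)


# ---------------------------------------------------------------------------
# Endemism accounting
# ---------------------------------------------------------------------------

def _endemic_mask(m: OccurrenceMatrix, cells: Set[str]) -> np.ndarray:
    rows = [m._cell_index[c] for c in cells]
    inside = m.incidence[rows].sum(axis=0) if rows else np.zeros(len(m.taxa))
    total = m.incidence.sum(axis=0)
    return (inside > 0) & (inside == total)


def endemics_of_unit(m: OccurrenceMatrix, cells: Iterable[str]) -> Set[str]:
    """Taxa whose entire recorded range lies within ``cells``.

    Uses occurrences of the *current* matrix (the full matrix should be
    passed: singletons included), so a taxon with any occurrence outside the
    unit is excluded.
    """
    cells = {str(c) for c in cells}
    unknown = cells - set(m.cells)
    if unknown:
        raise ValidationError(f"unknown cells: {sorted(unknown)[:5]}")
    mask = _endemic_mask(m, cells)
    return {m.taxa[j] for j in np.flatnonzero(mask)}


def endemism_table(m: OccurrenceMatrix, u: FloristicUnitSet) -> EndemismTable:
    rows = {}
    for uid, unit in u.units.items():
        taxa = set()
        for c in unit.cells:
            taxa |= m.taxa_of_cell(c)
        ends = endemics_of_unit(m, unit.cells)
        rows[uid] = {"level": unit.level, "n_cells": len(unit.cells),
                     "n_taxa": len(taxa), "n_endemics": len(ends)}
    return EndemismTable(rows=rows)


def units_from_partition(p: BocPartition, level: str = "CoE",
                         prefix: Optional[str] = None) -> FloristicUnitSet:
    """Name BOC clusters by left-to-right tree order and wrap them as units."""
    prefix = prefix or level
    units = {f"{prefix}-{k + 1}": FloristicUnit(cells=set(cl), level=level)
             for k, cl in enumerate(p.clusters)}
    return FloristicUnitSet(units=units, unassigned_cells=set(p.unassigned))


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

def refine_units(m: OccurrenceMatrix, u: FloristicUnitSet) -> FloristicUnitSet:
    """Iterate the three pruning rules to a fixed point.

    (1) drop units with no endemic taxa; (2) drop, from each unit, cells
    containing none of that unit's endemics; (3) drop single-cell units
    whose only endemics are single-cell taxa (clustering cannot corroborate
    them). Dropped cells join the unassigned pool; rule-3 cells are flagged
    ``singleton candidate``. Pruning a cell can never remove an endemic
    (endemic ranges contain no prunable cell), so the endemic sets of the
    surviving units are stable.
    """
    out = u.copy()
    changed = True
    while changed:
        changed = False
        for uid in list(out.units):
            unit = out.units[uid]
            ends = endemics_of_unit(m, unit.cells)
            if not ends:
                out.unassigned_cells |= unit.cells
                _drop_unit(out, uid)
                changed = True
                continue
            keep = set()
            for c in unit.cells:
                if m.taxa_of_cell(c) & ends:
                    keep.add(c)
            if keep != unit.cells:
                out.unassigned_cells |= unit.cells - keep
                unit.cells = keep
                changed = True
            if len(unit.cells) == 1 and all(m.range_sizes[t] == 1 for t in
                                            endemics_of_unit(m, unit.cells)):
                for c in unit.cells:
                    out.cell_flags[c] = "singleton candidate"
                out.unassigned_cells |= unit.cells
                _drop_unit(out, uid)
                changed = True
    return out


def _drop_unit(u: FloristicUnitSet, uid: str) -> None:
    del u.units[uid]
    for other in u.units.values():
        if other.parent == uid:
            other.parent = None


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

def expand_units(m: OccurrenceMatrix, u: FloristicUnitSet,
                 grid: Optional[CellGrid] = None,
                 adjacency_required: bool = True) -> FloristicUnitSet:
    """Greedy endemism-maximising assignment of unassigned cells to units.

    One move per iteration: over all (unassigned cell, unit) pairs - cells
    adjacent to the unit when ``adjacency_required`` - the move with the
    largest gain in the unit's endemic count is applied, provided the gain
    is positive. Ties break by (i) larger gain, (ii) smaller full range of
    the smallest-range newly endemic taxon, (iii) larger relative (percent)
    increase in the unit's endemism, (iv) lexicographic unit id, then cell
    id. The loop stops when no positive-gain move remains; it terminates
    because each move strictly increases the total endemic count.
    """
    if adjacency_required and grid is None:
        raise ConfigurationError("adjacency_required=True needs a CellGrid")
    out = u.copy()
    total = m.incidence.sum(axis=0)
    ranges = m.range_vector()

    while True:
        best = None  # (gain, min_new_range, -rel_gain, uid, cell)
        for uid in sorted(out.units):
            unit = out.units[uid]
            rows = [m._cell_index[c] for c in unit.cells]
            inside = m.incidence[rows].sum(axis=0)
            cur_mask = (inside > 0) & (inside == total)
            cur = int(cur_mask.sum())
            if adjacency_required:
                frontier = set()
                for c in unit.cells:
                    frontier |= grid.neighbours(c)
                candidates = sorted(frontier & out.unassigned_cells)
            else:
                candidates = sorted(out.unassigned_cells)
            for cell in candidates:
                if cell not in m._cell_index:
                    continue
                row = m.incidence[m._cell_index[cell]]
                new_inside = inside + row
                new_mask = (new_inside > 0) & (new_inside == total)
                gain = int(new_mask.sum()) - cur
                if gain <= 0:
                    continue
                new_ranges = ranges[new_mask & ~cur_mask]
                min_new = int(new_ranges.min()) if new_ranges.size else 10 ** 9
                rel = gain / cur if cur > 0 else float("inf")
                key = (-gain, min_new, -rel, uid, cell)
                if best is None or key < best[0]:
                    best = (key, uid, cell, gain)
        if best is None:
            break
        _, uid, cell, gain = best
        out.units[uid].cells.add(cell)
        out.unassigned_cells.discard(cell)
    return out


def create_units_from_orphan_taxa(m: OccurrenceMatrix, u: FloristicUnitSet,
                                  grid: CellGrid, level: str = "CoE") -> FloristicUnitSet:
    """Found new units for taxa whose whole range sits in unassigned cells.

    The union of such orphan ranges is split into connected components
    under the grid adjacency; each component becomes a new unit, and the
    newcomers are immediately refined.
    """
    out = u.copy()
    assigned = out.assigned_cells()
    orphan_cells: Set[str] = set()
    for j, t in enumerate(m.taxa):
        occ = {m.cells[i] for i in np.flatnonzero(m.incidence[:, j])}
        if occ and occ <= out.unassigned_cells and not (occ & assigned):
            orphan_cells |= occ
    if not orphan_cells:
        return out
    g = nx.Graph()
    g.add_nodes_from(orphan_cells)
    for c in orphan_cells:
        for nbr in grid.neighbours(c):
            if nbr in orphan_cells:
                g.add_edge(c, nbr)
    existing = len(out.at_level(level))
    new_units = {}
    comps = sorted(nx.connected_components(g), key=lambda s: sorted(s)[0])
    for k, comp in enumerate(comps):
        uid = f"{level}-orphan-{existing + k + 1}"
        new_units[uid] = FloristicUnit(cells=set(comp), level=level)
    refined_new = refine_units(m, FloristicUnitSet(units=new_units,
                                                   unassigned_cells=set()))
    out.units.update(refined_new.units)
    kept_cells = refined_new.assigned_cells()
    out.unassigned_cells -= kept_cells
    out.unassigned_cells |= (orphan_cells - kept_cells)
    out.check_disjoint()
    return out


# ---------------------------------------------------------------------------
# Bridging to spatially complete regions
# ---------------------------------------------------------------------------

def _k2_similarity(cell_taxa: Set[str], unit_taxa: Set[str]) -> float:
    a = len(cell_taxa & unit_taxa)
    b = len(cell_taxa - unit_taxa)
    c = len(unit_taxa - cell_taxa)
    if a + b == 0 or a + c == 0:
        return 0.0
    return 0.5 * (a / (a + b) + a / (a + c))


def bridge_to_biogeographic_regions(m: OccurrenceMatrix, u: FloristicUnitSet,
                                    region_cells: Optional[Set[str]] = None,
                                    grid: Optional[CellGrid] = None,
                                    level: str = "CoE") -> FloristicUnitSet:
    """Assign the remaining in-region cells to their closest unit.

    Each remaining cell joins the unit with the greatest Kulczynski-2
    *similarity* between the cell's taxon list and the unit's pooled taxon
    list (unweighted presences). Such cells complete no range, so they are
    flagged ``no endemics``; the result is a set of BR-level units mirroring
    the input units, with parents wired up. ``region_cells`` defaults to the
    cells inside the coordinate bounding box of all unit cells (requires a
    grid with coordinates).
    """
    base_units = u.at_level(level)
    if not base_units:
        raise ValidationError(f"no units at level {level!r}")
    assigned = u.assigned_cells(level)
    if region_cells is None:
        if grid is None or not grid.coordinates:
            raise ConfigurationError(
                "region_cells not given and no coordinates to infer them from")
        lons = [grid.coordinates[c][0] for c in assigned if c in grid.coordinates]
        lats = [grid.coordinates[c][1] for c in assigned if c in grid.coordinates]
        lo_x, hi_x, lo_y, hi_y = min(lons), max(lons), min(lats), max(lats)
        region_cells = {c for c in m.cells
                        if c in grid.coordinates
                        and lo_x <= grid.coordinates[c][0] <= hi_x
                        and lo_y <= grid.coordinates[c][1] <= hi_y}
    region_cells = {str(c) for c in region_cells}

    pooled = {}
    for uid, unit in base_units.items():
        taxa: Set[str] = set()
        for c in unit.cells:
            taxa |= m.taxa_of_cell(c)
        pooled[uid] = taxa

    out = u.copy()
    br_ids = {}
    for k, uid in enumerate(sorted(base_units)):
        br_id = f"BR-{k + 1}"
        br_ids[uid] = br_id
        out.units[br_id] = FloristicUnit(cells=set(base_units[uid].cells), level="BR")
        out.units[uid] = replace(out.units[uid], parent=br_id)

    todo = sorted(region_cells - assigned)
    for cell in todo:
        if cell not in m._cell_index:
            continue
        cell_taxa = m.taxa_of_cell(cell)
        if not cell_taxa:
            warnings.warn(f"cell {cell} has no taxa; left unassigned", stacklevel=2)
            continue
        scored = sorted(
            ((-_k2_similarity(cell_taxa, pooled[uid]), uid) for uid in sorted(pooled)),
        )
        best_sim, best_uid = -scored[0][0], scored[0][1]
        if best_sim <= 0:
            continue
        out.units[br_ids[best_uid]].cells.add(cell)
        out.unassigned_cells.discard(cell)
        out.cell_flags[cell] = "no endemics"
    out.check_disjoint()
    return out


# ---------------------------------------------------------------------------
# Evaluation and ranking
# ---------------------------------------------------------------------------

def evaluate_analysis(m: OccurrenceMatrix, u: FloristicUnitSet,
                      name: str = "", level: Optional[str] = None) -> AnalysisScore:
    """The four optimality criteria of one refined unit set.

    endemics = sum over units of their endemic counts; taxa = size of the
    union of taxa occurring in any unit cell; units and cells are counts.
    """
    units = u.units if level is None else u.at_level(level)
    n_endemics = 0
    taxa: Set[str] = set()
    n_cells = 0
    for unit in units.values():
        n_endemics += len(endemics_of_unit(m, unit.cells))
        for c in unit.cells:
            taxa |= m.taxa_of_cell(c)
        n_cells += len(unit.cells)
    return AnalysisScore(name=name, n_endemics=n_endemics, n_taxa=len(taxa),
                         n_units=len(units), n_cells=n_cells)


def _competition_rank(values: Sequence[float], descending: bool) -> list:
    """Competition (minimum) ranking: ties share the smallest rank."""
    order = sorted(values, reverse=descending)
    return [order.index(v) + 1 for v in values]


def rank_analyses(scores: Sequence[AnalysisScore]) -> list:
    """Fill per-criterion ranks, rank sums and final ranks.

    Each criterion is ranked descending (higher is better) with competition
    ranking; the final rank orders analyses by ascending rank sum, again
    with competition ranking for ties.
    """
    if len(scores) < 2:
        raise ValidationError("ranking needs at least two analyses")
    crits = ("n_endemics", "n_taxa", "n_units", "n_cells")
    per_crit = {}
    for crit in crits:
        per_crit[crit] = _competition_rank([getattr(s, crit) for s in scores],
                                           descending=True)
    out = []
    sums = []
    for i, s in enumerate(scores):
        ranks = {crit: per_crit[crit][i] for crit in crits}
        sums.append(sum(ranks.values()))
        out.append(replace(s, ranks=ranks, rank_sum=sum(ranks.values())))
    finals = _competition_rank(sums, descending=False)
    return [replace(s, final_rank=f) for s, f in zip(out, finals)]


# ---------------------------------------------------------------------------
# Upper hierarchy: recluster centres into regions
# ---------------------------------------------------------------------------

def recluster_units_to_brs(m: OccurrenceMatrix, u: FloristicUnitSet,
                           schemes: Sequence[str] = ("bell", "inverse", "integration"),
                           coef: str = "kulczynski2",
                           level: str = "CoE") -> FloristicUnitSet:
    """Cluster the centres themselves (as pseudo-OGUs) into regions.

    Each unit becomes one pseudo-cell whose taxa are those present in any
    member cell; taxa are re-weighted on the pseudo-OGU ranges, one UPGMA
    tree is built per weighting scheme, their majority consensus is cut at
    the standard second branch order, and each resulting cluster of units
    becomes a region whose cells are the union of its members' cells.
    """
    base = u.at_level(level)
    out = u.copy()
    if len(base) < 3:
        warnings.warn("fewer than 3 units; emitting a single region", stacklevel=2)
        cells = set()
        for unit in base.values():
            cells |= unit.cells
        out.units["BR-1"] = FloristicUnit(cells=cells, level="BR")
        for uid in base:
            out.units[uid] = replace(out.units[uid], parent="BR-1")
        return out

    uids = sorted(base)
    inc = np.zeros((len(uids), len(m.taxa)), dtype=np.int8)
    for i, uid in enumerate(uids):
        rows = [m._cell_index[c] for c in base[uid].cells]
        inc[i] = (m.incidence[rows].sum(axis=0) > 0).astype(np.int8)
    present = np.flatnonzero(inc.sum(axis=0) > 0)
    pseudo = OccurrenceMatrix.from_incidence(
        uids, [m.taxa[j] for j in present], inc[:, present])

    trees = []
    for scheme in schemes:
        w = assign_weights(pseudo, scheme)
        d = build_dissimilarity_matrix(pseudo, w, coef)
        trees.append(upgma(d))
    if len(trees) >= 2:
        tree = consensus_tree(trees, "majority").tree
    else:
        tree = trees[0]
    labels = assign_branch_orders(tree, "standard")
    part = extract_boc_clusters(tree, labels, 2)

    clusters = list(part.clusters)
    for lone in part.unassigned:  # units under no second-order branch
        clusters.append({lone})
    for k, comp in enumerate(clusters):
        br_id = f"BR-{k + 1}"
        cells = set()
        for uid in comp:
            cells |= base[uid].cells
            out.units[uid] = replace(out.units[uid], parent=br_id)
        out.units[br_id] = FloristicUnit(cells=cells, level="BR")
    out.check_disjoint()
    return out


# ---------------------------------------------------------------------------
# Reporting aids
# ---------------------------------------------------------------------------

def report_suspicious_units(m: OccurrenceMatrix, u: FloristicUnitSet,
                            widespread_threshold: int = 5) -> list:
    """Units whose every endemic is near the widespread threshold.

    Such units may stem from clustering of widely distributed taxa in
    poorly collected areas; they are reported, never deleted automatically.
    """
    flagged = []
    for uid, unit in sorted(u.units.items()):
        ends = endemics_of_unit(m, unit.cells)
        if ends and all(m.range_sizes[t] >= widespread_threshold for t in ends):
            flagged.append(uid)
    return flagged
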