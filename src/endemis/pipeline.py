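"""End-to-end orchestration: matrix -> weighted trees -> consensus -> units.

The canonical analysis weights the matrix under several schemes, builds one
Kulczynski-2 UPGMA phenogram per scheme, takes their majority-rule
consensus, cuts candidate units at the modified third branch order,
refines them on endemism, and expands them over the grid. Cells carrying no
clustering taxon (nothing with range >= 2) cannot enter a dissimilarity
matrix and start out unassigned.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from .boc import boc_partition
from .coe import (FloristicUnitSet, create_units_from_orphan_taxa, expand_units,
                  refine_units, units_from_partition)
from .consensus import ConsensusTree, consensus_tree
from .dendrogram import Dendrogram, upgma
from .dissimilarity import DissimilarityMatrix, build_dissimilarity_matrix
from .errors import ValidationError
from .occurrence import CellGrid, OccurrenceMatrix, flag_clustering_taxa
from .weighting import assign_weights

__all__ = ["PipelineResult", "run_coe_pipeline"]


@dataclass
class PipelineResult:
    trees: Dict[str, Dendrogram]
    consensus: Optional[ConsensusTree]
    units: FloristicUnitSet
    dissimilarities: Dict[str, DissimilarityMatrix] = field(default_factory=dict)
    dropped_cells: set = field(default_factory=set)


def run_coe_pipeline(m: OccurrenceMatrix, grid: Optional[CellGrid] = None,
                     schemes: Sequence[str] = ("bell", "inverse", "integration"),
                     coefficient: str = "kulczynski2",
                     boc_variant: str = "modified3", boc_level: Optional[int] = None,
                     expand: bool = True, adjacency_required: bool = True,
                     orphan_units: bool = False) -> PipelineResult:
    """Run the full centre-of-endemism delimitation on one matrix.

    Endemism accounting throughout uses the full input matrix (single-cell
    taxa included); clustering uses only cells that contain at least one
    taxon of range >= 2.

    ``boc_level`` defaults by context: on a single dendrogram the candidate
    centres are the modified third-order clusters, whereas on a multi-scheme
    majority consensus those clusters are the *sub*-centres and the centres
    are the larger, nearly basal clusters one order up (level 4 on the same
    modified ordering).
    """
    flags = flag_clustering_taxa(m)
    if not flags.clustering_taxa:
        raise ValidationError("no usable taxa: every taxon occupies a single cell")
    clustering = m.subset(taxa=flags.clustering_taxa)
    occupied = clustering.incidence.sum(axis=1) > 0
    usable_cells = [c for c, ok in zip(clustering.cells, occupied) if ok]
    dropped = set(m.cells) - set(usable_cells)
    clustering = clustering.subset(cells=usable_cells)

    trees: Dict[str, Dendrogram] = {}
    dms: Dict[str, DissimilarityMatrix] = {}
    for scheme in schemes:
        w = assign_weights(m, scheme)
        d = build_dissimilarity_matrix(clustering, w, coefficient)
        dms[scheme] = d
        trees[scheme] = upgma(d)

    cons: Optional[ConsensusTree] = None
    if len(trees) >= 2:
        cons = consensus_tree(list(trees.values()), "majority")
        cut_tree = cons.tree
        level = boc_level if boc_level is not None else 4
    else:
        cut_tree = next(iter(trees.values()))
        level = boc_level if boc_level is not None else 3

    part = boc_partition(cut_tree, variant=boc_variant, level=level)
    units = units_from_partition(part, level="CoE")
    units.unassigned_cells |= dropped
    units = refine_units(m, units)
    if expand:
        units = expand_units(m, units, grid=grid,
                             adjacency_required=adjacency_required and grid is not None)
    if orphan_units:
        if grid is None:
            raise ValidationError("orphan_units=True requires a grid")
        units = create_units_from_orphan_taxa(m, units, grid)
    return PipelineResult(trees=trees, consensus=cons, units=units,
                          dissimilarities=dms, dropped_cells=dropped)
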