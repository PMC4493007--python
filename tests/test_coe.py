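"""Endemism accounting, unit refinement/expansion, bridging and ranking."""
import numpy as np
import pytest

from endemis import (FloristicUnit, FloristicUnitSet, OccurrenceMatrix,
                     bridge_to_biogeographic_regions,
                     create_units_from_orphan_taxa, endemics_of_unit,
                     evaluate_analysis, expand_units, qds_adjacency,
                     rank_analyses, recluster_units_to_brs, refine_units)
from endemis.errors import ValidationError
from endemis.occurrence import qds_code


def matrix_from(spec):
    """Build a matrix from {taxon: [cells]} preserving insertion order."""
    cells = list(dict.fromkeys(c for occ in spec.values() for c in occ))
    taxa = list(spec)
    inc = np.zeros((len(cells), len(taxa)), dtype=int)
    ci = {c: i for i, c in enumerate(cells)}
    for j, t in enumerate(taxa):
        for c in spec[t]:
            inc[ci[c], j] = 1
    return OccurrenceMatrix.from_incidence(cells, taxa, inc)


def units_of(**kw):
    units = {uid: FloristicUnit(cells=set(cells), level="CoE")
             for uid, cells in kw.items()}
    return FloristicUnitSet(units=units)


class TestEndemics:
    def test_taxon_inside_unit_is_endemic(self):
        m = matrix_from({"t": ["c1"], "w": ["c1", "c2", "c3"]})
        assert endemics_of_unit(m, {"c1", "c2"}) == {"t"}

    def test_taxon_with_outside_occurrence_not_endemic(self):
        m = matrix_from({"t": ["c1", "c3"], "w": ["c1", "c2", "c3"]})
        assert endemics_of_unit(m, {"c1", "c2"}) == set()

    def test_union_superset_of_component_endemics(self):
        # a taxon spanning two units is endemic only to their union
        m = matrix_from({
            "left": ["c1", "c2"], "right": ["c4", "c5"],
            "span": ["c2", "c4"], "wide": ["c1", "c3", "c6"],
        })
        u1, u2 = {"c1", "c2"}, {"c4", "c5"}
        e1, e2 = endemics_of_unit(m, u1), endemics_of_unit(m, u2)
        eu = endemics_of_unit(m, u1 | u2)
        assert e1 | e2 <= eu
        assert "span" in eu and "span" not in e1 | e2

    def test_unknown_cell_rejected(self):
        m = matrix_from({"t": ["c1"]})
        with pytest.raises(ValidationError):
            endemics_of_unit(m, {"zz"})


class TestRefineUnits:
    def test_cell_without_unit_endemics_pruned(self):
        m = matrix_from({"end": ["c1", "c2"], "wide": ["c1", "c2", "c3", "c9"]})
        u = units_of(A={"c1", "c2", "c3"})
        out = refine_units(m, u)
        assert out.units["A"].cells == {"c1", "c2"}
        assert "c3" in out.unassigned_cells

    def test_unit_without_endemics_removed(self):
        m = matrix_from({"w1": ["c1", "c9"], "w2": ["c2", "c9"], "e": ["c9"]})
        u = units_of(A={"c1", "c2"})
        out = refine_units(m, u)
        assert "A" not in out.units

    def test_single_cell_unit_with_only_singleton_endemics_removed(self):
        m = matrix_from({"s": ["c1"], "w": ["c1", "c2", "c3"]})
        u = units_of(A={"c1"})
        out = refine_units(m, u)
        assert not out.units
        assert out.cell_flags["c1"] == "singleton candidate"

    def test_pruning_preserves_endemic_sets(self, rng):
        from conftest import random_occurrence
        for _ in range(20):
            m = random_occurrence(rng, 12, 30, density=0.25)
            cells = set(rng.choice(m.cells, size=6, replace=False))
            before = endemics_of_unit(m, cells)
            out = refine_units(m, units_of(A=cells))
            if "A" in out.units:
                assert endemics_of_unit(m, out.units["A"].cells) == before


def toy_grid(cells):
    return qds_adjacency(cells, scheme="queen")


class TestExpandUnits:
    def test_adjacent_cell_completing_a_range_joins(self):
        # t spans c1+c2; unit holds c1; c2 is adjacent and unassigned
        c1, c2 = qds_code(0, 0), qds_code(0, 1)
        m = matrix_from({"t": [c1, c2], "w": [c1, c2, qds_code(5, 5)]})
        u = units_of(A={c1})
        u.unassigned_cells = {c2}
        grid = toy_grid(m.cells)
        out = expand_units(m, u, grid=grid)
        assert out.units["A"].cells == {c1, c2}
        assert not out.unassigned_cells & {c2}

    def test_cell_adding_nothing_stays_unassigned(self):
        c1, c2 = qds_code(0, 0), qds_code(0, 1)
        far = qds_code(7, 7)
        m = matrix_from({"e": [c1], "stray": [c2, far], "w": [c1, c2, far]})
        u = units_of(A={c1})
        u.unassigned_cells = {c2}
        out = expand_units(m, u, grid=toy_grid(m.cells))
        assert out.units["A"].cells == {c1}
        assert c2 in out.unassigned_cells

    def test_tie_breaks_prefer_smaller_new_range(self):
        # cell x completes a range-2 taxon for A and a range-4 taxon for B,
        # with equal gains; A must win
        a1, x, b1 = qds_code(0, 0), qds_code(0, 1), qds_code(0, 2)
        b2, b3 = qds_code(1, 2), qds_code(1, 1)
        m = matrix_from({
            "endA": [a1], "endB": [b1],  # keep both units endemic
            "small": [a1, x],                      # range 2, completes in A
            "large": [b1, b2, b3, x],              # range 4, completes in B
            "wide": [a1, x, b1, b2, b3, qds_code(9, 9)],
        })
        u = units_of(A={a1}, B={b1, b2, b3})
        u.unassigned_cells = {x}
        out = expand_units(m, u, grid=toy_grid(m.cells))
        assert x in out.units["A"].cells
        assert x not in out.units["B"].cells

    def test_expansion_never_decreases_total_endemics(self, rng):
        from conftest import random_occurrence
        m = random_occurrence(rng, 16, 40, density=0.2)
        grid = None
        cells = list(m.cells)
        u = units_of(A=set(cells[:4]), B=set(cells[4:8]))
        u.unassigned_cells = set(cells[8:])
        before = sum(len(endemics_of_unit(m, x.cells)) for x in u.units.values())
        out = expand_units(m, u, grid=None, adjacency_required=False)
        after = sum(len(endemics_of_unit(m, x.cells)) for x in out.units.values())
        assert after >= before


class TestOrphanUnits:
    def test_orphan_range_founds_new_unit(self):
        c1, c2, c3 = qds_code(0, 0), qds_code(0, 1), qds_code(5, 5)
        far = qds_code(5, 6)
        m = matrix_from({"in": [c1], "orphan": [c3, far],
                         "w": [c1, c2, c3, far]})
        u = units_of(A={c1})
        u.unassigned_cells = {c2, c3, far}
        out = create_units_from_orphan_taxa(m, u, toy_grid(m.cells))
        new = [uid for uid in out.units if uid != "A"]
        assert len(new) == 1
        assert out.units[new[0]].cells == {c3, far}

    def test_taxon_overlapping_unit_is_not_orphan(self):
        c1, c2 = qds_code(0, 0), qds_code(0, 1)
        m = matrix_from({"in": [c1], "half": [c1, c2], "w": [c1, c2, qds_code(4, 4)]})
        u = units_of(A={c1})
        u.unassigned_cells = {c2}
        out = create_units_from_orphan_taxa(m, u, toy_grid(m.cells))
        assert set(out.units) == {"A"}

    def test_overlapping_orphan_ranges_merge(self):
        c = [qds_code(5, k) for k in range(3)]
        anchor = qds_code(0, 0)
        m = matrix_from({"in": [anchor], "o1": [c[0], c[1]], "o2": [c[1], c[2]],
                         "w": [anchor] + c})
        u = units_of(A={anchor})
        u.unassigned_cells = set(c)
        out = create_units_from_orphan_taxa(m, u, toy_grid(m.cells))
        new = [uid for uid in out.units if uid != "A"]
        assert len(new) == 1
        assert out.units[new[0]].cells == set(c)


class TestBridge:
    def test_cell_joins_unit_sharing_all_taxa(self):
        g = [qds_code(r, c) for r in range(3) for c in range(3)]
        m = matrix_from({
            "eA": [g[0], g[1]], "eB": [g[6], g[7]],
            "wA": [g[0], g[1], g[2]], "wB": [g[6], g[7], g[8]],
        })
        u = units_of(A={g[0], g[1]}, B={g[6], g[7]})
        u.unassigned_cells = {g[2], g[8]}
        out = bridge_to_biogeographic_regions(m, u, region_cells=set(m.cells))
        brA = out.units[out.units["A"].parent]
        brB = out.units[out.units["B"].parent]
        assert g[2] in brA.cells and g[8] in brB.cells
        assert out.cell_flags[g[2]] == "no endemics"

    def test_bridging_never_changes_endemic_counts(self):
        g = [qds_code(r, c) for r in range(2) for c in range(4)]
        m = matrix_from({
            "eA": [g[0]], "eB": [g[3]],
            "wA": [g[0], g[1]], "wB": [g[2], g[3]],
            "broad": [g[0], g[1], g[2], g[3], g[4], g[5], g[6], g[7]],
        })
        u = units_of(A={g[0]}, B={g[3]})
        u.unassigned_cells = set(g) - {g[0], g[3]}
        before = {uid: endemics_of_unit(m, un.cells) for uid, un in u.units.items()}
        out = bridge_to_biogeographic_regions(m, u, grid=toy_grid(m.cells))
        for uid in ("A", "B"):
            assert endemics_of_unit(m, out.units[uid].cells) == before[uid]

    def test_tie_resolved_lexicographically(self):
        g = [qds_code(0, c) for c in range(3)]
        m = matrix_from({"eA": [g[0]], "eB": [g[2]],
                         "shared": [g[0], g[1], g[2]]})
        u = units_of(A={g[0]}, B={g[2]})
        u.unassigned_cells = {g[1]}
        out = bridge_to_biogeographic_regions(m, u, grid=toy_grid(m.cells))
        assert g[1] in out.units[out.units["A"].parent].cells


class TestEvaluation:
    def test_empty_unit_set_scores_zero(self):
        m = matrix_from({"t": ["c1"]})
        s = evaluate_analysis(m, FloristicUnitSet())
        assert s.criteria == (0, 0, 0, 0)

    def test_whole_matrix_unit_counts_everything(self, rng):
        from conftest import random_occurrence
        m = random_occurrence(rng, 6, 12)
        s = evaluate_analysis(m, units_of(A=set(m.cells)))
        assert s.criteria == (12, 12, 1, 6)

    def test_hand_counted_toy(self):
        m = matrix_from({
            "e1": ["c1"], "e2": ["c1", "c2"], "out": ["c2", "c9"],
            "e3": ["c4"], "w": ["c1", "c2", "c4", "c9"],
        })
        u = units_of(A={"c1", "c2"}, B={"c4"})
        s = evaluate_analysis(m, u)
        assert s.n_endemics == 3   # e1, e2 in A; e3 in B
        assert s.n_taxa == 5       # every taxon touches a unit cell
        assert s.n_units == 2
        assert s.n_cells == 3


class TestRanking:
    def test_all_equal_scores_all_rank_one(self):
        from endemis import AnalysisScore
        scores = [AnalysisScore(name=str(i), n_endemics=5, n_taxa=10,
                                n_units=2, n_cells=8) for i in range(3)]
        ranked = rank_analyses(scores)
        for s in ranked:
            assert set(s.ranks.values()) == {1}
            assert s.final_rank == 1

    def test_ties_share_minimum_rank(self, benchmark_scores):
        ranked = rank_analyses(benchmark_scores)
        endemics_ranks = {s.name: s.ranks["n_endemics"] for s in ranked}
        # 472 endemics appears twice; both share rank 7
        assert endemics_ranks["Unw:K2"] == 7
        assert endemics_ranks["Bell:PAE"] == 7


class TestRecluster:
    def test_disjoint_blocks_give_two_regions(self):
        # two groups of units sharing no taxa across groups
        gA = [qds_code(0, c) for c in range(3)]
        gB = [qds_code(9, c) for c in range(3)]
        spec = {}
        for i, c in enumerate(gA):
            spec[f"a{i}"] = [c]
            spec[f"sa{i}"] = [c, gA[(i + 1) % 3]]
        for i, c in enumerate(gB):
            spec[f"b{i}"] = [c]
            spec[f"sb{i}"] = [c, gB[(i + 1) % 3]]
        m = matrix_from(spec)
        u = units_of(A1={gA[0]}, A2={gA[1]}, A3={gA[2]},
                     B1={gB[0]}, B2={gB[1]}, B3={gB[2]})
        out = recluster_units_to_brs(m, u, schemes=("inverse",))
        brs = out.at_level("BR")
        br_cells = [frozenset(b.cells) for b in brs.values()]
        assert frozenset(gA) in br_cells and frozenset(gB) in br_cells
        # conservation: regions cover exactly the union of member unit cells
        assert set().union(*br_cells) == set(gA) | set(gB)

    def test_fewer_than_three_units_single_region(self):
        m = matrix_from({"a": ["c1"], "b": ["c2"], "s": ["c1", "c2"]})
        u = units_of(A={"c1"}, B={"c2"})
        with pytest.warns(UserWarning):
            out = recluster_units_to_brs(m, u)
        assert set(out.at_level("BR")) == {"BR-1"}
        assert out.units["A"].parent == "BR-1"
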