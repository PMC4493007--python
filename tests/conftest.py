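"""Shared fixtures: published benchmark criteria and random structure factories."""
import numpy as np
import pytest

from endemis import AnalysisScore, Dendrogram, Node

# ---------------------------------------------------------------------------
# Published criterion values for the 16 weighting x clustering analyses of the
# benchmark study (a large Cape-flora regionalisation), used as input to the
# rank-sum machinery. Order: for each weighting (Unweighted, Inverse, Bell,
# Integration) the coefficients J, K2, S, PAE.
# ---------------------------------------------------------------------------
ANALYSIS_NAMES = [
    f"{w}:{c}"
    for w in ("Unw", "Inv", "Bell", "Int")
    for c in ("J", "K2", "S", "PAE")
]

CRITERIA_ENDEMICS = [463, 472, 299, 448, 490, 491, 395, 483,
                     496, 522, 404, 472, 466, 476, 418, 463]
CRITERIA_TAXA = [4144, 4169, 3909, 4112, 4199, 4218, 4156, 4193,
                 4212, 4244, 4200, 4179, 4187, 4217, 4173, 4177]
CRITERIA_UNITS = [47, 57, 53, 38, 57, 67, 63, 57,
                  63, 66, 67, 59, 59, 68, 63, 60]
CRITERIA_CELLS = [177, 197, 156, 162, 208, 241, 229, 203,
                  223, 256, 251, 201, 201, 237, 237, 199]

# the published per-criterion ranks, rank sums and final ranks
EXPECTED_RANKS_ENDEMICS = [10, 7, 16, 12, 4, 3, 15, 5, 2, 1, 14, 7, 9, 6, 13, 10]
EXPECTED_RANKS_TAXA = [14, 12, 16, 15, 6, 2, 13, 7, 4, 1, 5, 9, 8, 3, 11, 10]
EXPECTED_RANKS_UNITS = [15, 11, 14, 16, 11, 2, 5, 11, 5, 4, 2, 9, 9, 1, 5, 8]
EXPECTED_RANKS_CELLS = [14, 13, 16, 15, 8, 3, 6, 9, 7, 1, 2, 10, 10, 4, 4, 12]
EXPECTED_RANK_SUMS = [53, 43, 62, 58, 29, 10, 39, 32, 18, 7, 23, 35, 36, 14, 33, 40]
EXPECTED_FINAL_RANKS = [14, 13, 16, 15, 6, 2, 11, 7, 4, 1, 5, 9, 10, 3, 8, 12]


@pytest.fixture
def benchmark_scores():
    return [
        AnalysisScore(name=n, n_endemics=e, n_taxa=t, n_units=u, n_cells=c)
        for n, e, t, u, c in zip(ANALYSIS_NAMES, CRITERIA_ENDEMICS, CRITERIA_TAXA,
                                 CRITERIA_UNITS, CRITERIA_CELLS)
    ]


# ---------------------------------------------------------------------------
# Random structure factories
# ---------------------------------------------------------------------------

def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> Dendrogram:
    """Random binary ultrametric tree with strictly increasing merge heights."""
    nodes = [Node(label=f"L{i:03d}", height=0.0) for i in range(n_leaves)]
    heights = np.sort(rng.random(n_leaves - 1)) + 0.01
    k = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(height=float(heights[k] + (0 if k == 0 else 0)),
                      children=[nodes[i], nodes[j]])
        k += 1
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return Dendrogram(nodes[0])


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix in (0, 1) with zero diagonal."""
    a = rng.random((n, n))
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def random_occurrence(rng: np.random.Generator, n_cells: int, n_taxa: int,
                      density: float = 0.3):
    """Random binary matrix without empty rows or columns."""
    from endemis import OccurrenceMatrix
    while True:
        inc = (rng.random((n_cells, n_taxa)) < density).astype(int)
        if inc.sum(axis=0).min() > 0 and inc.sum(axis=1).min() > 0:
            break
    cells = [f"c{i:03d}" for i in range(n_cells)]
    taxa = [f"t{j:03d}" for j in range(n_taxa)]
    return OccurrenceMatrix.from_incidence(cells, taxa, inc)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
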