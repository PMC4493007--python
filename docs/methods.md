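# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical conventions adopted where the
method's description leaves room, and what the synthetic test-bed does and
does not establish.

## Data model and refinement

The unit of analysis is a grid cell (OGU); occurrence is binary. A taxon's
**range size** is its cell count in the *full* input matrix, computed once
at read time and never recomputed after cells are dropped — weighting must
reflect full ranges, while clustering runs on the refined cell set. The
refinement filters keep a cell only if it contains at least one
range-restricted taxon (range ≤ 5 cells by default) *and* at least 20
widespread taxa (range > 5); the second condition guards against
under-collected cells in survey data. Range-1 taxa are flagged, not
deleted: they cannot inform clustering (they co-occur with nothing), but
they count fully in endemism accounting, including single-cell candidate
centres.

QDS-style identifiers (`3318CB`) parse to quarter-degree row/column
indices; latitudes are treated as southern, which only fixes a sign
convention — adjacency and bounding boxes depend on relative positions
only. The default neighbourhood is queen (8-neighbour): the manual
map-based reasoning the expansion step formalises treats corner contact as
contiguity. An explicit adjacency CSV overrides the grid-derived one.

## Weighting (0–9 integer scale)

All schemes give singletons weight 0 and every other taxon at least 1
(widespread taxa retain a floor of signal). The 0–9 scale is a convention
inherited from character-weighting software and kept for comparability.

* **Inverse**: `clamp(round(20/x), 1, 9)`. Rounding is half-away-from-zero
  (so 20/40 = 0.5 → 1); the scheme's description says only "nearest
  integer", and this convention also keeps the floor of one automatic.
* **Bell**: raw `exp(−|a|·x^p)`, defaults a = −0.005, p = 3. As printed in
  its source the formula would *increase* with range for negative *a*; the
  intent (and every qualitative description of it) is decay, so the
  absolute value of *a* is used. The raw value in (0, 1] is scaled by 9 and
  rounded, then clamped to [1, 9]; whether the original rounded or
  truncated is unrecorded, and rounding is symmetric with the other
  schemes. Parameters that fail to decay raise a configuration error.
* **Integration**: ordinary least squares of log frequency on log range
  size over non-empty unit-width bins yields `y = c·x^b`; the area under
  the curve on [2, x_max] (x_max = largest clustering range) is split into
  nine equal parts using the closed-form antiderivative
  `c/(b+1)·x^{b+1}` (logarithmic form at b = −1), solving each interior
  boundary exactly. Bin membership is half-open `[x_{j−1}, x_j)` with the
  last bin closed, so every integer range maps to exactly one weight;
  weight = 10 − bin. For the published reference curve
  (c = 4773.5, b = −1.802, x ∈ [2, 169]) the first boundaries are
  x₁ ≈ 2.306 and x₂ ≈ 2.709, so range 2 weighs 9 and range 3 weighs 7 —
  each bin integral equals total/9 to 10⁻⁶ relative.

Weights are realised by column duplication (taxon with weight k appears as
k identical columns), which makes weighted counts and plain counts on the
expanded matrix provably identical in any presence–absence coefficient;
the test suite checks this equivalence to 10⁻¹².

## Dissimilarity and Mantel comparison

Counts a/b/c are weight sums over shared/unique taxa; cells with zero
total weight are errors (refinement should have removed them), not silent
omissions. Kulczynski-2 is implemented as the one-complement of the mean
of the two shared proportions — the printed formula in the method's source
is typographically garbled, but its prose definition ("arithmetic mean of
the shared proportions") is unambiguous. Simpson (β_sim) is already a
dissimilarity and takes no complement; it is 0 for fully nested pairs,
which is why it can under-rate peripheral, species-poor cells.

The Mantel test correlates the upper-triangle vectors (Pearson) and
permutes rows and columns of the second matrix jointly; the p-value is the
+1-corrected one-tailed proportion of permuted correlations ≥ the observed
one. Seeding is mandatory. Under independent random matrices (n = 30,
999 permutations) the rejection rate at α = 0.05 sits within [0.02, 0.08]
across 200 replicates — the calibration test in the suite.

## UPGMA

Classical average linkage: merge the pair with minimal average pairwise
dissimilarity; node height is that average (un-halved); the update is the
size-weighted Lance–Williams mean, equivalent to the arithmetic mean over
all member pairs. Ties on the minimum are broken by the lexicographically
smallest member label, then the smaller second label, making output
identical across platforms and label orders. The implementation is checked
against a naive O(n³) re-implementation and against scipy's average
linkage (cophenetic equality).

## Branch orders and BOC

Leaves are order 1. Standard rule at an internal node with maximum child
order m attained by k children: order = m + 1 if k ≥ 2 else m (polytomies
use the same rule, which reduces to Strahler's on binary trees). The
**modified** variant (for BOC3m) promotes any node whose maximum child
order is exactly 2 to order 3 — covering (2,1), (2,2), and, for consensus
polytomies, any node with a second-order child; everything above order 3
follows the standard rule. A BOC partition at level L collects the leaf
sets of maximal order-L nodes (parent order > L, or root). Leaves on paths
that skip the level (possible under the modified rule, where a leaf can
hang directly under an order-3 node) are reported unassigned rather than
absorbed — resolving them is the expansion step's job. If no node reaches
the requested level the whole leaf set is returned as one cluster with a
warning; silent emptiness would hide errors on degenerate trees.

Note one subtlety: promotion is monotone per node (modified order ≥
standard order everywhere), but the *assigned leaf count* at level 3 is
not monotone — promoting a subtree from 3 to 4 can strand a leaf attached
directly to it. The tests assert the true per-node monotonicity.

## Consensus and the unit hierarchy

Consensus is computed on rooted clusters (phenograms are rooted by
construction): strict keeps clusters in all trees, majority those in
> 50% (so ≥ 2 of 3). Retained clusters of rooted same-leaf trees are
pairwise compatible and assemble into a unique cladogram with support
values. On the majority tree, modified-order level-3 clusters are
**Sub-CoEs** and level-4 clusters on the same ordering are **CoEs** — the
"larger nearly basal clusters". The level-4 operationalisation of the
centre level is a design choice (the original procedure drew it
graphically); it is exposed as a parameter. The end-to-end pipeline
therefore cuts a single dendrogram at level 3 (per-analysis candidate
centres) but a consensus tree at level 4, and every Sub-CoE provably nests
inside a CoE or the unassigned set.

## Refinement, expansion, bridging, ranking

Unit refinement iterates to a fixed point: drop endemic-free units; prune
cells carrying none of their unit's endemics (pruning cannot change the
endemic set — an endemic range contains no prunable cell); drop
single-cell units whose only endemics are single-cell taxa, flagging them
`singleton candidate`. Expansion is strict best-first: one (cell, unit)
move per iteration, gain = added complete ranges, tie-broken by larger
gain, smaller range of the smallest newly-endemic taxon, larger percent
increase in unit endemism, lexicographic unit id, then cell id (the last
added for determinism). Each applied move strictly increases total
endemism, so termination is guaranteed. Adjacency is required by default
(the procedure being formalised worked on maps); disabling it gives a
purely compositional variant. Orphan ranges (wholly in unassigned cells)
found new units from connected components of their union. Bridging
assigns each remaining in-region cell to the unit with the highest
unweighted Kulczynski-2 similarity between the cell's taxa and the unit's
pooled taxa, flags it `no endemics`, and wraps the result as BR-level
units; the region defaults to the coordinate bounding box of all unit
cells and can be supplied explicitly. Suspicious units (every endemic at
or above the widespread threshold) are reported, never auto-deleted.

Analyses are compared on four criteria — Σ endemics over units, union of
taxa in unit cells, unit count, cell count — each ranked descending with
competition (minimum) ranking; the final rank orders rank sums ascending,
again with competition ranking. The suite reproduces a published
16-analysis rank table and its marginal sums exactly from the printed
criterion values.

Reclustering centres into regions treats each CoE as a pseudo-OGU
(presence = presence in any member cell), re-weights taxa on pseudo-OGU
ranges, builds one UPGMA tree per scheme, takes majority consensus and
cuts at standard order 2; units under no second-order branch become
singleton regions. Fewer than three centres degenerate to a single region
with a warning.

## Synthetic landscapes

The generator emulates the situation the method is for: a G × G grid
(default 20) of QDS-style cells; `n_taxa` (default 800) range sizes drawn
from a truncated discrete power law with exponent α = 1.802 on
[1, G²/4] — the empirical slope of a large regional flora's range-size
histogram; a fraction (default 0.6) of taxa endemic to one of
`n_patches` (default 4) contiguous patches; relocation noise ε (default
0.02) moving each occurrence to a uniform random cell. Patch sizes are
drawn from 6–10 cells, the footprint scale of observed centres (a few
hundred assigned cells over ~60 centres). Endemic ranges grow by random
contiguous accretion *from the patch nucleus*, giving the core–periphery
structure centres are defined by (endemics shared across most of the
centre, richest at the core); non-endemic ranges grow from uniform starts
anywhere. Everything is reproducible bit-for-bit from (parameters, seed).

What this does **not** emulate: collector-effort artefacts, taxonomic
noise, environmental gradients, range shapes constrained by topography,
and the survey-style sparsity that motivates the 20-widespread-taxa cell
filter (synthetic landscapes are complete by construction, so the
pipeline applies no cell-level refinement to them — only cells with no
clustering taxon are set aside). Passing recovery tests therefore shows
the chain is implemented coherently and is robust to relocation noise; it
does not certify performance on herbarium data.

At the default conditions (seed 42) the full pipeline recovers the four
planted centres exactly (ARI = 1 over patch cells), and mean ARI over ten
seeds degrades monotonically with noise (≈ 0.97 / 0.94 / 0.84 at
ε = 0 / 0.05 / 0.15) — both computed by the test suite, at these problem
sizes (400 cells × 800 taxa).

## Degenerate inputs and numerical conventions

Matrices must be strictly binary; duplicate ids, empty matrices,
all-singleton floras, NaN dissimilarities, unparseable QDS codes, empty
Newick strings and leaf-set mismatches all raise typed errors naming the
offenders. Dissimilarities are clipped to [0, 1] after symmetrisation at
10⁻¹² tolerance. Newick serialisation encodes ultrametric heights as
branch-length differences; cladograms round-trip without lengths;
structural equality compares heights at 10⁻⁹.
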