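# endemis

Endemism-based biogeographic regionalisation: delimit **Centres of Endemism
(CoEs)** — and from them spatially complete **Biogeographic Regions (BRs)** —
from a binary site-by-taxon occurrence matrix over grid cells (operational
geographic units, OGUs; typically Quarter Degree Squares such as `3318CB`).

The package is written for biogeographers and macroecologists who want the
whole chain — widespread-taxon down-weighting, weighted beta-diversity,
clustering, objective dendrogram cutting, consensus, and endemism-driven
refinement of the resulting units — as reproducible, scriptable code rather
than a sequence of manual GIS decisions.

## The method

Given a refined cell × taxon incidence matrix (cells must contain
range-restricted taxa and at least 20 widespread ones; single-cell taxa are
flagged and kept out of clustering but retained for endemism accounting):

1. **Weighting.** Each taxon with range *x* (cells occupied in the full
   matrix) receives an integer weight on a 0–9 scale:
   inverse `clamp(round(20/x), 1, 9)`; bell `clamp(round(9·e^{−|a|x^p}), 1, 9)`
   with *a* = −0.005, *p* = 3; or integration weighting, which fits a power
   law `y = c·x^b` to the range-size frequency histogram, splits the area
   under the curve on `[2, x_max]` into nine equal parts, and weights each
   taxon by its bin (9 down to 1). Weights are realised by duplicating
   matrix columns, so they work in any presence–absence coefficient.
2. **Dissimilarity.** For cells with weighted counts *a* (shared), *b*, *c*
   (unique): Jaccard `1 − a/(a+b+c)`, Simpson (β_sim)
   `min(b,c)/(min(b,c)+a)`, and Kulczynski-2
   `1 − ½(a/(a+b) + a/(a+c))`. Mantel tests (Pearson, 999 permutations)
   quantify agreement between matrices.
3. **Clustering.** UPGMA (average linkage) with a deterministic
   lexicographic tie-break.
4. **Branch Order Cut-off (BOC).** Branches are ordered like Strahler
   stream orders (leaves = 1; equal orders meeting → order + 1). Candidate
   centres are the maximal subtrees of a target order — BOC3m uses a
   modified rule in which any branch whose highest child order is 2 becomes
   order 3, giving intermediate-sized clusters; standard BOC2 demarcates
   regions. The cut adapts to each cluster's own topology instead of a
   global phenon line.
5. **Consensus.** Strict and majority-rule consensus of the per-weighting
   trees establish a robustness hierarchy; on the majority tree the BOC3m
   clusters are Sub-CoEs and the larger nearly-basal (level-4) clusters are
   the consensus CoEs.
6. **Refinement, expansion, bridging.** Units lose endemic-free cells and
   units; unassigned cells join adjacent units greedily whenever they
   complete additional ranges (maximisation of endemism, with documented
   tie-breaks); orphan ranges found new units; remaining cells join their
   compositionally closest unit to form BRs. Analyses are compared on four
   criteria (endemics, taxa, units, cells in units) by summed competition
   ranks.

A synthetic-landscape generator plants contiguous centres with a
power-law range-size distribution (exponent ≈ 1.8) so the entire chain is
testable end to end without any proprietary data.

## Worked example

```python
from endemis import generate_landscape, run_coe_pipeline, recovery_score, evaluate_analysis

land = generate_landscape(seed=42)          # 400 cells x 800 taxa, 4 planted centres
res = run_coe_pipeline(land.matrix, grid=land.grid)
print(evaluate_analysis(land.matrix, res.units))
print(recovery_score(land.truth, res.units))
```

prints (`examples/05_full_pipeline.py` shows the full narrative):

```
recovered units: 9 covering 212 cells, 590 endemic taxa, 671 taxa in total
adjusted Rand index vs planted patches: 1.000
```

The pipeline recovers every planted centre exactly (ARI = 1 over patch
cells); the extra units are genuine small aggregations of restricted-range
background taxa, exactly what the method is designed to surface. The other
scripts in `examples/` demonstrate one capability each: weighting schemes,
dissimilarity + Mantel comparison, UPGMA + branch orders, the consensus
hierarchy, and rank-sum comparison of analysis variants.

A thin CLI mirrors the library (`endemis simulate|refine|weight|dissim|
mantel|cluster|boc|consensus|units|refine-units|expand|bridge|rank`); run
`endemis --help` for the formats involved.

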