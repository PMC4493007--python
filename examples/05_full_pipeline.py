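"""End-to-end delimitation of planted centres of endemism.

Generates the default synthetic landscape (four contiguous patches on a
20 x 20 grid, 800 taxa with a power-law range-size distribution, 60%
patch endemics, 2% noise), runs the full pipeline - three weighting
schemes x Kulczynski-2 -> UPGMA -> majority consensus -> branch-order
cut -> endemism refinement -> grid expansion - and scores recovery.
"""
from endemis import (endemism_table, evaluate_analysis, generate_landscape,
                     recovery_score, run_coe_pipeline)

land = generate_landscape(seed=42)
print(f"landscape: {land.matrix.shape[0]} cells x {land.matrix.shape[1]} taxa, "
      f"patch sizes {[len(v) for v in land.patch_cells().values()]}")

res = run_coe_pipeline(land.matrix, grid=land.grid)
score = evaluate_analysis(land.matrix, res.units)
print(f"recovered units: {score.n_units} covering {score.n_cells} cells, "
      f"{score.n_endemics} endemic taxa, {score.n_taxa} taxa in total")

table = endemism_table(land.matrix, res.units)
for rec in table.to_records():
    print(f"  {rec['unit']}: {rec['n_cells']} cells, "
          f"{rec['n_endemics']} endemics, {rec['n_taxa']} taxa")

ari = recovery_score(land.truth, res.units)
print(f"adjusted Rand index vs planted patches: {ari:.3f}")
print("ARI of 1 means the recovered centres coincide exactly with the")
print("planted patches over patch cells; 0 would be chance agreement.")
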