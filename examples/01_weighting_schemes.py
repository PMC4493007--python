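"""Down-weighting widespread taxa: the three schemes side by side.

Builds a small matrix with one taxon per range size and prints the integer
weight (0-9) each scheme gives it. Weights fall with range size: narrow
endemics carry the biogeographic signal, widespread taxa are kept at a
floor of one.
"""
import numpy as np

from endemis import OccurrenceMatrix, assign_weights

sizes = [1, 2, 3, 5, 8, 12, 20, 40]
cells = [f"c{i:02d}" for i in range(40)]
inc = np.zeros((40, len(sizes)), dtype=int)
for j, s in enumerate(sizes):
    inc[:s, j] = 1
m = OccurrenceMatrix.from_incidence(cells, [f"range{s}" for s in sizes], inc)

weights = {scheme: assign_weights(m, scheme) for scheme in
           ("unweighted", "inverse", "bell", "integration")}

print(f"{'range':>6} " + " ".join(f"{s:>11}" for s in weights))
for s in sizes:
    row = " ".join(f"{weights[k].weights[f'range{s}']:>11}" for k in weights)
    print(f"{s:>6} {row}")
print()
print("Range-1 taxa weigh 0 everywhere: they cannot inform clustering.")
print("Bell collapses fastest (e.g. range 12 already at the floor of 1), the")
print("inverse scheme follows, and integration spreads its nine equal-area")
print("bins over the whole observed range spectrum.")
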