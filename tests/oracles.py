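"""Independent reference implementations used to cross-check the package.

These deliberately take the slow, direct route (explicit pair averaging,
recursion, numerical quadrature) so that agreement with the optimised
implementations is informative.
"""
import sys

import numpy as np

from endemis import Dendrogram, Node


def naive_upgma(labels, matrix):
    """O(n^3) UPGMA recomputing every inter-cluster average from scratch.

    Uses the same deterministic tie-break as the implementation (pair with
    the lexicographically smallest member labels) so trees are comparable
    exactly, not just statistically.
    """
    matrix = np.asarray(matrix, dtype=float)
    clusters = [[i] for i in range(len(labels))]
    nodes = [Node(label=labels[i], height=0.0) for i in range(len(labels))]

    def minlab(c):
        return min(str(labels[i]) for i in c)

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                avg = matrix[np.ix_(clusters[x], clusters[y])].mean()
                key = tuple(sorted((minlab(clusters[x]), minlab(clusters[y]))))
                if best is None or avg < best[0] - 1e-15 or (
                        abs(avg - best[0]) <= 1e-15 and key < best[1]):
                    best = (avg, key, x, y)
        avg, _, x, y = best
        a, b = nodes[x], nodes[y]
        if minlab(clusters[y]) < minlab(clusters[x]):
            a, b = b, a
        merged_node = Node(height=float(avg), children=[a, b])
        merged_cluster = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        nodes = [nd for k, nd in enumerate(nodes) if k not in (x, y)]
        clusters.append(merged_cluster)
        nodes.append(merged_node)
    return Dendrogram(nodes[0])


def recursive_strahler(node, modified=False):
    """Textbook recursive branch-order definition."""
    sys.setrecursionlimit(10000)
    if node.is_leaf:
        return 1
    orders = [recursive_strahler(c, modified) for c in node.children]
    m = max(orders)
    o = m + 1 if orders.count(m) >= 2 else m
    if modified and m == 2:
        o = 3
    return o


def quadrature_bin_boundary(c, b, x_min, x_max, k, n_bins=9):
    """k-th equal-area boundary of y = c x^b by quadrature plus bisection."""
    from scipy import integrate

    def area(lo, hi):
        val, _ = integrate.quad(lambda x: c * x ** b, lo, hi)
        return val

    total = area(x_min, x_max)
    target = total * k / n_bins
    lo, hi = x_min, x_max
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if area(x_min, mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
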