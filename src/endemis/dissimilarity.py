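"""Weighted presence-absence dissimilarity between cells, and Mantel tests.

For two cells the classical 2x2 quantities are weight sums rather than raw
counts: ``a`` over taxa shared by both cells, ``b`` over taxa unique to the
first, ``c`` over taxa unique to the second. Because weights are realised by
column duplication, these weighted sums coincide exactly with plain counts
on the expanded matrix.

Coefficients (as dissimilarities in [0, 1]):

* Jaccard          ``1 - a / (a + b + c)``
* Simpson (beta-sim) ``min(b, c) / (min(b, c) + a)`` - a pure turnover
  measure, already a dissimilarity (0 for fully nested pairs);
* Kulczynski-2     ``1 - (a/(a+b) + a/(a+c)) / 2`` - one-complement of the
  mean of the two shared proportions.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dendrogram import Dendrogram, upgma_from_matrix
from .errors import AlignmentError, DomainError, ValidationError
from .occurrence import OccurrenceMatrix
from .weighting import WeightVector

__all__ = [
    "SimilarityCounts",
    "DissimilarityMatrix",
    "MantelResult",
    "COEFFICIENTS",
    "pairwise_counts",
    "coefficient_dissimilarity",
    "build_dissimilarity_matrix",
    "mantel_test",
    "correlation_dendrogram",
]

COEFFICIENTS = ("jaccard", "simpson", "kulczynski2")


@dataclass
class SimilarityCounts:
    """Weight sums of shared (`a`) and one-sided (`b`, `c`) taxa."""

    a: float
    b: float
    c: float


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise cell dissimilarities in [0, 1], zero diagonal."""

    labels: list
    values: np.ndarray
    coefficient: str = ""
    weighting: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("diagonal is not zero")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValidationError("entries outside [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries as a flat vector (row-major)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DissimilarityMatrix":
        idx = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in idx]
        if missing:
            raise AlignmentError(f"labels not in matrix: {missing}")
        order = [idx[l] for l in labels]
        return DissimilarityMatrix(list(labels), self.values[np.ix_(order, order)],
                                   self.coefficient, self.weighting)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, coefficient: str = "", weighting: str = "") -> "DissimilarityMatrix":
        df = pd.read_csv(Path(path), index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float),
                   coefficient, weighting)


@dataclass
class MantelResult:
    """Pearson matrix correlation with a one-tailed permutation p-value."""

    r: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Counts and coefficients
# ---------------------------------------------------------------------------

def pairwise_counts(m: OccurrenceMatrix, w: WeightVector,
                    cell_x: str, cell_y: str) -> SimilarityCounts:
    """Weighted a/b/c counts for one cell pair."""
    wx = w.vector(m.taxa)
    x = m.cell_row(cell_x).astype(float)
    y = m.cell_row(cell_y).astype(float)
    tx, ty = float(wx @ x), float(wx @ y)
    for cell, tot in ((cell_x, tx), (cell_y, ty)):
        if tot <= 0:
            raise ValidationError(f"empty cell (zero total weight): {cell!r}")
    a = float(wx @ (x * y))
    return SimilarityCounts(a=a, b=tx - a, c=ty - a)


def coefficient_dissimilarity(counts: SimilarityCounts, kind: str) -> float:
    """Dissimilarity in [0, 1] from a/b/c counts under the named coefficient."""
    a, b, c = counts.a, counts.b, counts.c
    if a + b <= 0 or a + c <= 0:
        raise DomainError(f"degenerate counts a={a}, b={b}, c={c}: "
                          "each cell must contain at least one weighted taxon")
    if kind == "jaccard":
        return 1.0 - a / (a + b + c)
    if kind == "simpson":
        mn = min(b, c)
        return mn / (mn + a) if (mn + a) > 0 else 0.0
    if kind == "kulczynski2":
        return 1.0 - 0.5 * (a / (a + b) + a / (a + c))
    raise DomainError(f"unknown coefficient {kind!r}; choose from {COEFFICIENTS}")


def build_dissimilarity_matrix(m: OccurrenceMatrix, w: WeightVector,
                               kind: str) -> DissimilarityMatrix:
    """All unordered cell pairs under one coefficient, labels in input order."""
    if kind not in COEFFICIENTS:
        raise DomainError(f"unknown coefficient {kind!r}; choose from {COEFFICIENTS}")
    wx = w.vector(m.taxa)
    X = m.incidence.astype(float)
    totals = X @ wx
    empty = [c for c, t in zip(m.cells, totals) if t <= 0]
    if empty:
        raise ValidationError(f"empty cells (zero total weight): {empty}")
    A = (X * wx) @ X.T  # A[i, j] = weighted count of shared taxa
    tx = totals[:, None]
    ty = totals[None, :]
    B = tx - A
    C = ty - A
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "jaccard":
            D = 1.0 - A / (tx + ty - A)
        elif kind == "simpson":
            mn = np.minimum(B, C)
            D = mn / (mn + A)
            D = np.where((mn + A) > 0, D, 0.0)
        else:
            D = 1.0 - 0.5 * (A / tx + A / ty)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(list(m.cells), D, coefficient=kind, weighting=w.scheme)


# ---------------------------------------------------------------------------
# Mantel comparison of dissimilarity matrices
# ---------------------------------------------------------------------------

def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u * u).sum() * (v * v).sum())
    if denom == 0:
        raise DomainError("constant dissimilarities: correlation undefined")
    return float((u * v).sum() / denom)


def mantel_test(d1: DissimilarityMatrix, d2: DissimilarityMatrix,
                n_permutations: int = 999, seed: int = 0) -> MantelResult:
    """Mantel test with Pearson correlation on the triangle vectors.

    The p-value is the one-tailed, +1-corrected share of joint row/column
    permutations of the second matrix whose correlation is at least the
    observed one.
    """
    if d1.labels != d2.labels:
        diff = set(d1.labels) ^ set(d2.labels)
        raise AlignmentError(
            f"label mismatch between matrices (symmetric difference: {sorted(diff)[:6]})"
        )
    n = len(d1.labels)
    if n < 3:
        raise ValidationError("Mantel test needs at least 3 cells")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    r_obs = _pearson(v1, d2.values[iu])
    rng = np.random.default_rng(seed)
    u = v1 - v1.mean()
    su = np.sqrt((u * u).sum())
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        vp = d2.values[np.ix_(perm, perm)][iu]
        vp = vp - vp.mean()
        r_perm = float((u * vp).sum() / (su * np.sqrt((vp * vp).sum())))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_permutations)


def correlation_dendrogram(matrices: Sequence[DissimilarityMatrix],
                           names: Optional[Sequence[str]] = None) -> Dendrogram:
    """UPGMA tree of (1 - Pearson r) between dissimilarity matrices.

    Summarises how strongly the matrices (e.g. the weighting x coefficient
    combinations) agree; matrices must share the same labels in the same
    order. Negative correlations yield heights above 1; UPGMA is unaffected.
    """
    if len(matrices) < 2:
        raise ValidationError("need at least two matrices")
    base = matrices[0].labels
    for d in matrices[1:]:
        if d.labels != base:
            diff = set(d.labels) ^ set(base)
            raise AlignmentError(f"matrices disagree on labels: {sorted(diff)[:6]}")
    if names is None:
        names = []
        for i, d in enumerate(matrices):
            tag = ":".join(p for p in (d.weighting, d.coefficient) if p)
            names.append(tag or f"matrix{i}")
    if len(set(names)) != len(names):
        names = [f"{nm}#{i}" for i, nm in enumerate(names)]
    k = len(matrices)
    iu = np.triu_indices(len(base), k=1)
    vecs = [d.values[iu] for d in matrices]
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            corr[i, j] = corr[j, i] = _pearson(vecs[i], vecs[j])
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return upgma_from_matrix(list(names), dist)
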