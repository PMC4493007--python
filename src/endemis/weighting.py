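"""Per-taxon integer weights on the 0-9 scale.

Widespread taxa carry little information about centres of endemism, so they
are down-weighted before dissimilarities are computed. Three schemes are
provided, all emitting integers on a 0-9 scale (a convention inherited from
character-weighting software, kept for comparability):

* **inverse** - weight proportional to 1/range: ``clamp(round(20/x), 1, 9)``;
* **bell** - exponential decay ``exp(-|a| x^p)`` rescaled to the 0-9 range,
  with defaults ``a = -0.005, p = 3``;
* **integration** - fit a power law ``y = c x^b`` to the range-size
  frequency histogram, split the area under the fitted curve between range 2
  and the largest observed range into nine equal-area bins, and weight each
  taxon 9 (first bin) down to 1 (last bin) by the bin its range falls in.

Single-cell taxa always receive weight 0 (they cannot contribute to
clustering); every other taxon receives at least 1, because even widespread
taxa carry some signal. Weights are realised in any presence-absence
coefficient by duplicating matrix columns, so the arithmetic of weighted
counts and of the expanded binary matrix is identical.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError, ValidationError
from .occurrence import OccurrenceMatrix, flag_clustering_taxa

__all__ = [
    "WeightVector",
    "BellParams",
    "PowerLawFit",
    "IntegrationBins",
    "inverse_weight",
    "bell_weight",
    "fit_power_law",
    "range_histogram",
    "integration_bins",
    "assign_integration_weights",
    "assign_weights",
    "expand_by_duplication",
    "SCHEMES",
]

SCHEMES = ("unweighted", "inverse", "bell", "integration")

MAX_WEIGHT = 9


def _round_half_away(v: float) -> int:
    """Round to nearest integer with halves away from zero (0.5 -> 1)."""
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


@dataclass
class WeightVector:
    """Taxon -> integer weight in [0, 9] under a named scheme."""

    weights: dict
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: w for t, w in self.weights.items()
               if not (0 <= int(w) <= MAX_WEIGHT)}
        if bad:
            raise ValidationError(f"weights outside [0, 9]: {dict(list(bad.items())[:5])}")
        self.weights = {t: int(w) for t, w in self.weights.items()}

    def vector(self, taxa) -> np.ndarray:
        """Weights in the given taxon order (0 for taxa with no weight)."""
        return np.array([self.weights.get(t, 0) for t in taxa], dtype=float)


@dataclass
class BellParams:
    """Parameters of the bell decay curve; ``a`` scales area, ``p`` steepness."""

    a: float = -0.005
    p: float = 3.0


@dataclass
class PowerLawFit:
    """``y = c x^b`` fitted on log-log axes by ordinary least squares."""

    c: float
    b: float
    r_squared: float

    def __call__(self, x):
        return self.c * np.asarray(x, dtype=float) ** self.b


@dataclass
class IntegrationBins:
    """Nine equal-area bins of the fitted range-size curve.

    ``boundaries`` holds the ten ascending edges x0 < x1 < ... < x9; each
    bin's definite integral of the fitted curve equals ``bin_area``.
    """

    boundaries: np.ndarray
    bin_area: float
    fit: PowerLawFit

    def weight_of(self, range_size: float) -> int:
        """Weight 9 for the first bin down to 1 for the last (closed) bin."""
        x = float(range_size)
        lo, hi = self.boundaries[0], self.boundaries[-1]
        if x < lo or x > hi:
            raise DomainError(
                f"range {range_size} outside the binned interval [{lo}, {hi}]; "
                "bins must be built from the same matrix"
            )
        j = int(np.searchsorted(self.boundaries, x, side="right"))
        j = min(j, len(self.boundaries) - 1)  # last bin is closed
        return 10 - j


# ---------------------------------------------------------------------------
# Elementary schemes
# ---------------------------------------------------------------------------

def inverse_weight(range_size: int) -> int:
    """Inverse weighting: 20/x rounded to the nearest integer, clamped to [1, 9].

    E.g. a taxon in three cells scores 1/3 * 20 ~ 6.67, rounded to 7; a
    taxon in two cells scores 10, clamped to the scale ceiling of 9.
    """
    if range_size < 2:
        raise DomainError("inverse weighting is defined for ranges >= 2 "
                          "(singletons receive weight 0 upstream)")
    raw = _round_half_away(20.0 / range_size)
    return max(1, min(MAX_WEIGHT, raw))


def bell_weight(range_size: int, params: Optional[BellParams] = None) -> int:
    """Bell weighting: exp(-|a| x^p) scaled to the 0-9 range, floored at 1."""
    params = params or BellParams()
    if range_size < 2:
        raise DomainError("bell weighting is defined for ranges >= 2")
    if params.a == 0 or params.p <= 0:
        raise ConfigurationError(
            f"bell parameters a={params.a}, p={params.p} do not produce "
            "weights that decay with range size"
        )
    raw2 = math.exp(-abs(params.a) * 2.0 ** params.p)
    raw20 = math.exp(-abs(params.a) * 20.0 ** params.p)
    if raw20 >= raw2:
        raise ConfigurationError(
            f"bell parameters a={params.a}, p={params.p} yield non-decaying weights"
        )
    raw = math.exp(-abs(params.a) * float(range_size) ** params.p)
    return max(1, min(MAX_WEIGHT, _round_half_away(MAX_WEIGHT * raw)))


# ---------------------------------------------------------------------------
# Integration weighting
# ---------------------------------------------------------------------------

def range_histogram(m: OccurrenceMatrix) -> dict:
    """Frequency of each observed full range size (bin width one cell)."""
    hist: dict = {}
    for t in m.taxa:
        s = int(m.range_sizes[t])
        hist[s] = hist.get(s, 0) + 1
    return hist


def fit_power_law(range_hist: Mapping[int, int]) -> PowerLawFit:
    """OLS of log(frequency) on log(range size) over bins with frequency > 0."""
    pairs = sorted((x, y) for x, y in range_hist.items() if y > 0)
    xs = np.array([p[0] for p in pairs], dtype=float)
    ys = np.array([p[1] for p in pairs], dtype=float)
    if len(xs) < 2:
        raise ValidationError("power-law fit needs at least two non-empty bins")
    res = stats.linregress(np.log(xs), np.log(ys))
    return PowerLawFit(c=float(np.exp(res.intercept)), b=float(res.slope),
                       r_squared=float(res.rvalue ** 2))


def _antiderivative(fit: PowerLawFit):
    if np.isclose(fit.b, -1.0):
        return lambda x: fit.c * np.log(x), lambda F: np.exp(F / fit.c)
    e = fit.b + 1.0
    return (lambda x: fit.c / e * np.asarray(x, dtype=float) ** e,
            lambda F: (e / fit.c * F) ** (1.0 / e))


def integration_bins(fit: PowerLawFit, x_min: float = 2.0,
                     x_max: float = None) -> IntegrationBins:
    """Split the area under ``c x^b`` over [x_min, x_max] into 9 equal parts.

    The interior boundaries are solved in closed form from the power-law
    antiderivative (logarithmic antiderivative when b = -1).
    """
    if x_max is None or x_max <= x_min:
        raise DomainError(f"x_max must exceed x_min={x_min}")
    F, Finv = _antiderivative(fit)
    total = F(x_max) - F(x_min)
    edges = [float(x_min)]
    for i in range(1, MAX_WEIGHT):
        edges.append(float(Finv(F(x_min) + total * i / MAX_WEIGHT)))
    edges.append(float(x_max))
    return IntegrationBins(boundaries=np.array(edges), bin_area=float(total) / MAX_WEIGHT,
                           fit=fit)


def assign_integration_weights(m: OccurrenceMatrix, bins: IntegrationBins) -> WeightVector:
    """Weight each clustering taxon by its equal-area bin; singletons get 0."""
    flags = flag_clustering_taxa(m)
    weights = {}
    for t in m.taxa:
        if t in flags.singleton_taxa:
            weights[t] = 0
        else:
            weights[t] = bins.weight_of(m.range_sizes[t])
    return WeightVector(weights=weights, scheme="integration",
                        params={"boundaries": bins.boundaries.tolist()})


# ---------------------------------------------------------------------------
# Scheme dispatcher and weighted-matrix expansion
# ---------------------------------------------------------------------------

def assign_weights(m: OccurrenceMatrix, scheme: str,
                   bell_params: Optional[BellParams] = None) -> WeightVector:
    """Compute the weight vector for a matrix under a named scheme.

    For integration weighting the power law is fitted to the matrix's own
    range-size histogram (all observed ranges) and integrated from range 2
    up to the largest observed range.
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    flags = flag_clustering_taxa(m)
    if not flags.clustering_taxa:
        raise ValidationError("no usable taxa: every taxon occupies a single cell")
    if scheme == "integration":
        fit = fit_power_law(range_histogram(m))
        x_max = max(m.range_sizes[t] for t in flags.clustering_taxa)
        bins = integration_bins(fit, x_min=2.0, x_max=float(x_max))
        return assign_integration_weights(m, bins)
    weights = {}
    for t in m.taxa:
        if t in flags.singleton_taxa:
            weights[t] = 0
        elif scheme == "unweighted":
            weights[t] = 1
        elif scheme == "inverse":
            weights[t] = inverse_weight(m.range_sizes[t])
        else:
            weights[t] = bell_weight(m.range_sizes[t], bell_params)
    params = {}
    if scheme == "bell":
        bp = bell_params or BellParams()
        params = {"a": bp.a, "p": bp.p}
    return WeightVector(weights=weights, scheme=scheme, params=params)


def expand_by_duplication(m: OccurrenceMatrix, w: WeightVector) -> OccurrenceMatrix:
    """Duplicate each taxon's column as many times as its weight.

    A taxon with weight k appears as k identical columns with suffixed ids
    (``t#1 .. t#k``); weight-0 taxa are omitted. Any presence-absence
    coefficient computed with plain counts on the expanded matrix equals the
    same coefficient computed from weighted counts on the original.
    """
    new_taxa = []
    cols = []
    ranges = {}
    for j, t in enumerate(m.taxa):
        k = w.weights.get(t, 0)
        for r in range(1, k + 1):
            tid = f"{t}#{r}"
            new_taxa.append(tid)
            cols.append(m.incidence[:, j])
            ranges[tid] = m.range_sizes[t]
    if not new_taxa:
        raise ValidationError("all weights are zero; nothing to expand")
    inc = np.stack(cols, axis=1)
    return OccurrenceMatrix(list(m.cells), new_taxa, inc, ranges)
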