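"""Weighting schemes: inverse, bell, integration, and matrix expansion."""
import math

import numpy as np
import pytest

from conftest import random_occurrence
from endemis import (BellParams, OccurrenceMatrix, PowerLawFit, assign_weights,
                     bell_weight, expand_by_duplication, fit_power_law,
                     integration_bins, inverse_weight)
from endemis.errors import ConfigurationError, DomainError
from endemis.weighting import WeightVector, assign_integration_weights
from oracles import quadrature_bin_boundary


class TestInverse:
    @pytest.mark.parametrize("rng_size,expected", [
        (3, 7),    # 1/3 * 20 = 6.67 -> 7 (the scheme's worked example)
        (2, 9),    # raw 10 clamps to the scale ceiling
        (4, 5),
        (20, 1),
        (40, 1),   # raw 0.5 rounds half away from zero to 1
    ])
    def test_values(self, rng_size, expected):
        assert inverse_weight(rng_size) == expected

    def test_singleton_range_rejected(self):
        with pytest.raises(DomainError):
            inverse_weight(1)


class TestBell:
    @pytest.mark.parametrize("x,expected", [
        (2, 9),    # exp(-0.04) * 9 = 8.65 -> 9
        (5, 5),    # exp(-0.625) * 9 = 4.82 -> 5
        (10, 1),   # exp(-5) * 9 = 0.06 -> floor of one
    ])
    def test_default_curve(self, x, expected):
        assert bell_weight(x) == expected

    def test_matches_independent_evaluation(self):
        for x in range(2, 60):
            raw = math.exp(-0.005 * x ** 3)
            expected = max(1, min(9, int(math.floor(9 * raw + 0.5))))
            assert bell_weight(x) == expected

    def test_non_decaying_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            bell_weight(5, BellParams(a=0.0, p=3))
        with pytest.raises(ConfigurationError):
            bell_weight(5, BellParams(a=-0.005, p=-1))


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        hist = {x: 100 * x ** -2.0 for x in range(2, 51)}
        fit = fit_power_law(hist)
        assert fit.b == pytest.approx(-2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_histogram_gives_zero_slope(self):
        fit = fit_power_law({x: 5 for x in range(1, 30)})
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_noisy_draw_recovers_slope(self):
        rng = np.random.default_rng(7)
        xs = np.arange(1, 80)
        freq = 4773.5 * xs ** -1.802 * np.exp(rng.normal(0, 0.15, len(xs)))
        fit = fit_power_law({int(x): float(f) for x, f in zip(xs, freq)})
        assert fit.b == pytest.approx(-1.802, abs=0.15)

    def test_single_bin_rejected(self):
        from endemis.errors import ValidationError
        with pytest.raises(ValidationError):
            fit_power_law({3: 10})


class TestIntegrationBins:
    FIT = PowerLawFit(c=4773.5, b=-1.802, r_squared=0.928)

    def test_equal_areas(self):
        bins = integration_bins(self.FIT, 2, 169)
        e = self.FIT.b + 1
        F = lambda x: self.FIT.c / e * x ** e
        areas = [F(hi) - F(lo) for lo, hi in zip(bins.boundaries, bins.boundaries[1:])]
        for a in areas:
            assert a == pytest.approx(bins.bin_area, rel=1e-6)

    def test_first_boundary_against_quadrature_oracle(self):
        bins = integration_bins(self.FIT, 2, 169)
        oracle = quadrature_bin_boundary(4773.5, -1.802, 2, 169, k=1)
        assert bins.boundaries[1] == pytest.approx(oracle, rel=1e-6)
        assert bins.boundaries[1] == pytest.approx(2.31, abs=0.01)

    def test_uniform_curve_gives_equal_spacing(self):
        bins = integration_bins(PowerLawFit(c=3.0, b=0.0, r_squared=1.0), 2, 20)
        assert np.allclose(np.diff(bins.boundaries), 2.0)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(DomainError):
            integration_bins(self.FIT, 2, 2)

    def test_range_two_always_first_bin(self):
        bins = integration_bins(self.FIT, 2, 169)
        assert bins.weight_of(2) == 9

    def test_max_range_in_closed_last_bin(self):
        bins = integration_bins(self.FIT, 2, 169)
        assert bins.weight_of(169) == 1

    def test_range_three_bin_agrees_with_quadrature_oracle(self):
        # boundaries from the quadrature oracle: x1 ~ 2.31, x2 ~ 2.71, so
        # integer range 3 falls in the third bin and weighs 7
        bins = integration_bins(self.FIT, 2, 169)
        x2 = quadrature_bin_boundary(4773.5, -1.802, 2, 169, k=2)
        assert x2 == pytest.approx(2.709, abs=0.01)
        assert x2 < 3 < quadrature_bin_boundary(4773.5, -1.802, 2, 169, k=3)
        assert bins.weight_of(3) == 7

    def test_out_of_interval_range_rejected(self):
        bins = integration_bins(self.FIT, 2, 169)
        with pytest.raises(DomainError):
            bins.weight_of(200)


class TestSchemes:
    @pytest.mark.parametrize("scheme", ["inverse", "bell", "integration"])
    def test_weights_non_increasing_in_range(self, scheme):
        # one taxon per range size from 2 to 200 on a synthetic matrix
        sizes = list(range(2, 201))
        n_cells = 200
        inc = np.zeros((n_cells, len(sizes)), dtype=int)
        for j, s in enumerate(sizes):
            inc[:s, j] = 1
        m = OccurrenceMatrix.from_incidence(
            [f"c{i}" for i in range(n_cells)], [f"t{s}" for s in sizes], inc)
        w = assign_weights(m, scheme)
        values = [w.weights[f"t{s}"] for s in sizes]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert min(values) >= 1 and max(values) <= 9

    def test_singletons_get_zero_everywhere(self, rng):
        m = random_occurrence(rng, 8, 30)
        for scheme in ("unweighted", "inverse", "bell", "integration"):
            w = assign_weights(m, scheme)
            for t in m.taxa:
                if m.range_sizes[t] == 1:
                    assert w.weights[t] == 0
                else:
                    assert w.weights[t] >= 1

    def test_bell_decays_fastest_then_inverse_then_integration(self):
        # relative weight retained at range 6 on a right-skewed histogram
        rng = np.random.default_rng(3)
        from endemis.synthetic import _sample_power_law
        sizes = _sample_power_law(rng, 1.802, 100, 2000)
        sizes = sizes[sizes >= 2]
        n_cells = 100
        inc = np.zeros((n_cells, len(sizes)), dtype=int)
        for j, s in enumerate(sizes):
            inc[: min(int(s), n_cells), j] = 1
        m = OccurrenceMatrix.from_incidence(
            [f"c{i}" for i in range(n_cells)],
            [f"t{j}" for j in range(len(sizes))], inc)
        rel = {}
        for scheme in ("bell", "inverse", "integration"):
            w = assign_weights(m, scheme)
            weights_at = {}
            for x in (2, 6, 10):
                weights_at[x] = np.mean(
                    [w.weights[t] for t in m.taxa if m.range_sizes[t] == x])
            rel[scheme] = (weights_at[6] / weights_at[2],
                           weights_at[10] / weights_at[2])
        # integer rounding makes bell and inverse coincide at range 6; the
        # strict ordering of relative decay shows by range 10
        assert rel["bell"][0] <= rel["inverse"][0] < rel["integration"][0]
        assert rel["bell"][1] < rel["inverse"][1] < rel["integration"][1]


class TestExpansion:
    def test_weight_three_gives_three_identical_columns(self):
        m = OccurrenceMatrix.from_incidence(["c1", "c2"], ["t"], [[1], [1]])
        w = WeightVector({"t": 3}, scheme="unweighted")
        ex = expand_by_duplication(m, w)
        assert ex.shape == (2, 3)
        assert (ex.incidence == 1).all()

    def test_unit_weights_preserve_shape(self, rng):
        m = random_occurrence(rng, 6, 10)
        w = WeightVector({t: 1 for t in m.taxa}, scheme="unweighted")
        ex = expand_by_duplication(m, w)
        assert ex.shape == m.shape
        assert (ex.incidence == m.incidence).all()

    def test_column_count_is_sum_of_weights(self, rng):
        m = random_occurrence(rng, 6, 20)
        w = assign_weights(m, "inverse")
        ex = expand_by_duplication(m, w)
        assert ex.shape[1] == sum(w.weights.values())
        n_clustering = sum(1 for t in m.taxa if m.range_sizes[t] >= 2)
        assert ex.shape[1] <= 9 * n_clustering
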