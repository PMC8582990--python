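"""Empirical semivariogram estimation and theoretical-model fitting."""

import numpy as np
import pytest

from asriskmap.variogram import (
    EmpiricalVariogram, VariogramModel, empirical_semivariogram, fit_model,
    model_gamma,
)
from conftest import brute_force_semivariogram


class TestModelGamma:
    def test_exponential_sill_at_infinity(self):
        m = VariogramModel("exponential", 0.01, 0.05, 10000.0)
        assert model_gamma(m, 1e12) == pytest.approx(0.06, rel=1e-12)

    def test_spherical_reaches_sill_exactly_beyond_range(self):
        m = VariogramModel("spherical", 0.02, 0.05, 15000.0)
        assert model_gamma(m, 2 * m.range_) == 0.07
        assert model_gamma(m, m.range_) == pytest.approx(0.07)

    def test_zero_lag_convention(self):
        for kind in ("spherical", "exponential", "gaussian"):
            m = VariogramModel(kind, 0.02, 0.05, 1000.0)
            assert model_gamma(m, 0.0) == 0.0

    def test_exponential_closed_form_at_the_range(self):
        m = VariogramModel("exponential", 0.01, 0.05, 10000.0)
        expected = 0.01 + 0.05 * (1 - np.exp(-3.0))
        assert model_gamma(m, 10000.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_lag_rejected(self):
        m = VariogramModel("exponential", 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            model_gamma(m, -1.0)

    @pytest.mark.parametrize("kind", ["spherical", "exponential", "gaussian"])
    def test_monotone_nondecreasing_and_bounded(self, kind):
        m = VariogramModel(kind, 0.013, 0.049, 12345.0)
        h = np.linspace(0, 10 * m.range_, 4000)
        g = model_gamma(m, h)
        assert np.all(np.diff(g) >= -1e-15)
        assert g[-1] == pytest.approx(m.sill, abs=1e-6 * m.sill)


class TestEmpirical:
    def test_two_equal_wells_give_zero(self):
        emp = empirical_semivariogram(
            [(0, 0), (100, 0)], [1.0, 1.0], bin_width=100, max_lag=150, min_pairs=1)
        assert emp.gamma == pytest.approx([0.0])

    def test_two_wells_half_squared_difference(self):
        emp = empirical_semivariogram(
            [(0, 0), (100, 0)], [0.0, 1.0], bin_width=100, max_lag=150, min_pairs=1)
        assert emp.gamma == pytest.approx([0.5])
        assert emp.pair_counts.tolist() == [1]

    def test_three_collinear_wells(self):
        emp = empirical_semivariogram(
            [(0, 0), (100, 0), (200, 0)], [0.0, 1.0, 3.0],
            bin_width=100, max_lag=250, min_pairs=1)
        assert emp.gamma == pytest.approx([1.25, 4.5])
        assert emp.lag_centers == pytest.approx([100.0, 200.0])
        assert emp.pair_counts.tolist() == [2, 1]

    @pytest.mark.parametrize("n,seed", [(10, 0), (30, 1), (50, 2)])
    def test_matches_brute_force_pair_loop(self, n, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 10000, (n, 2))
        z = rng.normal(0, 0.3, n)
        bw, ml, mp = 800.0, 7000.0, 3
        emp = empirical_semivariogram(xy, z, bin_width=bw, max_lag=ml, min_pairs=mp)
        lags, gamma, counts = brute_force_semivariogram(xy, z, bw, ml, mp)
        assert emp.pair_counts.tolist() == counts.tolist()
        np.testing.assert_allclose(emp.gamma, gamma, rtol=1e-12)
        np.testing.assert_allclose(emp.lag_centers, lags, rtol=1e-12)

    def test_duplicate_locations_excluded(self):
        emp = empirical_semivariogram(
            [(0, 0), (0, 0), (100, 0)], [0.0, 5.0, 1.0],
            bin_width=100, max_lag=150, min_pairs=1)
        # the zero-lag pair (values 0 vs 5) must not enter any bin
        assert emp.pair_counts.sum() == 2

    def test_all_pairs_beyond_max_lag_errors(self):
        with pytest.raises(ValueError, match="max_lag"):
            empirical_semivariogram([(0, 0), (5000, 0)], [0.0, 1.0],
                                    bin_width=10, max_lag=100, min_pairs=1)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            EmpiricalVariogram(np.array([1.0, 1.0]), np.array([0.1, 0.2]),
                               np.array([5, 5]))
        with pytest.raises(ValueError):
            EmpiricalVariogram(np.array([1.0, 2.0]), np.array([-0.1, 0.2]),
                               np.array([5, 5]))


class TestFit:
    @pytest.mark.parametrize("kind", ["spherical", "exponential", "gaussian"])
    def test_noiseless_inverse_recovers_parameters(self, kind):
        truth = VariogramModel(kind, 0.012, 0.05, 9000.0)
        h = np.linspace(1000, 20000, 10)
        emp = EmpiricalVariogram(h, model_gamma(truth, h), np.full(10, 40))
        fit = fit_model(emp, kind)
        assert fit.model.nugget == pytest.approx(truth.nugget, rel=1e-5, abs=1e-8)
        assert fit.model.partial_sill == pytest.approx(truth.partial_sill, rel=1e-5)
        assert fit.model.range_ == pytest.approx(truth.range_, rel=1e-5)
        assert fit.weighted_sse < 1e-10

    def test_invariant_to_common_pair_count_factor(self):
        truth = VariogramModel("exponential", 0.01, 0.06, 8000.0)
        h = np.linspace(500, 15000, 12)
        g = model_gamma(truth, h) * (1 + 0.05 * np.sin(np.arange(12)))
        f1 = fit_model(EmpiricalVariogram(h, g, np.full(12, 10)), "exponential")
        f2 = fit_model(EmpiricalVariogram(h, g, np.full(12, 70)), "exponential")
        assert f1.model == f2.model

    def test_flat_variogram_flags_unidentifiable_range(self):
        h = np.linspace(1000, 10000, 6)
        emp = EmpiricalVariogram(h, np.full(6, 0.04), np.full(6, 50))
        fit = fit_model(emp, "exponential")
        assert not fit.range_identifiable
        assert fit.model.sill == pytest.approx(0.04)

    def test_needs_four_bins(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0, 3.0]),
                                 np.array([0.1, 0.2, 0.3]), np.array([9, 9, 9]))
        with pytest.raises(ValueError, match="4 usable"):
            fit_model(emp, "exponential")
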