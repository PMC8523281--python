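"""Distribution-function, quantile and moment properties of the GLL."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import integrate, stats

from gllsurv import (
    GLLParams,
    MomentNotDefinedError,
    cdf,
    core,
    cumulants_and_shape,
    cumulative_hazard,
    galton_moors,
    hazard,
    hazard_rate_average,
    mean_variance,
    negative_moment,
    pdf,
    quantile,
    random_sample,
    raw_moment,
    residual_life_sf,
    reversed_hazard,
    reversed_residual_life_sf,
    survival,
)
from gllsurv.core import hazard_mode, logpdf

from conftest import random_params


class TestParams:
    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -2, 1), (1, 1, 0), (np.nan, 1, 1)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            GLLParams(*bad)

    def test_c_finite_positive(self, params):
        assert 0 < params.c < np.inf


class TestDensityIdentities:
    def test_pdf_normalizes(self, params):
        total, err = integrate.quad(lambda t: pdf(params, t), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_pdf_equals_hazard_times_survival(self, rng):
        for p in random_params(rng, 20):
            x = rng.uniform(0.05, 5.0)
            assert pdf(p, x) == pytest.approx(hazard(p, x) * survival(p, x), rel=1e-12)

    def test_survival_cdf_complement(self, rng):
        for p in random_params(rng, 20):
            x = rng.uniform(0.0, 8.0)
            assert survival(p, x) + cdf(p, x) == pytest.approx(1.0, abs=1e-12)

    def test_boundary_values(self):
        assert survival(GLLParams(2, 1, 1), 0.0) == 1.0
        assert cdf(GLLParams(2, 1, 1), 0.0) == 0.0
        # alpha = kappa = eta = 1: f(0) = k = 1
        assert pdf(GLLParams(1, 1, 1), 0.0) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pdf(GLLParams(1, 1, 1), -0.5)


class TestHazard:
    def test_constant_exponential_limit(self):
        # alpha = 1 with vanishing tail rate: constant hazard = kappa
        p = GLLParams(1.0, 2.0, 1e-9)
        x = np.array([0.1, 1.0, 5.0, 50.0])
        assert hazard(p, x) == pytest.approx(2.0, rel=1e-6)

    def test_loglogistic_value(self):
        # kappa = eta reduces to the two-parameter log-logistic hazard
        assert hazard(GLLParams(2, 1, 1), 1.0) == pytest.approx(1.0)

    def test_mode_matches_grid_argmax(self):
        p = GLLParams(3.0, 0.5, 0.25)
        grid = np.linspace(1e-3, 50, 200_001)
        h = hazard(p, grid)
        assert grid[np.argmax(h)] == pytest.approx(hazard_mode(p), abs=5e-4)
        assert hazard_mode(p) == pytest.approx(2 ** (1 / 3) / 0.25)

    def test_nonincreasing_for_small_alpha(self):
        p = GLLParams(0.7, 1.0, 1.0)
        grid = np.linspace(0.01, 20, 500)
        h = hazard(p, grid)
        assert np.all(np.diff(h) <= 1e-12)

    def test_at_zero_conventions(self):
        assert hazard(GLLParams(2, 1, 1), 0.0) == 0.0
        assert hazard(GLLParams(1, 3, 1), 0.0) == pytest.approx(3.0)
        assert np.isinf(hazard(GLLParams(0.5, 1, 1), 0.0))


class TestSubmodelReductions:
    def test_loglogistic_when_rates_equal(self, rng):
        for _ in range(20):
            a, k = np.exp(rng.uniform(-1, 1, 2))
            x = rng.uniform(0.05, 5)
            p = GLLParams(a, k, k)
            assert logpdf(p, x) == pytest.approx(
                stats.fisk.logpdf(x, a, scale=1 / k), rel=1e-10)

    def test_standard_loglogistic(self):
        p = GLLParams(1.7, 1.0, 1.0)
        x = np.linspace(0.1, 5, 50)
        np.testing.assert_allclose(pdf(p, x), stats.fisk.pdf(x, 1.7), rtol=1e-12)

    def test_burr_xii_reduction(self):
        # eta = kappa * lambda^(-1/alpha) gives the Burr XII hazard; with
        # lambda = kappa^alpha the reduced hazard is alpha k^alpha x^(a-1)/(1+x^a)
        a, k = 1.5, 2.0
        lam = k**a
        p = GLLParams(a, k, k * lam ** (-1 / a))
        x = np.linspace(0.1, 5, 50)
        d = k**a  # Burr XII tail parameter
        expected = stats.burr12.pdf(x, a, d) / stats.burr12.sf(x, a, d)
        np.testing.assert_allclose(hazard(p, x), expected, rtol=1e-10)

    def test_weibull_limit(self):
        a, k = 1.8, 0.7
        p = GLLParams(a, k, 1e-8)
        x = np.linspace(0.01, 10, 100)
        expected = a * k * (k * x) ** (a - 1)
        np.testing.assert_allclose(hazard(p, x), expected, rtol=1e-5)


class TestCumulativeHazard:
    def test_equals_minus_log_survival(self, rng):
        for p in random_params(rng, 20):
            x = rng.uniform(0.1, 5)
            s = survival(p, x)
            if s == 0.0:  # -log S overflows double precision; identity unverifiable
                continue
            assert cumulative_hazard(p, x) == pytest.approx(-np.log(s), rel=1e-12)

    def test_zero_at_origin(self, params):
        assert cumulative_hazard(params, 0.0) == 0.0

    def test_matches_quadrature_of_hazard(self):
        p = GLLParams(2.0, 1.0, 0.5)
        val, _ = integrate.quad(lambda t: hazard(p, t), 0, 3.0, limit=200)
        assert cumulative_hazard(p, 3.0) == pytest.approx(val, abs=1e-6)

    def test_average_identities(self, rng):
        for p in random_params(rng, 10):
            x = rng.uniform(0.1, 5)
            assert hazard_rate_average(p, x) == pytest.approx(cumulative_hazard(p, x) / x)
        # exponential limit: HRA constant = kappa
        p = GLLParams(1.0, 1.5, 1e-9)
        grid = np.array([0.5, 1, 2, 5])
        np.testing.assert_allclose(hazard_rate_average(p, grid), 1.5, rtol=1e-6)

    def test_average_decreasing_for_decreasing_hazard(self):
        p = GLLParams(0.5, 1.0, 1.0)
        grid = np.linspace(0.1, 10, 200)
        h = hazard_rate_average(p, grid)
        assert np.all(np.diff(h) < 0)


class TestReversedHazard:
    def test_defining_identity(self, rng):
        for p in random_params(rng, 20):
            x = rng.uniform(0.05, 5)
            assert reversed_hazard(p, x) * cdf(p, x) == pytest.approx(pdf(p, x), rel=1e-12)

    def test_hazard_relationship(self, rng):
        # r = h S / (1 - S)
        for p in random_params(rng, 20):
            x = rng.uniform(0.05, 5)
            expected = hazard(p, x) * survival(p, x) / (1 - survival(p, x))
            assert reversed_hazard(p, x) == pytest.approx(expected, rel=1e-9)

    def test_vanishes_at_infinity(self):
        assert reversed_hazard(GLLParams(1.5, 1, 1), 1e6) < 1e-8

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            reversed_hazard(GLLParams(1, 1, 1), 0.0)


class TestQuantile:
    # reference quantiles for (kappa, alpha, eta) triples, frozen from the
    # closed form and cross-checked against the published table
    @pytest.mark.parametrize("k,a,e,p,expected", [
        (0.5, 0.5, 0.5, 0.9, 162.0000),
        (5.0, 1.5, 1.5, 0.5, 0.1627),
        (3.0, 2.0, 3.0, 0.5, 0.3333),
        (4.0, 4.0, 2.5, 0.5, 0.2312),
        (5.0, 3.0, 2.0, 0.9, 0.2707),
    ])
    def test_reference_values(self, k, a, e, p, expected):
        # the reference table prints 4 decimals (truncated, not rounded)
        assert quantile(GLLParams(a, k, e), p) == pytest.approx(expected, abs=1e-4)

    def test_survival_at_upper_decile(self):
        assert survival(GLLParams(0.5, 0.5, 0.5), 162.0) == pytest.approx(0.1, abs=1e-6)

    def test_median_inversion(self):
        assert cdf(GLLParams(2.0, 3.0, 3.0), 0.33333) == pytest.approx(0.5, abs=1e-4)

    def test_zero_and_domain(self, params):
        assert quantile(params, 0.0) == 0.0
        for bad in (-0.01, 1.0, 1.5):
            with pytest.raises(ValueError):
                quantile(params, bad)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        a=st.floats(0.3, 5.0), k=st.floats(0.3, 5.0), e=st.floats(0.3, 5.0),
        p=st.floats(0.001, 0.995),
    )
    def test_cdf_inverts_quantile(self, a, k, e, p):
        par = GLLParams(a, k, e)
        with np.errstate(over="ignore"):
            q = quantile(par, p)
        # extremely heavy-tailed triples can have quantiles beyond double range
        assume(np.isfinite(q))
        assert cdf(par, q) == pytest.approx(p, abs=1e-10)

    def test_strictly_increasing(self, params):
        p = np.linspace(0.01, 0.99, 99)
        q = quantile(params, p)
        assert np.all(np.diff(q) > 0)


class TestRandomSample:
    def test_deterministic_given_seed(self):
        p = GLLParams(1.5, 1, 1)
        a = random_sample(p, 500, seed=123)
        b = random_sample(p, 500, seed=123)
        np.testing.assert_array_equal(a, b)

    def test_positive_and_size(self):
        x = random_sample(GLLParams(0.9, 0.5, 2.5), 1000, seed=0)
        assert x.shape == (1000,) and np.all(x > 0)
        with pytest.raises(ValueError):
            random_sample(GLLParams(1, 1, 1), 0, seed=0)

    def test_ks_against_cdf(self):
        p = GLLParams(1.5, 1, 1)
        x = random_sample(p, 100_000, seed=1)
        d = stats.kstest(x, lambda t: cdf(p, t)).statistic
        assert d < 0.01

    def test_sample_median_matches_quantile(self):
        p = GLLParams(2.0, 3.0, 3.0)
        x = random_sample(p, 1_000_000, seed=2)
        assert np.median(x) == pytest.approx(0.3333, abs=0.003)


class TestMoments:
    @pytest.mark.parametrize("k,a,e,expected", [
        (4.0, 4.5, 0.2, 0.2281),
        (5.0, 4.0, 0.5, 0.1813),
    ])
    def test_reference_means(self, k, a, e, expected):
        assert raw_moment(GLLParams(a, k, e), 1) == pytest.approx(expected, abs=5e-5)

    def test_matches_quadrature(self):
        p = GLLParams(4.0, 5.0, 0.5)
        m2 = raw_moment(p, 2)
        val, _ = integrate.quad(lambda t: t**2 * pdf(p, t), 0, np.inf, limit=200)
        assert m2 == pytest.approx(val, rel=1e-6)

    def test_heavy_tail_nonexistence(self):
        with pytest.raises(MomentNotDefinedError):
            raw_moment(GLLParams(0.5, 0.5, 0.5), 1)

    def test_negative_moment_quadrature(self):
        p = GLLParams(2.0, 1.0, 1.0)
        m = negative_moment(p, 1)
        val, _ = integrate.quad(lambda t: pdf(p, t) / t, 0, np.inf, limit=200)
        assert m == pytest.approx(val, rel=1e-6)

    def test_negative_moment_small_order_limit(self):
        assert negative_moment(GLLParams(2, 1, 1), 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_negative_moment_nonexistence(self):
        with pytest.raises(MomentNotDefinedError):
            negative_moment(GLLParams(0.8, 1, 1), 1)

    def test_negative_moment_positive_finite(self):
        m = negative_moment(GLLParams(4, 5, 0.5), 1)
        assert 0 < m < np.inf

    @pytest.mark.parametrize("k,a,e,sd", [
        (4.0, 4.5, 0.2, 0.0575),
        (5.0, 4.0, 0.5, 0.0509),
    ])
    def test_reference_sd(self, k, a, e, sd):
        _, var = mean_variance(GLLParams(a, k, e))
        assert np.sqrt(var) == pytest.approx(sd, abs=5e-5)

    def test_variance_nonnegative(self, rng):
        ok = 0
        for p in random_params(rng, 100):
            try:
                _, var = mean_variance(p)
            except MomentNotDefinedError:
                continue
            assert var >= 0
            ok += 1
        assert ok >= 30  # the grid produces plenty of finite-variance triples

    @pytest.mark.parametrize("k,a,e,cs,ck", [
        (4.0, 4.5, 0.2, -0.1784, 2.8081),
        (5.0, 4.0, 0.5, -0.0871, 2.7479),
    ])
    def test_reference_shape_measures(self, k, a, e, cs, ck):
        out = cumulants_and_shape(GLLParams(a, k, e))
        assert out["skewness"] == pytest.approx(cs, abs=5e-5)
        assert out["kurtosis"] == pytest.approx(ck, abs=5e-5)

    def test_simulated_skewness_matches_analytic(self):
        p = GLLParams(4.5, 4.0, 0.2)
        x = random_sample(p, 10_000_000, seed=3)
        assert stats.skew(x) == pytest.approx(cumulants_and_shape(p)["skewness"], abs=0.02)

    def test_cumulant_threshold(self):
        with pytest.raises(MomentNotDefinedError):
            cumulants_and_shape(GLLParams(1.5, 1.0, 1.0))  # alpha*c = 1.5 < 4


class TestGaltonMoors:
    def test_galton_bounded(self, rng):
        for p in random_params(rng, 30):
            sk, _ = galton_moors(p)
            assert abs(sk) <= 1

    def test_reference_value(self):
        # c = 1 triple: quartiles sqrt(1/3)/3, 1/3, sqrt(3)/3 give SK exactly
        sk, _ = galton_moors(GLLParams(2.0, 3.0, 3.0))
        q1, q2, q3 = np.sqrt(1 / 3) / 3, 1 / 3, np.sqrt(3) / 3
        assert sk == pytest.approx((q3 + q1 - 2 * q2) / (q3 - q1), rel=1e-10)

    def test_symmetric_quantile_function_scores_zero(self):
        # the defining ratio vanishes for any distribution symmetric about its median
        q = stats.norm(loc=3.0, scale=2.0).ppf(np.arange(1, 8) / 8)
        sk = (q[5] + q[1] - 2 * q[3]) / (q[5] - q[1])
        assert sk == pytest.approx(0.0, abs=1e-12)


class TestResidualLife:
    def test_no_extra_time_is_certain(self, params):
        assert residual_life_sf(params, 1.0, 0.0) == pytest.approx(1.0)

    def test_fresh_item_is_marginal_survival(self, params):
        assert residual_life_sf(params, 0.0, 1.3) == pytest.approx(survival(params, 1.3))

    def test_decreasing_in_additional_time(self):
        p = GLLParams(2, 1, 1)
        vals = residual_life_sf(p, 1.0, np.linspace(0, 5, 100))
        assert np.all(np.diff(vals) < 0)

    def test_reversed_repaired_convention(self):
        p = GLLParams(1, 1, 1)
        assert reversed_residual_life_sf(p, 2.0, 2.0) == pytest.approx(1 / survival(p, 2.0))
        assert reversed_residual_life_sf(p, 2.0, 1.0) == pytest.approx(
            survival(p, 1.0) / survival(p, 2.0))

    def test_reversed_domain_guards(self):
        p = GLLParams(1, 1, 1)
        with pytest.raises(ValueError):
            reversed_residual_life_sf(p, 2.0, 3.0)  # x > t under repaired reading
        with pytest.raises(ValueError):
            reversed_residual_life_sf(p, 2.0, 1.0, repaired=False)
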