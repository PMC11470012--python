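"""Oracle and property tests for the scout/recruit mixture densities.

Adaptive quadrature of each unnormalised integrand is the independent
oracle for the closed-form normalizers and CDFs.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import erf

from wagglemix import (
    MixtureParams,
    ParameterError,
    RecruitParams,
    ScoutParams,
    log_likelihood,
    mixture_cdf,
    mixture_pdf,
    recruit_pdf,
    sample_mixture,
    scout_pdf,
)
from wagglemix.distributions import recruit_norm, scout_norm


def quad_pdf(pdf, params, lo, hi):
    val, err = integrate.quad(lambda x: pdf(x, params), lo, hi, limit=300)
    assert err < 1e-9
    return val


class TestValidation:
    @pytest.mark.parametrize(
        "a,b,m",
        [(-0.1, 1.0, 0.0), (0.2, -1.0, 0.0), (0.2, 1.0, 5.0), (0.2, 1.0, -0.5), (0.0, 1.0, 0.0)],
    )
    def test_invalid_component_params_rejected(self, a, b, m):
        with pytest.raises(ParameterError):
            ScoutParams(a, b, m)
        with pytest.raises(ParameterError):
            RecruitParams(a, b, m)

    def test_mixture_weight_and_shared_minimum(self):
        s, r = ScoutParams(0.2, 1.0, 0.5), RecruitParams(0.3, 1.0, 0.5)
        with pytest.raises(ParameterError):
            MixtureParams(1.5, s, r)
        with pytest.raises(ParameterError):
            MixtureParams(0.5, s, RecruitParams(0.3, 1.0, 0.4))


class TestSupport:
    def test_scout_density_vanishes_outside_support(self):
        p = ScoutParams(0.2, 2.0, 0.5)
        assert scout_pdf(1 / 0.2, p) == 0.0
        assert scout_pdf(0.5 - 0.01, p) == 0.0
        assert scout_pdf(6.0, p) == 0.0

    def test_recruit_density_vanishes_outside_support(self):
        p = RecruitParams(0.15, 3.0, 0.5)
        assert recruit_pdf(1 / 0.15, p) == 0.0
        assert recruit_pdf(0.49, p) == 0.0

    def test_densities_nonnegative_on_grid(self, canonical_params):
        x = np.linspace(0.0, 8.0, 500)
        assert np.all(mixture_pdf(x, canonical_params) >= 0.0)


class TestNormalization:
    def test_scout_quadrature_example(self):
        p = ScoutParams(0.2, 2.0, 0.5)
        assert quad_pdf(scout_pdf, p, 0.5, 5.0) == pytest.approx(1.0, abs=1e-8)

    def test_recruit_quadrature_example(self):
        # this test adjudicates the normalizer's erf argument
        p = RecruitParams(0.15, 3.0, 0.5)
        assert quad_pdf(recruit_pdf, p, 0.5, 1 / 0.15) == pytest.approx(1.0, abs=1e-8)

    def test_misprinted_normalizer_fails_quadrature(self):
        # the variant with erf(a*sqrt(pi*b*m)) does not normalise the density
        a, b, m = 0.15, 3.0, 0.5
        wrong = (1 - a * m) * np.exp(-np.pi * b * (a * m) ** 2) + (
            erf(a * np.sqrt(np.pi * b * m)) - erf(np.sqrt(np.pi * b))
        ) / (2 * np.sqrt(b))
        raw, _ = integrate.quad(
            lambda x: 2 * np.pi * a**2 * b * x * np.exp(-np.pi * b * (a * x) ** 2) * (1 - a * x),
            m,
            1 / a,
        )
        assert abs(raw / wrong - 1.0) > 1e-3
        assert raw / recruit_norm(RecruitParams(a, b, m)) == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_normalizers_match_quadrature_sweep(self, random_valid_params):
        for params in random_valid_params:
            s, r = params.scout, params.recruit
            raw_s, _ = integrate.quad(
                lambda x: s.a_s * s.b_s * np.exp(-s.b_s * s.a_s * (x - s.m)) * (1 - s.a_s * x),
                s.m,
                s.upper,
            )
            raw_r, _ = integrate.quad(
                lambda x: 2 * np.pi * r.a_r**2 * r.b_r * x
                * np.exp(-np.pi * r.b_r * (r.a_r * x) ** 2) * (1 - r.a_r * x),
                r.m,
                r.upper,
                limit=200,
            )
            assert raw_s == pytest.approx(scout_norm(s), abs=1e-9)
            assert raw_r == pytest.approx(recruit_norm(r), abs=1e-9)

    def test_all_densities_integrate_to_one_sweep(self, random_valid_params):
        for params in random_valid_params:
            for pdf, pp, hi in (
                (scout_pdf, params.scout, params.scout.upper),
                (recruit_pdf, params.recruit, params.recruit.upper),
                (mixture_pdf, params, params.upper),
            ):
                val, _ = integrate.quad(lambda x: pdf(x, pp), params.m, hi, limit=300)
                assert val == pytest.approx(1.0, abs=1e-7)


class TestRayleighLimit:
    def test_recruit_reduces_to_rayleigh_for_small_ax(self):
        # with m=0 and the taper negligible over the Rayleigh bulk
        # (a*x << 1 wherever there is mass), the density matches
        # 2*pi*lam*x*exp(-pi*lam*x^2) within 1%
        a, b = 0.001, 250_000.0
        p = RecruitParams(a, b, 0.0)
        lam = a * a * b  # 0.25: Rayleigh bulk within x ~ 3, i.e. a*x <= 0.003
        x = np.linspace(0.05, 3.0, 60)
        rayleigh = 2 * np.pi * lam * x * np.exp(-np.pi * lam * x**2)
        assert np.allclose(recruit_pdf(x, p), rayleigh, rtol=0.01)

    def test_unnormalised_shape_is_tapered_rayleigh(self):
        # removing taper and normalizer recovers the Rayleigh form exactly
        a, b = 0.15, 3.0
        p = RecruitParams(a, b, 0.5)
        lam = a * a * b
        x = np.linspace(0.6, 5.0, 40)
        reconstructed = recruit_pdf(x, p) * recruit_norm(p) / (1 - a * x)
        rayleigh = 2 * np.pi * lam * x * np.exp(-np.pi * lam * x**2)
        assert np.allclose(reconstructed, rayleigh, rtol=1e-12)


class TestMixtureStructure:
    def test_degenerate_weights_select_components(self, canonical_params):
        x = np.linspace(0.5, 6.0, 50)
        ps = canonical_params
        pure_s = MixtureParams(1.0, ps.scout, ps.recruit)
        pure_r = MixtureParams(0.0, ps.scout, ps.recruit)
        assert np.array_equal(mixture_pdf(x, pure_s), scout_pdf(x, ps.scout))
        assert np.array_equal(mixture_pdf(x, pure_r), recruit_pdf(x, ps.recruit))

    def test_half_weight_is_arithmetic_mean(self, canonical_params):
        ps = canonical_params
        half = MixtureParams(0.5, ps.scout, ps.recruit)
        x = np.linspace(0.6, 4.0, 20)
        expected = 0.5 * (scout_pdf(x, ps.scout) + recruit_pdf(x, ps.recruit))
        assert np.allclose(mixture_pdf(x, half), expected, rtol=1e-12)


class TestCDF:
    def test_boundary_values(self, canonical_params):
        p = canonical_params
        assert mixture_cdf(p.m, p) == pytest.approx(0.0, abs=1e-12)
        assert mixture_cdf(p.upper, p) == pytest.approx(1.0, abs=1e-12)
        assert mixture_cdf(0.0, p) == 0.0

    def test_matches_quadrature_of_pdf(self, canonical_params):
        p = canonical_params
        val, _ = integrate.quad(lambda x: mixture_pdf(x, p), p.m, 2.0, limit=200)
        assert mixture_cdf(2.0, p) == pytest.approx(val, abs=1e-8)

    def test_monotone_and_derivative_matches_pdf(self, random_valid_params):
        for params in random_valid_params[:10]:
            grid = np.linspace(params.m, params.upper, 400)
            cdf = mixture_cdf(grid, params)
            assert np.all(np.diff(cdf) >= -1e-12)
            # central difference with small h at interior points
            pts = np.linspace(params.m + 1e-3, params.upper - 1e-3, 50)
            h = 1e-6
            deriv = (mixture_cdf(pts + h, params) - mixture_cdf(pts - h, params)) / (2 * h)
            assert np.allclose(deriv, mixture_pdf(pts, params), atol=1e-5, rtol=1e-4)


class TestLogLikelihood:
    def test_single_observation(self, canonical_params):
        x0 = 1.3
        expected = float(np.log(mixture_pdf(x0, canonical_params)))
        assert log_likelihood([x0], canonical_params) == pytest.approx(expected)

    def test_zero_density_observation_gives_minus_inf(self, canonical_params):
        assert log_likelihood([1.0, canonical_params.upper + 1.0], canonical_params) == -np.inf

    def test_matches_elementwise_sum(self, canonical_params):
        x = sample_mixture(100, canonical_params, seed=3)
        expected = float(np.sum(np.log(mixture_pdf(x, canonical_params))))
        assert log_likelihood(x, canonical_params) == pytest.approx(expected, rel=1e-12)

    def test_empty_data_rejected(self, canonical_params):
        with pytest.raises(ValueError):
            log_likelihood([], canonical_params)


class TestSampling:
    def test_same_seed_identical(self, canonical_params):
        a = sample_mixture(500, canonical_params, seed=9)
        b = sample_mixture(500, canonical_params, seed=9)
        assert np.array_equal(a, b)

    def test_support_respected_pure_scout(self, canonical_params):
        ps = canonical_params
        pure = MixtureParams(1.0, ps.scout, ps.recruit)
        x = sample_mixture(2000, pure, seed=1)
        assert np.all(x >= ps.m) and np.all(x < ps.scout.upper)

    def test_empirical_cdf_matches_model(self, canonical_params):
        # Glivenko-Cantelli at n=1e5: sup distance below 0.01
        x = np.sort(sample_mixture(100_000, canonical_params, seed=7))
        ecdf = np.arange(1, x.size + 1) / x.size
        sup = np.max(np.abs(ecdf - mixture_cdf(x, canonical_params)))
        assert sup < 0.01

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_samples_always_inside_support(self, canonical_params, seed):
        x = sample_mixture(50, canonical_params, seed=seed)
        assert np.all((x >= canonical_params.m) & (x < canonical_params.upper))
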