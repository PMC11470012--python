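"""Tests for maximum-likelihood fitting, AIC selection and the KS test."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from wagglemix import (
    FitConfig,
    MixtureParams,
    WaggleDataset,
    bootstrap_ks_gof,
    compare_models,
    fit_both,
    fit_collective,
    fit_individual,
    fit_pooled,
    log_likelihood,
    sample_mixture,
)
from wagglemix.fitting import FitResult, _ks_stat

SCOUT_ONLY = MixtureParams.from_values(p=1.0, a_s=0.2, b_s=2.0, a_r=0.2, b_r=2.0, m=0.5)
MIX = MixtureParams.from_values(p=0.3, a_s=0.1, b_s=0.5, a_r=0.08, b_r=39.0, m=0.2)


def make_data(params, n, seed, hive="h"):
    return WaggleDataset(hive_id=hive, durations=sample_mixture(n, params, seed=seed))


class TestIndividualFit:
    def test_parameter_recovery(self):
        # median over seeds of 2000 scout-only draws recovers a_s within
        # 10% and b_s within 20%
        a_hats, b_hats = [], []
        for s in range(20):
            fit = fit_individual(make_data(SCOUT_ONLY, 2000, 10 + s))
            a_hats.append(fit.params.scout.a_s)
            b_hats.append(fit.params.scout.b_s)
        assert abs(np.median(a_hats) / 0.2 - 1) < 0.10
        assert abs(np.median(b_hats) / 2.0 - 1) < 0.20

    def test_support_constraint_and_optimality(self):
        data = make_data(SCOUT_ONLY, 500, 3)
        fit = fit_individual(data)
        assert fit.params.scout.a_s * data.durations.max() < 1.0
        truth = MixtureParams.from_values(1.0, 0.2, 2.0, 0.2, 2.0, data.m)
        assert fit.loglik >= log_likelihood(data.durations, truth) - 1e-9

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_individual(WaggleDataset("h", [1.0] * 5))

    def test_aic_identity_and_free_params(self):
        fit = fit_individual(make_data(SCOUT_ONLY, 200, 5))
        assert fit.n_free_params == 2
        assert fit.params.p == 1.0
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik, rel=1e-15)


class TestCollectiveFit:
    def test_mixture_proportion_recovery(self):
        errs = []
        for s in range(5):
            fit = fit_collective(make_data(MIX, 2000, 40 + s))
            errs.append(abs(fit.params.p - 0.3))
        assert np.median(errs) <= 0.05

    def test_boundary_recovery_pure_scout(self):
        # generated with p=1 at the study-default scout shape (flat, long
        # ranged — a recruit hump cannot mimic it): p_hat near 1 and AIC
        # prefers the individual model.  With a steep scout truth p is
        # weakly identified at the boundary, so the flat shape is the
        # informative case.
        truth = MixtureParams.from_values(1.0, 0.1, 0.5, 0.08, 39.0, 0.2)
        phats, winners = [], []
        for s in range(5):
            data = make_data(truth, 2000, 60 + s)
            cmp_ = fit_both(data)
            phats.append(cmp_.collective.params.p)
            winners.append(cmp_.selected)
        assert np.median(phats) >= 0.95
        assert winners.count("individual") >= 4

    @pytest.mark.parametrize("params,n,seed", [(MIX, 300, 1), (SCOUT_ONLY, 300, 2), (MIX, 141, 3)])
    def test_nesting(self, params, n, seed):
        # the collective model contains the individual model
        data = make_data(params, n, seed)
        ind = fit_individual(data)
        col = fit_collective(data, individual_start=ind)
        assert col.loglik >= ind.loglik - 1e-6
        assert col.n_free_params == 5


class TestModelComparison:
    @staticmethod
    def _mk(kind, llf, k, hive="h"):
        return FitResult(
            model_kind=kind,
            hive_id=hive,
            params=MIX if kind == "collective" else SCOUT_ONLY,
            loglik=llf,
            n_free_params=k,
            nobs=100,
            converged=True,
            n_restarts_used=1,
        )

    def test_equal_loglik_penalty_arithmetic(self):
        cmp_ = compare_models(self._mk("individual", -100.0, 2), self._mk("collective", -100.0, 5))
        assert cmp_.delta_aic == pytest.approx(-6.0)
        assert cmp_.selected == "individual"

    def test_weights_sum_to_one(self):
        cmp_ = compare_models(self._mk("individual", -100.0, 2), self._mk("collective", -90.0, 5))
        assert sum(cmp_.akaike_weights) == pytest.approx(1.0, abs=1e-12)
        assert cmp_.selected == "collective"

    def test_waggle_dance_use_is_one_minus_p(self):
        cmp_ = compare_models(self._mk("individual", -100.0, 2), self._mk("collective", -90.0, 5))
        assert cmp_.waggle_dance_use == pytest.approx(1.0 - MIX.p)

    def test_mismatched_hives_rejected(self):
        with pytest.raises(ValueError, match="different hives"):
            compare_models(self._mk("individual", -1.0, 2, "a"), self._mk("collective", -1.0, 5, "b"))


class TestBootstrapKS:
    def test_stat_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=80), rng.normal(0.5, size=120)
        ours = _ks_stat(np.concatenate([x, y])[None, :], 80, 120)[0]
        assert ours == pytest.approx(ks_2samp(x, y).statistic, abs=1e-12)

    def test_reproducible_given_seed(self):
        data = make_data(MIX, 150, 1)
        fit = fit_collective(data)
        r1 = bootstrap_ks_gof(data, fit, n_boot=200, seed=5)
        r2 = bootstrap_ks_gof(data, fit, n_boot=200, seed=5)
        assert r1 == r2

    def test_model_consistent_data_accepted(self):
        data = make_data(MIX, 150, 2)
        fit = fit_collective(data)
        assert bootstrap_ks_gof(data, fit, n_boot=300, seed=1).pvalue > 0.05

    def test_power_against_uniform_data(self):
        # durations uniform on the support are rejected at n=500
        rng = np.random.default_rng(7)
        data = WaggleDataset("u", rng.uniform(0.2, 9.0, 500))
        fit = fit_collective(data)
        assert bootstrap_ks_gof(data, fit, n_boot=300, seed=2).pvalue < 0.05

    def test_non_converged_fit_refused(self):
        data = make_data(MIX, 150, 3)
        fit = fit_collective(data)
        bad = FitResult(**{**fit.__dict__, "converged": False})
        with pytest.raises(ValueError, match="non-converged"):
            bootstrap_ks_gof(data, bad, seed=0)


class TestPooled:
    def test_pooling_dataset_with_itself_matches_single_fit(self):
        data = make_data(MIX, 400, 9)
        single = fit_both(data)
        pooled = fit_pooled([data, data])
        assert pooled.pooled.collective.params.p == pytest.approx(
            single.collective.params.p, abs=1e-3
        )

    def test_heterogeneous_hives_favour_per_hive_fits(self):
        # hives with very different scout fractions: summed per-hive AIC
        # beats the pooled AIC
        from dataclasses import replace

        wins = 0
        for s in range(5):
            lo = WaggleDataset("a", sample_mixture(141, replace(MIX, p=0.1), seed=70 + s))
            hi = WaggleDataset("b", sample_mixture(141, replace(MIX, p=0.9), seed=170 + s))
            cmp_ = fit_pooled([lo, hi])
            wins += cmp_.sum_per_hive_best_aic < cmp_.pooled_best_aic
        assert wins >= 4

    def test_fewer_than_two_datasets_rejected(self):
        with pytest.raises(ValueError):
            fit_pooled([])
        with pytest.raises(ValueError):
            fit_pooled([make_data(MIX, 100, 1)])
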