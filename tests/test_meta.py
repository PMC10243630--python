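"""Stage-2 Bayesian pooling: closed-form limits, shrinkage, reproducibility."""

import numpy as np
import pytest

from comorbmeta._errors import ConfigurationError, ValidationError
from comorbmeta.meta import (
    MCMCConfig,
    MetaInput,
    meta_analyse,
    meta_input_from_exports,
    pool_ratio_scale,
    select_effects_model,
)

from conftest import gls_pool

VAGUE = MCMCConfig(prior_mu_scale=100.0, nsteps=3000, burn=1000)


def _uni(estimates, variances, **kw):
    est = np.asarray(estimates, dtype=float)[:, None]
    cov = np.asarray(variances, dtype=float)[:, None, None]
    return MetaInput("ind", "cmp", ("b",), est, cov, **kw)


class TestEffectsModelRule:
    @pytest.mark.parametrize(
        "k,sensitivity,expected",
        [(5, False, "random"), (4, False, "fixed"), (4, True, "random"),
         (1, False, "fixed"), (12, False, "random"), (5, True, "random")],
    )
    def test_threshold_and_sensitivity(self, k, sensitivity, expected):
        assert select_effects_model(k, sensitivity) == expected

    def test_configurable_threshold(self):
        assert select_effects_model(4, threshold=4) == "random"

    def test_rejects_empty_group(self):
        with pytest.raises(ConfigurationError):
            select_effects_model(0)


class TestFixedEffects:
    def test_single_trial_posterior_matches_trial_estimate(self):
        res = meta_analyse(_uni([0.42], [0.09**2]), "fixed", VAGUE, seed=1)
        assert res.mean[0] == pytest.approx(0.42, abs=0.02)
        assert np.std(res.mu_draws) == pytest.approx(0.09, rel=0.05)

    def test_two_trial_inverse_variance_closed_form(self):
        res = meta_analyse(_uni([0.0, 2.0], [1.0, 1.0]), "fixed", VAGUE, seed=2)
        mcse = np.std(res.mu_draws) / np.sqrt(res.diagnostics["min_ess"])
        assert abs(res.mean[0] - 1.0) < 4 * mcse + 1e-3
        assert np.std(res.mu_draws) == pytest.approx(np.sqrt(0.5), rel=0.05)

    def test_multivariate_matches_gls_oracle(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(0.2, 0.1, size=(4, 2))
        covs = np.array(
            [np.array([[0.02, 0.005], [0.005, 0.03]]) * (1 + 0.3 * i) for i in range(4)]
        )
        mi = MetaInput("i", "c", ("a", "b"), theta, covs)
        res = meta_analyse(mi, "fixed", VAGUE, seed=3)
        oracle_mean, oracle_cov = gls_pool(theta, covs)
        mcse = res.mu_draws.std(axis=0) / np.sqrt(res.diagnostics["min_ess"])
        assert np.all(np.abs(res.mean - oracle_mean) < 4 * mcse + 1e-3)
        assert np.allclose(res.mu_draws.std(axis=0), np.sqrt(np.diag(oracle_cov)), rtol=0.06)


class TestRandomEffects:
    def test_shrinkage_pulls_trials_toward_pooled_mean(self):
        """Every trial-specific posterior mean lies between its raw estimate
        and the pooled mean (hierarchical compression)."""
        rng = np.random.default_rng(4)
        theta = 0.2 + 0.15 * rng.normal(size=6)
        res = meta_analyse(_uni(theta, np.full(6, 0.02)), "random", seed=4)
        pooled = res.mean[0]
        for raw, shrunk in zip(theta, res.trial_posterior_means[:, 0]):
            lo, hi = sorted((raw, pooled))
            assert lo - 1e-9 <= shrunk <= hi + 1e-9

    def test_between_trial_sd_summarised(self):
        rng = np.random.default_rng(5)
        theta = 0.3 + 0.2 * rng.normal(size=8)
        res = meta_analyse(_uni(theta, np.full(8, 0.005)), "random", seed=5)
        assert res.tau_mean is not None and res.tau_mean[0] > 0.1
        assert res.tau_lower[0] <= res.tau_mean[0] <= res.tau_upper[0]

    def test_reproducible_given_seed(self):
        theta = [0.1, 0.25, 0.3, 0.15, 0.4]
        a = meta_analyse(_uni(theta, np.full(5, 0.01)), "random", seed=6)
        b = meta_analyse(_uni(theta, np.full(5, 0.01)), "random", seed=6)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.lower, b.lower)
        assert a.diagnostics == b.diagnostics

    def test_diagnostics_recorded_and_interval_ordered(self):
        res = meta_analyse(_uni([0.0, 0.1, 0.2, 0.3, 0.4], np.full(5, 0.02)), "random", seed=7)
        assert res.diagnostics["max_rhat"] <= 1.01
        assert res.diagnostics["min_ess"] >= 400
        assert res.lower[0] <= res.mean[0] <= res.upper[0]


class TestRatioScale:
    def test_null_log_coefficient_pools_to_unit_ratio(self):
        res = pool_ratio_scale(_uni([0.0], [0.04**2]), "fixed", VAGUE, seed=8)
        assert res.mean[0] == pytest.approx(1.0, abs=0.01)
        assert res.scale == "ratio"

    def test_two_identical_trials_tiny_se_recover_ratio(self):
        res = pool_ratio_scale(
            _uni([0.0953, 0.0953], [1e-6, 1e-6]), "fixed", VAGUE, seed=9
        )
        assert res.mean[0] == pytest.approx(1.10, abs=0.005)
        assert res.lower[0] <= res.mean[0] <= res.upper[0]


class TestInputValidation:
    def test_non_psd_covariance_rejected(self):
        bad = np.array([[[1.0, 2.0], [2.0, 1.0]]])  # eigenvalues -1, 3
        with pytest.raises(ValidationError, match="PSD"):
            MetaInput("i", "c", ("a", "b"), np.zeros((1, 2)), bad)

    def test_group_mixture_rejected(self, diabetes_trial, diabetes_design):
        import dataclasses

        from comorbmeta.stage1 import AnalysisSpec, fit_trial

        e1 = fit_trial(diabetes_trial, AnalysisSpec(family="age_sex"), design=diabetes_design)
        other = dataclasses.replace(diabetes_design, indication="hypertension")
        e2 = fit_trial(diabetes_trial, AnalysisSpec(family="age_sex"), design=other)
        with pytest.raises(ConfigurationError, match="multiple groups"):
            meta_input_from_exports([e1, e2], ("arm:age15",))

    def test_convergence_gate_raises_on_hopeless_budget(self):
        from comorbmeta._errors import ConvergenceError

        cfg = MCMCConfig(nsteps=60, burn=10, ess_min=5.0)
        theta = np.linspace(-0.5, 0.5, 8)
        with pytest.raises(ConvergenceError):
            meta_analyse(_uni(theta, np.full(8, 0.01)), "random", cfg, seed=10)
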