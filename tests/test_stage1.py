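"""Within-trial interaction models: design construction, fits, exports."""

import dataclasses

import numpy as np
import pytest

from comorbmeta._errors import ConfigurationError
from comorbmeta.cohorts import (
    DIABETES_PROFILE,
    GroundTruth,
    TrialDesign,
    generate_trial,
)
from comorbmeta.io import read_exports, write_exports
from comorbmeta.stage1 import (
    AnalysisSpec,
    build_design,
    comorbidity_specs,
    fit_program,
    fit_trial,
)

from conftest import make_count_design


class TestBuildDesign:
    def test_age_sex_labels_continuous(self, diabetes_trial):
        X, y, _ = build_design(diabetes_trial, AnalysisSpec(family="age_sex"))
        assert tuple(X.columns) == (
            "intercept", "baseline", "age15", "male", "arm", "arm:age15", "arm:male",
        )

    def test_count_family_appends_covariate_and_interaction(self, diabetes_trial):
        X, _, _ = build_design(diabetes_trial, AnalysisSpec(family="comorbidity_count"))
        assert tuple(X.columns)[-2:] == ("comorbidity_count", "arm:comorbidity_count")

    def test_change_measure_outcome_drops_baseline(self, diabetes_trial):
        """Outcomes that are themselves change scores (ACR-N style) are
        modelled without the baseline covariate."""
        X, _, _ = build_design(
            diabetes_trial, AnalysisSpec(family="age_sex", include_baseline=False)
        )
        assert "baseline" not in X.columns

    def test_single_sex_trial_drops_sex_terms(self, diabetes_design):
        profile = dataclasses.replace(DIABETES_PROFILE, pct_male=1.0)
        trial = generate_trial(diabetes_design, profile, seed=1)
        X, _, notices = build_design(trial, AnalysisSpec(family="age_sex"))
        assert "male" not in X.columns and "arm:male" not in X.columns
        assert any("single-sex" in n for n in notices)

    def test_extra_covariate_contract(self):
        with pytest.raises(ConfigurationError):
            AnalysisSpec(family="single_comorbidity")
        with pytest.raises(ConfigurationError):
            AnalysisSpec(family="age_sex", extra_covariate="gout")


class TestFitTrial:
    def test_noise_free_fit_recovers_truth_exactly(self):
        truth = GroundTruth(
            beta0=2.0, beta_base=0.5, beta_age=0.4, beta_sex=-0.2,
            delta=-1.0, gamma_age=0.1, gamma_sex=0.05, gamma_count=0.3,
            sigma=1e-12,
        )
        design = TrialDesign(
            "NF", "diabetes", "x", "hba1c", "continuous", "higher_worse", 4.0, 800,
            truth=truth,
        )
        trial = generate_trial(design, DIABETES_PROFILE, seed=2)
        exp = fit_trial(trial, AnalysisSpec(family="comorbidity_count"), age_center=DIABETES_PROFILE.age_mean)
        assert exp.coef("arm:comorbidity_count") == pytest.approx(0.3, abs=1e-8)
        assert exp.coef("arm") == pytest.approx(-1.0, abs=1e-8)
        assert exp.coef("baseline") == pytest.approx(0.5, abs=1e-8)
        assert exp.coef("arm:age15") == pytest.approx(0.1, abs=1e-8)

    def test_estimates_match_normal_equations_oracle(self, diabetes_trial):
        spec = AnalysisSpec(family="comorbidity_count")
        exp = fit_trial(diabetes_trial, spec)
        X, y, _ = build_design(diabetes_trial, spec)
        A = X.to_numpy()
        beta = np.linalg.solve(A.T @ A, A.T @ y.to_numpy())
        assert np.allclose(exp.estimates, beta, atol=1e-8)
        resid = y.to_numpy() - A @ beta
        s2 = resid @ resid / (len(y) - A.shape[1])
        vcov = s2 * np.linalg.inv(A.T @ A)
        assert np.allclose(exp.vcov, vcov, atol=1e-8)

    def test_vcov_diagonal_equals_se_squared(self, diabetes_trial):
        exp = fit_trial(diabetes_trial, AnalysisSpec(family="age_sex"))
        assert np.allclose(np.diag(exp.vcov), exp.se**2, rtol=0, atol=1e-10)

    def test_poisson_family_recovers_null_rate_ratio(self):
        design = TrialDesign(
            "P", "diabetes", "x", "headaches", "count", "higher_worse", 1.0, 4000,
            truth=GroundTruth(beta0=0.8, gamma_count=0.0, sigma=1.0),
        )
        trial = generate_trial(design, DIABETES_PROFILE, seed=3)
        exp = fit_trial(trial, AnalysisSpec(family="comorbidity_count", outcome_family="count"))
        est = exp.coef("arm:comorbidity_count")
        se = exp.coef_se("arm:comorbidity_count")
        assert abs(np.exp(est) - 1.0) < 3 * se  # rate ratio per count unit ~ 1

    def test_logistic_family_fits_binary_events(self):
        design = TrialDesign(
            "L", "diabetes", "x", "events", "binary", "higher_worse", 1.0, 3000,
            truth=GroundTruth(beta0=-0.5, delta=0.4, sigma=1.0),
        )
        trial = generate_trial(design, DIABETES_PROFILE, seed=4)
        exp = fit_trial(trial, AnalysisSpec(family="age_sex", outcome_family="binary"))
        assert abs(exp.coef("arm") - 0.4) < 3 * exp.coef_se("arm")

    def test_logistic_separation_falls_back_with_warning(self):
        import pandas as pd

        n = 200
        rng = np.random.default_rng(5)
        x = rng.normal(size=n)
        trial = pd.DataFrame(
            {
                "trial_id": "SEP",
                "arm": (np.arange(n) % 2),
                "age": 50 + 10 * x,
                "male": rng.integers(0, 2, n),
                "event": (x > 0).astype(int),  # separated by age
            }
        )
        with pytest.warns(UserWarning, match="separation"):
            exp = fit_trial(
                trial, AnalysisSpec(family="age_sex", outcome_family="binary")
            )
        assert np.all(np.isfinite(exp.se))
        assert exp.metadata.get("separation_fallback")


class TestFitProgram:
    def test_six_comorbidities_modelled_separately(self):
        tables = {
            f"T{i}": generate_trial(make_count_design(f"T{i}", 0.3, 300), DIABETES_PROFILE, seed=10 + i)
            for i in range(3)
        }
        specs = comorbidity_specs(DIABETES_PROFILE.six_comorbidities)
        exports, failures = fit_program(tables, specs)
        assert len(exports) == 18  # 3 trials x 6 comorbidities
        assert not failures
        covs = {e.spec.extra_covariate for e in exports}
        assert covs == set(DIABETES_PROFILE.six_comorbidities)

    def test_single_trial_single_spec(self, diabetes_trial):
        exports, failures = fit_program(
            {"DIA01": diabetes_trial}, [AnalysisSpec(family="age_sex")]
        )
        assert len(exports) == 1 and not failures

    def test_degenerate_trial_failure_is_collected_not_fatal(self, diabetes_trial):
        """A trial with no comorbidity variation is rank deficient for the
        count analysis; it lands in the failure log while other trials fit."""
        profile = dataclasses.replace(
            DIABETES_PROFILE, comorbidity_pmf=(1.0, 0.0, 0.0, 0.0)
        )
        bad = generate_trial(make_count_design("BAD", 0.0, 200), profile, seed=6)
        exports, failures = fit_program(
            {"BAD": bad, "GOOD": diabetes_trial},
            [AnalysisSpec(family="comorbidity_count")],
        )
        assert len(exports) == 1 and exports[0].trial_id == "DIA01"
        assert len(failures) == 1 and failures[0]["trial_id"] == "BAD"
        assert "rank deficient" in failures[0]["error"]

    def test_empty_program_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_program({}, [AnalysisSpec(family="age_sex")])


def test_export_json_round_trip(tmp_path, diabetes_trial, diabetes_design):
    exp = fit_trial(diabetes_trial, AnalysisSpec(family="comorbidity_count"),
                    design=diabetes_design)
    path = tmp_path / "exports.json"
    write_exports([exp], path)
    back = read_exports(path)[0]
    assert back.labels == exp.labels
    assert np.allclose(back.estimates, exp.estimates)
    assert np.allclose(back.vcov, exp.vcov)
    assert back.indication == "diabetes"
    assert back.metadata["outcome_name"] == "hba1c"
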