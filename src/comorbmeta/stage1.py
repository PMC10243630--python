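"""Within-trial interaction regressions (stage 1 of the two-stage meta-analysis).

For each trial the final outcome is regressed on the baseline measure (for
continuous outcomes, unless the outcome is itself a change measure such as
ACR-N), age in 15-year units, sex, treatment arm, and arm interactions with
every covariate.  Four analysis families are supported:

* ``age_sex`` — age- and sex-treatment interactions only;
* ``comorbidity_count`` — adds the comorbidity count and its arm interaction;
* ``single_comorbidity`` — adds one binary comorbidity flag (each of an
  indication's six commonest comorbidities is modelled separately);
* ``biomarker`` — adds one continuous biomarker, standardised per trial.

Continuous outcomes use ordinary least squares; count and binary outcomes use
Poisson and logistic regression.  Each fit exports the coefficient vector,
standard errors, and the full variance-covariance matrix — the only objects
that leave the trial, mirroring a secure-repository analysis in which raw
participant data cannot be exported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import statsmodels.api as sm

from ._errors import ConfigurationError, FitError
from .cohorts import TrialDesign
from .covariates import age_units

__all__ = [
    "ANALYSIS_FAMILIES",
    "AnalysisSpec",
    "CoefficientExport",
    "build_design",
    "fit_trial",
    "fit_program",
    "comorbidity_specs",
]

logger = logging.getLogger(__name__)

ANALYSIS_FAMILIES = ("age_sex", "comorbidity_count", "single_comorbidity", "biomarker")

#: Interaction labels whose stage-2 pooling the pipeline runs per family.
INTERACTION_LABELS = {
    "age_sex": ("arm:age15", "arm:male"),
    "comorbidity_count": ("arm:comorbidity_count",),
}


@dataclass(frozen=True)
class AnalysisSpec:
    """Which interaction model to fit within each trial."""

    family: str
    outcome_family: str = "continuous"
    extra_covariate: str | None = None
    include_baseline: bool = True

    def __post_init__(self) -> None:
        if self.family not in ANALYSIS_FAMILIES:
            raise ConfigurationError(
                f"family must be one of {ANALYSIS_FAMILIES}, got {self.family!r}"
            )
        needs_extra = self.family in ("single_comorbidity", "biomarker")
        if needs_extra and not self.extra_covariate:
            raise ConfigurationError(f"family {self.family!r} requires extra_covariate")
        if not needs_extra and self.extra_covariate:
            raise ConfigurationError(
                f"family {self.family!r} does not take extra_covariate"
            )

    @property
    def covariate_label(self) -> str | None:
        if self.family == "comorbidity_count":
            return "comorbidity_count"
        return self.extra_covariate


@dataclass
class CoefficientExport:
    """Stage-1 fit result: labelled estimates, SEs, and covariance matrix."""

    trial_id: str
    comparison: str
    indication: str
    spec: AnalysisSpec
    labels: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    n: int
    family: str
    metadata: dict = field(default_factory=dict)

    def validate(self) -> "CoefficientExport":
        p = len(self.labels)
        if self.estimates.shape != (p,) or self.se.shape != (p,) or self.vcov.shape != (p, p):
            raise FitError("export dimensions disagree with labels")
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
            raise FitError("vcov is not symmetric within 1e-8")
        scale = max(1.0, float(np.max(np.diag(self.vcov))))
        if np.min(np.linalg.eigvalsh(self.vcov)) < -1e-8 * scale:
            raise FitError("vcov is not positive semi-definite within tolerance")
        if not np.allclose(np.diag(self.vcov), self.se**2, atol=1e-10):
            raise FitError("diag(vcov) does not equal se^2 within 1e-10")
        if np.any(self.se < 0):
            raise FitError("negative standard error")
        return self

    def coef(self, label: str) -> float:
        return float(self.estimates[self.labels.index(label)])

    def coef_se(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])

    def subset(self, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Estimate vector and covariance block for a subset of coefficients."""
        idx = [self.labels.index(lbl) for lbl in labels]
        return self.estimates[idx], self.vcov[np.ix_(idx, idx)]

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "comparison": self.comparison,
            "indication": self.indication,
            "spec": {
                "family": self.spec.family,
                "outcome_family": self.spec.outcome_family,
                "extra_covariate": self.spec.extra_covariate,
                "include_baseline": self.spec.include_baseline,
            },
            "labels": list(self.labels),
            "estimates": self.estimates.tolist(),
            "se": self.se.tolist(),
            "vcov": self.vcov.tolist(),
            "n": int(self.n),
            "family": self.family,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientExport":
        return cls(
            trial_id=d["trial_id"],
            comparison=d["comparison"],
            indication=d["indication"],
            spec=AnalysisSpec(**d["spec"]),
            labels=tuple(d["labels"]),
            estimates=np.asarray(d["estimates"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            vcov=np.asarray(d["vcov"], dtype=float),
            n=int(d["n"]),
            family=d["family"],
            metadata=dict(d.get("metadata", {})),
        ).validate()


_OUTCOME_COLUMN = {
    "continuous": "final_outcome",
    "count": "event_count",
    "binary": "event",
}


def build_design(
    trial: pd.DataFrame,
    spec: AnalysisSpec,
    age_width: float = 15.0,
    age_center: float | None = None,
    biomarker_scaling: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Assemble the model matrix, response, and any degeneracy notices.

    Column order is fixed: intercept, baseline (continuous only), age15, male,
    arm, arm:age15, arm:male, then the family's extra covariate and its arm
    interaction.  Sex is coded male=1 / female=0; arm intervention=1.
    Complete-case: rows missing any used column are dropped.  In a single-sex
    trial the sex terms are dropped with a notice rather than failing.
    Biomarker covariates are standardised per trial (or via the supplied
    ``biomarker_scaling`` registry of (center, scale) pairs).
    """
    outcome_col = _OUTCOME_COLUMN[spec.outcome_family]
    needed = ["age", "male", "arm", outcome_col]
    use_baseline = spec.outcome_family == "continuous" and spec.include_baseline
    if use_baseline:
        needed.append("baseline_outcome")

    cov_label = spec.covariate_label
    cov_col = None
    if cov_label is not None:
        if spec.family == "single_comorbidity":
            cov_col = f"com_{cov_label}" if f"com_{cov_label}" in trial.columns else cov_label
        else:
            cov_col = cov_label
        if cov_col not in trial.columns:
            raise ConfigurationError(f"trial table lacks covariate column {cov_col!r}")
        needed.append(cov_col)

    df = trial[needed].dropna()
    notices: list[str] = []

    age15 = age_units(df["age"].to_numpy(), width=age_width, center=age_center)
    arm = df["arm"].to_numpy(dtype=float)
    male = df["male"].to_numpy(dtype=float)

    X: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    if use_baseline:
        X["baseline"] = df["baseline_outcome"].to_numpy(dtype=float)
    X["age15"] = age15
    drop_sex = df["male"].nunique() < 2
    if drop_sex:
        notices.append("single-sex trial: dropping sex main effect and interaction")
        logger.info("%s", notices[-1])
    else:
        X["male"] = male
    X["arm"] = arm
    X["arm:age15"] = arm * age15
    if not drop_sex:
        X["arm:male"] = arm * male

    if cov_label is not None:
        cov = df[cov_col].to_numpy(dtype=float)
        if spec.family == "biomarker":
            if biomarker_scaling and cov_label in biomarker_scaling:
                center, scale = biomarker_scaling[cov_label]
            else:
                center, scale = float(cov.mean()), float(cov.std(ddof=1))
            if scale <= 0:
                raise FitError(f"biomarker {cov_label!r} has zero spread in this trial")
            cov = (cov - center) / scale
        X[cov_label] = cov
        X[f"arm:{cov_label}"] = arm * cov

    Xdf = pd.DataFrame(X, index=df.index)
    y = df[outcome_col].astype(float)
    return Xdf, y, notices


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise FitError(f"design matrix is rank deficient; collinear columns: {bad}")


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """L2-penalised logistic fit used as the separation fallback.

    Returns the penalised MLE and the inverse of the penalised Hessian as an
    approximate covariance.  Intentionally biased: it trades a small, known
    shrinkage for finite, stable standard errors under (quasi-)separation.
    """

    def negll(beta):
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + alpha * beta @ beta)

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return X.T @ (p - y) + 2.0 * alpha * beta

    res = scipy.optimize.minimize(negll, np.zeros(X.shape[1]), jac=grad, method="BFGS")
    beta = res.x
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    H = (X * (p * (1 - p))[:, None]).T @ X + 2.0 * alpha * np.eye(X.shape[1])
    return beta, np.linalg.inv(H)


def fit_trial(
    trial: pd.DataFrame,
    spec: AnalysisSpec,
    design: TrialDesign | None = None,
    ridge_alpha: float = 1.0,
    **design_kwargs,
) -> CoefficientExport:
    """Fit one within-trial interaction model and export its coefficients.

    OLS for continuous outcomes, Poisson regression (log link) for counts,
    logistic regression for binary events; model-based (non-robust)
    covariance throughout.  Logistic fits that separate fall back to a
    ridge-penalised fit with a warning instead of exporting unstable SEs.
    """
    X, y, notices = build_design(trial, spec, **design_kwargs)
    _check_rank(X)
    labels = tuple(X.columns)
    arr = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    meta: dict = {"notices": notices}
    if design is not None:
        meta["outcome_name"] = design.outcome_name

    if spec.outcome_family == "continuous":
        res = sm.OLS(yv, arr).fit()
        params, vcov = res.params, np.asarray(res.cov_params())
    elif spec.outcome_family == "count":
        res = sm.GLM(yv, arr, family=sm.families.Poisson()).fit()
        if not res.converged:
            raise FitError(
                f"Poisson fit did not converge after {res.fit_history['iteration']} iterations"
            )
        params, vcov = res.params, np.asarray(res.cov_params())
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
                res = sm.GLM(yv, arr, family=sm.families.Binomial()).fit()
            if not res.converged:
                raise FitError(
                    f"logistic fit did not converge after {res.fit_history['iteration']} iterations"
                )
            params, vcov = res.params, np.asarray(res.cov_params())
            if np.any(np.sqrt(np.diag(vcov)) > 1e3):
                raise sm.tools.sm_exceptions.PerfectSeparationWarning("unstable SEs")
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
        ):
            warnings.warn(
                "logistic separation detected; using ridge-penalised fallback",
                UserWarning,
                stacklevel=2,
            )
            params, vcov = _ridge_logit(arr, yv, ridge_alpha)
            meta["separation_fallback"] = True

    vcov = 0.5 * (vcov + vcov.T)  # symmetrise floating-point asymmetry
    export = CoefficientExport(
        trial_id=str(trial["trial_id"].iloc[0]) if "trial_id" in trial else "",
        comparison=design.comparison if design else "",
        indication=design.indication if design else "",
        spec=spec,
        labels=labels,
        estimates=np.asarray(params, dtype=float),
        se=np.sqrt(np.diag(vcov)),
        vcov=vcov,
        n=len(y),
        family=spec.outcome_family,
        metadata=meta,
    )
    return export.validate()


def comorbidity_specs(
    six: Sequence[str], outcome_family: str = "continuous", include_baseline: bool = True
) -> list[AnalysisSpec]:
    """One single-comorbidity spec per condition (each modelled separately)."""
    return [
        AnalysisSpec(
            family="single_comorbidity",
            outcome_family=outcome_family,
            extra_covariate=label,
            include_baseline=include_baseline,
        )
        for label in six
    ]


def fit_program(
    trials: Mapping[str, pd.DataFrame],
    specs: Sequence[AnalysisSpec],
    designs: Mapping[str, TrialDesign] | None = None,
    **fit_kwargs,
) -> tuple[list[CoefficientExport], list[dict]]:
    """Fit every (trial, spec) pair, collecting failures instead of aborting.

    Returns ``(exports, failures)``; each failure records the trial, spec,
    and error message, and is also emitted on the module logger.
    """
    if len(trials) == 0:
        raise ConfigurationError("fit_program requires at least one trial")
    exports: list[CoefficientExport] = []
    failures: list[dict] = []
    for trial_id, table in trials.items():
        design = designs.get(trial_id) if designs else None
        for spec in specs:
            try:
                exports.append(fit_trial(table, spec, design=design, **fit_kwargs))
            except Exception as exc:  # noqa: BLE001 - failures are collected by contract
                failures.append(
                    {"trial_id": trial_id, "family": spec.family,
                     "extra_covariate": spec.extra_covariate, "error": str(exc)}
                )
                logger.warning("fit failed for %s/%s: %s", trial_id, spec.family, exc)
    return exports, failures
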