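"""Synthetic multi-trial IPD programmes with known ground truth.

Real individual-participant trial data of the kind analysed here live in
access-controlled repositories and cannot ship with an analysis pipeline.
This module generates participant-level trial tables whose marginal structure
(age, sex, comorbidity-count distribution, biomarkers) is configured per
indication, and whose outcomes follow a known data-generating model with
explicit treatment, covariate, and treatment-covariate interaction
coefficients.  Every downstream stage of the pipeline is therefore testable
against ground truth.

The 21-condition comorbidity vocabulary is the standard medication/history
derived list used in trial multimorbidity work: each participant carries a
binary flag per condition and a count equal to the number of flags set
(the index condition itself is never counted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError

__all__ = [
    "COMORBIDITIES",
    "BIOMARKERS",
    "BiomarkerDist",
    "CohortProfile",
    "GroundTruth",
    "TrialDesign",
    "expand_count_pmf",
    "sample_comorbidity_profile",
    "generate_trial",
    "generate_program",
    "DIABETES_PROFILE",
    "HYPERTENSION_PROFILE",
    "COPD_PROFILE",
]

#: The 21 predefined long-term conditions (index condition excluded from counts).
COMORBIDITIES: tuple[str, ...] = (
    "cardiovascular_disease",
    "chronic_pain",
    "arthritis",
    "affective_disorders",
    "acid_related_disorders",
    "asthma_copd",
    "diabetes_mellitus",
    "osteoporosis",
    "thyroid_disease",
    "thromboembolic_disease",
    "inflammatory_conditions",
    "benign_prostatic_hyperplasia",
    "gout",
    "glaucoma",
    "urinary_incontinence",
    "erectile_dysfunction",
    "psychotic_disorders",
    "epilepsy",
    "migraine",
    "parkinsonism",
    "dementia",
)

#: Continuous biomarkers carried on every synthetic participant record.
BIOMARKERS: tuple[str, ...] = ("egfr", "bmi", "fib4", "haemoglobin", "mid_bp")

OUTCOME_FAMILIES = ("continuous", "count", "binary")
DIRECTIONS = ("higher_worse", "higher_better")


@dataclass(frozen=True)
class BiomarkerDist:
    """Marginal distribution of a biomarker on its natural units.

    ``mean``/``sd`` are always the natural-scale moments; for
    ``dist="lognormal"`` the log-scale parameters are derived by moment
    matching, so configured and realised moments agree for both families.
    """

    mean: float
    sd: float
    dist: str = "normal"  # "normal" | "lognormal"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"biomarker sd must be > 0, got {self.sd}")
        if self.dist not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown biomarker dist {self.dist!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "normal":
            return rng.normal(self.mean, self.sd, size=n)
        s2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - s2 / 2.0
        return rng.lognormal(mu, math.sqrt(s2), size=n)


DEFAULT_BIOMARKER_PARAMS: dict[str, BiomarkerDist] = {
    "egfr": BiomarkerDist(85.0, 20.0),          # mL/min/1.73m^2
    "bmi": BiomarkerDist(29.0, 5.0, "lognormal"),  # kg/m^2
    "fib4": BiomarkerDist(1.2, 0.6, "lognormal"),  # unitless
    "haemoglobin": BiomarkerDist(140.0, 14.0),  # g/L
    "mid_bp": BiomarkerDist(100.0, 12.0),       # mmHg
}


def _validate_pmf(pmf: Sequence[float]) -> np.ndarray:
    p = np.asarray(pmf, dtype=float)
    if p.shape != (4,):
        raise ConfigurationError(
            f"comorbidity_pmf must have 4 masses (0, 1, 2, 3+), got shape {p.shape}"
        )
    for i, mass in enumerate(p):
        if not np.isfinite(mass) or mass < 0 or mass > 1:
            raise ConfigurationError(
                f"comorbidity_pmf[{i}] = {mass} is not a probability in [0, 1]"
            )
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"comorbidity_pmf sums to {p.sum()!r}, expected 1 within 1e-9"
        )
    return p


def expand_count_pmf(
    pmf: Sequence[float], n_flags: int = 21, tail_decay: float = 0.5
) -> np.ndarray:
    """Expand a (0, 1, 2, 3+) count pmf to a full pmf on 0..n_flags.

    The aggregate 3+ mass is spread over counts 3..n_flags with a truncated
    geometric tail, P(k) proportional to ``tail_decay**(k-3)``, keeping high
    counts rare as observed in trial populations.
    """
    p = _validate_pmf(pmf)
    if not (0 < tail_decay < 1):
        raise ConfigurationError(f"tail_decay must lie in (0, 1), got {tail_decay}")
    full = np.zeros(n_flags + 1)
    full[:3] = p[:3]
    k = np.arange(3, n_flags + 1)
    w = tail_decay ** (k - 3)
    full[3:] = p[3] * w / w.sum()
    return full


def sample_comorbidity_profile(
    pmf: Sequence[float],
    n: int,
    n_flags: int = 21,
    seed: int | np.random.Generator | None = None,
    tail_decay: float = 0.5,
    weights: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw comorbidity flags and counts for ``n`` participants.

    Counts are drawn from the expanded pmf; conditional on the count, the set
    of flagged conditions is drawn without replacement — uniformly by default,
    or with probability proportional to ``weights`` (Gumbel top-k sampling)
    when per-condition allocation weights are supplied.

    Returns ``(flags, counts)`` with ``flags`` an ``(n, n_flags)`` 0/1 array
    and ``counts == flags.sum(axis=1)`` by construction.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    full = expand_count_pmf(pmf, n_flags=n_flags, tail_decay=tail_decay)
    counts = rng.choice(n_flags + 1, size=n, p=full)

    if weights is None:
        logw = np.zeros(n_flags)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n_flags,) or np.any(w <= 0):
            raise ConfigurationError(
                f"weights must be {n_flags} positive values, got {w!r}"
            )
        logw = np.log(w)

    # Gumbel top-k: taking the `count` largest perturbed log-weights per row is
    # an exact draw without replacement with inclusion ordered by weight.
    keys = logw[None, :] + rng.gumbel(size=(n, n_flags))
    order = np.argsort(-keys, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(n_flags)[None, :]
    flags = (ranks < counts[:, None]).astype(np.int64)
    return flags, counts


@dataclass(frozen=True)
class CohortProfile:
    """Indication-level cohort structure used to simulate participants."""

    indication: str
    age_mean: float
    age_sd: float
    pct_male: float
    comorbidity_pmf: tuple[float, float, float, float]
    six_comorbidities: tuple[str, ...] = ()
    biomarker_params: Mapping[str, BiomarkerDist] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_PARAMS)
    )
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    #: correlation between baseline outcome and age (0 = independent draw)
    baseline_age_corr: float = 0.0
    comorbidity_weights: tuple[float, ...] | None = None
    tail_decay: float = 0.5

    def __post_init__(self) -> None:
        if self.age_sd <= 0:
            raise ConfigurationError(f"age_sd must be > 0, got {self.age_sd}")
        if not 0.0 <= self.pct_male <= 1.0:
            raise ConfigurationError(f"pct_male must lie in [0, 1], got {self.pct_male}")
        _validate_pmf(self.comorbidity_pmf)
        if self.baseline_sd <= 0:
            raise ConfigurationError(f"baseline_sd must be > 0, got {self.baseline_sd}")
        if not -1.0 < self.baseline_age_corr < 1.0:
            raise ConfigurationError("baseline_age_corr must lie in (-1, 1)")
        unknown = set(self.six_comorbidities) - set(COMORBIDITIES)
        if unknown:
            raise ConfigurationError(f"unknown comorbidity labels: {sorted(unknown)}")
        if len(self.six_comorbidities) not in (0, 6):
            raise ConfigurationError("six_comorbidities must list exactly 6 conditions")


@dataclass(frozen=True)
class GroundTruth:
    """True coefficients of the synthetic data-generating model.

    The linear predictor (identity link for continuous outcomes, log link for
    counts, logit link for binary events) is::

        beta0 + beta_base*baseline + beta_age*age15 + beta_sex*male
        + arm * (delta + gamma_age*age15 + gamma_sex*male
                 + gamma_count*count + sum gamma_comorb*flag
                 + sum gamma_biomarker*z_biomarker)

    with ``age15 = (age - cohort mean)/15`` and biomarkers standardised to
    their configured cohort mean/SD, so the gammas are the estimands the
    within-trial interaction models target.
    """

    beta0: float = 0.0
    beta_base: float = 0.5
    beta_age: float = 0.0
    beta_sex: float = 0.0
    delta: float = 0.0
    gamma_age: float = 0.0
    gamma_sex: float = 0.0
    gamma_count: float = 0.0
    gamma_comorb: Mapping[str, float] = field(default_factory=dict)
    gamma_biomarker: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, dict):
                bad = {k: v for k, v in value.items() if not np.isfinite(v)}
                if bad:
                    raise ConfigurationError(f"non-finite {name} entries: {bad}")
            elif not np.isfinite(value):
                raise ConfigurationError(f"{name} must be finite, got {value}")


@dataclass(frozen=True)
class TrialDesign:
    """Trial-level metadata: identity, outcome, MCID, and (synthetic) truth."""

    trial_id: str
    indication: str
    comparison: str
    outcome_name: str
    outcome_family: str
    direction: str
    mcid: float
    n: int
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.outcome_family not in OUTCOME_FAMILIES:
            raise ConfigurationError(
                f"outcome_family must be one of {OUTCOME_FAMILIES}, got {self.outcome_family!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.mcid <= 0:
            raise ConfigurationError(f"mcid must be > 0, got {self.mcid}")
        if self.n < 4:
            raise ConfigurationError(f"n must allow >= 2 per arm, got {self.n}")


def _comorbidity_columns(flags: np.ndarray) -> dict[str, np.ndarray]:
    return {f"com_{label}": flags[:, j] for j, label in enumerate(COMORBIDITIES)}


def generate_trial(
    design: TrialDesign,
    profile: CohortProfile,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate one randomised trial as a participant table.

    Randomisation is 1:1 (balanced permuted assignment).  The seed stream is
    split by purpose — covariates and outcome noise use independent child
    streams — so enabling or disabling an interaction coefficient never
    perturbs the covariate draws.
    """
    if design.truth is None:
        raise ConfigurationError("synthetic generation requires GroundTruth")
    if profile.indication != design.indication:
        raise ConfigurationError(
            f"profile indication {profile.indication!r} does not match "
            f"design indication {design.indication!r}"
        )
    truth = design.truth
    if design.outcome_family == "continuous" and truth.sigma <= 0:
        raise ConfigurationError(f"sigma must be > 0, got {truth.sigma}")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cov_ss, out_ss = ss.spawn(2)
    rng_cov = np.random.default_rng(cov_ss)
    rng_out = np.random.default_rng(out_ss)

    n = design.n
    arm = np.zeros(n, dtype=np.int64)
    arm[: n // 2] = 1
    rng_cov.shuffle(arm)

    age = rng_cov.normal(profile.age_mean, profile.age_sd, size=n)
    male = (rng_cov.random(n) < profile.pct_male).astype(np.int64)
    flags, counts = sample_comorbidity_profile(
        profile.comorbidity_pmf,
        n,
        seed=rng_cov,
        tail_decay=profile.tail_decay,
        weights=profile.comorbidity_weights,
    )
    biomarkers = {
        label: dist.sample(n, rng_cov) for label, dist in profile.biomarker_params.items()
    }

    rho = profile.baseline_age_corr
    z_age = (age - profile.age_mean) / profile.age_sd
    eps = rng_cov.normal(size=n)
    baseline = profile.baseline_mean + profile.baseline_sd * (
        rho * z_age + math.sqrt(1.0 - rho * rho) * eps
    )

    age15 = (age - profile.age_mean) / 15.0
    lin = truth.beta0 + truth.beta_age * age15 + truth.beta_sex * male
    if design.outcome_family == "continuous":
        lin = lin + truth.beta_base * baseline
    mod = (
        truth.delta
        + truth.gamma_age * age15
        + truth.gamma_sex * male
        + truth.gamma_count * counts
    )
    for label, g in truth.gamma_comorb.items():
        if label not in COMORBIDITIES:
            raise ConfigurationError(f"unknown comorbidity in gamma_comorb: {label!r}")
        mod = mod + g * flags[:, COMORBIDITIES.index(label)]
    for label, g in truth.gamma_biomarker.items():
        if label not in profile.biomarker_params:
            raise ConfigurationError(f"unknown biomarker in gamma_biomarker: {label!r}")
        dist = profile.biomarker_params[label]
        mod = mod + g * (biomarkers[label] - dist.mean) / dist.sd
    eta = lin + arm * mod

    data: dict[str, np.ndarray] = {
        "trial_id": np.repeat(design.trial_id, n),
        "arm": arm,
        "age": age,
        "male": male,
        **_comorbidity_columns(flags),
        "comorbidity_count": counts,
        **biomarkers,
    }
    if design.outcome_family == "continuous":
        data["baseline_outcome"] = baseline
        data["final_outcome"] = eta + rng_out.normal(0.0, truth.sigma, size=n)
    elif design.outcome_family == "count":
        data["event_count"] = rng_out.poisson(np.exp(eta))
    else:
        p = 1.0 / (1.0 + np.exp(-eta))
        data["event"] = (rng_out.random(n) < p).astype(np.int64)
    return pd.DataFrame(data)


def generate_program(
    config: Sequence[tuple[TrialDesign, CohortProfile]],
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate a multi-trial programme and return tables plus a manifest.

    The manifest records the master seed, per-trial spawn indices and designs
    (including ground truths), and the grouping of trials by
    (indication, comparison) — the unit at which stage-2 pooling operates.
    """
    if len(config) == 0:
        raise ConfigurationError("programme config must contain at least one design")
    ids = [design.trial_id for design, _ in config]
    dupes = {t for t in ids if ids.count(t) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate trial_id(s): {sorted(dupes)}")

    master = np.random.SeedSequence(seed)
    children = master.spawn(len(config))
    tables: dict[str, pd.DataFrame] = {}
    trial_entries = []
    groups: dict[tuple[str, str], list[str]] = {}
    for i, ((design, profile), child) in enumerate(zip(config, children)):
        tables[design.trial_id] = generate_trial(design, profile, seed=child)
        entry = {
            "trial_id": design.trial_id,
            "indication": design.indication,
            "comparison": design.comparison,
            "outcome_name": design.outcome_name,
            "outcome_family": design.outcome_family,
            "direction": design.direction,
            "mcid": design.mcid,
            "n": design.n,
            "spawn_index": i,
            "truth": None if design.truth is None else asdict(design.truth),
        }
        trial_entries.append(entry)
        groups.setdefault((design.indication, design.comparison), []).append(design.trial_id)
    manifest = {
        "seed": seed,
        "n_trials": len(config),
        "trials": trial_entries,
        "groups": [
            {"indication": ind, "comparison": comp, "trial_ids": tids}
            for (ind, comp), tids in sorted(groups.items())
        ],
    }
    return tables, manifest


def _weights_favouring(six: Sequence[str], boost: float = 3.0) -> tuple[float, ...]:
    return tuple(boost if label in six else 1.0 for label in COMORBIDITIES)


_DIABETES_SIX = (
    "cardiovascular_disease",
    "chronic_pain",
    "acid_related_disorders",
    "arthritis",
    "affective_disorders",
    "thyroid_disease",
)
_HYPERTENSION_SIX = (
    "chronic_pain",
    "acid_related_disorders",
    "diabetes_mellitus",
    "arthritis",
    "affective_disorders",
    "asthma_copd",
)
_COPD_SIX = (
    "cardiovascular_disease",
    "chronic_pain",
    "acid_related_disorders",
    "affective_disorders",
    "arthritis",
    "diabetes_mellitus",
)

#: Type 2 diabetes cohort: mean age 58.7 (SD 10), 58.6% male, comorbidity-count
#: distribution 18.6% / 31.3% / 26.3% / 23.8% for 0/1/2/3+.
DIABETES_PROFILE = CohortProfile(
    indication="diabetes",
    age_mean=58.7,
    age_sd=10.0,
    pct_male=0.586,
    comorbidity_pmf=(0.186, 0.313, 0.263, 0.238),
    six_comorbidities=_DIABETES_SIX,
    comorbidity_weights=_weights_favouring(_DIABETES_SIX),
    baseline_mean=64.0,  # HbA1c mmol/mol
    baseline_sd=10.0,
)

#: Hypertension cohort: mean age 58.3 (SD 11.8), 54.4% male, counts
#: 35.7% / 36.8% / 18.9% / 8.6%.
HYPERTENSION_PROFILE = CohortProfile(
    indication="hypertension",
    age_mean=58.3,
    age_sd=11.8,
    pct_male=0.544,
    comorbidity_pmf=(0.357, 0.368, 0.189, 0.086),
    six_comorbidities=_HYPERTENSION_SIX,
    comorbidity_weights=_weights_favouring(_HYPERTENSION_SIX),
    baseline_mean=152.0,  # systolic BP mmHg
    baseline_sd=14.0,
)

#: COPD cohort: mean age 63.7 (SD 8.5), 67% male, counts
#: 22.3% / 33.5% / 25.1% / 19.1%.
COPD_PROFILE = CohortProfile(
    indication="copd",
    age_mean=63.7,
    age_sd=8.5,
    pct_male=0.67,
    comorbidity_pmf=(0.223, 0.335, 0.251, 0.191),
    six_comorbidities=_COPD_SIX,
    comorbidity_weights=_weights_favouring(_COPD_SIX),
    baseline_mean=1.4,  # FEV1, litres
    baseline_sd=0.5,
)
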