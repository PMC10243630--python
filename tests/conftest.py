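import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from comorbmeta.cohorts import (  # noqa: E402
    DIABETES_PROFILE,
    GroundTruth,
    TrialDesign,
    generate_trial,
)


@pytest.fixture(scope="session")
def diabetes_truth() -> GroundTruth:
    return GroundTruth(
        beta0=-4.0,
        beta_base=0.6,
        beta_age=0.5,
        beta_sex=0.3,
        delta=-8.0,
        gamma_age=0.2,
        gamma_count=0.6,
        sigma=8.0,
    )


@pytest.fixture(scope="session")
def diabetes_design(diabetes_truth) -> TrialDesign:
    return TrialDesign(
        trial_id="DIA01",
        indication="diabetes",
        comparison="sglt2_vs_placebo",
        outcome_name="hba1c",
        outcome_family="continuous",
        direction="higher_worse",
        mcid=4.0,
        n=1500,
        truth=diabetes_truth,
    )


@pytest.fixture(scope="session")
def diabetes_trial(diabetes_design):
    return generate_trial(diabetes_design, DIABETES_PROFILE, seed=20240901)


def make_count_design(trial_id: str, gamma_count: float, n: int, sigma: float = 8.0,
                      mcid: float = 4.0) -> TrialDesign:
    """A diabetes-like continuous-outcome design with a count interaction."""
    return TrialDesign(
        trial_id=trial_id,
        indication="diabetes",
        comparison="sglt2_vs_placebo",
        outcome_name="hba1c",
        outcome_family="continuous",
        direction="higher_worse",
        mcid=mcid,
        n=n,
        truth=GroundTruth(
            beta0=-4.0, beta_base=0.6, beta_age=0.5, beta_sex=0.3,
            delta=-8.0, gamma_count=gamma_count, sigma=sigma,
        ),
    )


def gls_pool(thetas: np.ndarray, covs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent inverse-variance / GLS oracle for fixed-effect pooling."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    covs = np.asarray(covs, dtype=float)
    if covs.ndim == 2:
        covs = covs[None]
    d = thetas.shape[1]
    prec = np.zeros((d, d))
    mom = np.zeros(d)
    for t in range(thetas.shape[0]):
        W = np.linalg.inv(covs[t])
        prec += W
        mom += W @ thetas[t]
    V = np.linalg.inv(prec)
    return V @ mom, V
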