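"""Bayesian multivariate meta-analysis of standardised interaction coefficients.

Stage 2 pools, per (indication, drug-class comparison) group, the exported
within-trial coefficient vectors.  The model is the classical multivariate
normal-normal hierarchy with known within-trial covariance:

    theta_t ~ MVN(mu + b_t, Sigma_t),   b_t ~ MVN(0, T)

where ``Sigma_t`` is fixed at the exported covariance and ``T`` is the
between-trial covariance (LKJ-style correlation with half-normal scales).
Pooling is random-effects when a group contains 5 or more trials and
fixed-effects (T = 0) otherwise, with a sensitivity switch forcing random
effects everywhere.

Sampling marginalises the trial effects analytically (theta_t ~ MVN(mu,
Sigma_t + T)) and runs an affine-invariant ensemble MCMC over (mu, log tau,
correlation) — a handful of parameters regardless of trial count.  Walkers
are treated as chains for split-R-hat/ESS diagnostics, and fits failing the
convergence gate raise rather than returning unstable summaries.  Fixed and
random effects share this sampler; the analytic inverse-variance solution is
used only as an independent oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import ConfigurationError, ConvergenceError, ValidationError
from .stage1 import CoefficientExport

__all__ = [
    "MCMCConfig",
    "MetaInput",
    "MetaResult",
    "select_effects_model",
    "meta_analyse",
    "pool_ratio_scale",
    "meta_input_from_exports",
]


def select_effects_model(
    k_trials: int, sensitivity: bool = False, threshold: int = 5
) -> str:
    """Fixed/random selection rule: random with ``threshold`` (default 5) or
    more trials in the group, fixed below it; the sensitivity analysis forces
    random effects regardless of trial count."""
    if k_trials < 1:
        raise ConfigurationError(f"k_trials must be >= 1, got {k_trials}")
    if sensitivity:
        return "random"
    return "random" if k_trials >= threshold else "fixed"


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings and the convergence gate.

    Defaults favour stable summaries: 32 walkers, 4,000 retained draws each
    after 2,000 burn-in, gate at split-R-hat <= 1.01 and bulk ESS >= 400.
    ``prior_mu_scale`` is the SD of the Normal(0, .) prior on pooled means in
    MCID units (1.0 by default: MCID-scale interactions beyond +/-1 are
    large); ``prior_tau_scale`` the half-normal scale on between-trial SDs;
    ``lkj_eta`` the LKJ concentration on random-effect correlations.
    """

    nwalkers: int = 32
    nsteps: int = 6000
    burn: int = 2000
    prior_mu_scale: float = 1.0
    prior_tau_scale: float = 0.5
    lkj_eta: float = 2.0
    rhat_max: float = 1.01
    ess_min: float = 400.0
    check_convergence: bool = True


@dataclass
class MetaInput:
    """Per-group pooling input: one estimate vector + covariance per trial."""

    indication: str
    comparison: str
    labels: tuple[str, ...]
    estimates: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d)
    ns: tuple[int, ...] = ()
    analysis: str = ""  # stage-1 analysis family these coefficients came from

    def __post_init__(self) -> None:
        self.estimates = np.atleast_2d(np.asarray(self.estimates, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]
        k, d = self.estimates.shape
        if len(self.labels) != d or self.covariances.shape != (k, d, d):
            raise ConfigurationError("MetaInput dimensions disagree")
        for t in range(k):
            S = self.covariances[t]
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValidationError(f"within-trial covariance {t} is not symmetric")
            if np.min(np.linalg.eigvalsh(S)) < -1e-10 * max(1.0, S.max()):
                raise ValidationError(f"within-trial covariance {t} is not PSD")

    @property
    def k(self) -> int:
        return self.estimates.shape[0]

    @property
    def d(self) -> int:
        return self.estimates.shape[1]


@dataclass
class MetaResult:
    """Posterior summary per pooled coefficient plus sampler diagnostics."""

    indication: str
    comparison: str
    labels: tuple[str, ...]
    mean: np.ndarray
    lower: np.ndarray  # 2.5% quantile
    upper: np.ndarray  # 97.5% quantile
    effects_model: str
    k_trials: int
    tau_mean: np.ndarray | None = None
    tau_lower: np.ndarray | None = None
    tau_upper: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None
    scale: str = "mcid"  # "mcid" | "ratio"
    analysis: str = ""
    trial_posterior_means: np.ndarray | None = None  # (k, d), random effects only
    mu_draws: np.ndarray | None = None  # (n_draws, d) pooled-mean posterior draws

    def summary_rows(self) -> list[dict]:
        rows = []
        for j, lbl in enumerate(self.labels):
            rows.append(
                {
                    "indication": self.indication,
                    "comparison": self.comparison,
                    "coefficient": lbl,
                    "mean": float(self.mean[j]),
                    "lower95": float(self.lower[j]),
                    "upper95": float(self.upper[j]),
                    "effects_model": self.effects_model,
                    "k_trials": self.k_trials,
                    "scale": self.scale,
                }
            )
        return rows


def _corr_chol(z: np.ndarray, d: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial
    correlations tanh(z), filled row by row."""
    r = np.tanh(z)
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            L[i, j] = r[idx] * np.sqrt(rem)
            rem *= 1.0 - r[idx] ** 2
            idx += 1
        L[i, i] = np.sqrt(rem)
    return L


class _MarginalModel:
    """Log-posterior of (mu, log tau, z) under the marginalised hierarchy."""

    def __init__(self, minput: MetaInput, effects_model: str, cfg: MCMCConfig):
        self.theta = minput.estimates
        self.Sigma = minput.covariances
        self.k, self.d = minput.k, minput.d
        self.random = effects_model == "random"
        self.cfg = cfg
        self.n_z = self.d * (self.d - 1) // 2 if self.random else 0
        self.ndim = self.d + (self.d + self.n_z if self.random else 0)

    # -- log-probability, vectorised over an ensemble of walkers ----------
    def log_prob(self, P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        W = P.shape[0]
        d = self.d
        mu = P[:, :d]
        lp = -0.5 * np.sum((mu / self.cfg.prior_mu_scale) ** 2, axis=1)

        if not self.random:
            return lp + self._loglik_fixed(mu)

        logtau = P[:, d : 2 * d]
        tau = np.exp(logtau)
        # half-normal prior on tau, plus the log-scale Jacobian
        lp += np.sum(-0.5 * (tau / self.cfg.prior_tau_scale) ** 2 + logtau, axis=1)
        z = P[:, 2 * d :]
        if self.n_z:
            r = np.tanh(z)
            # per-partial-correlation LKJ-style density (exact LKJ for d=2)
            # plus tanh Jacobian
            lp += np.sum(self.cfg.lkj_eta * np.log1p(-(r**2)), axis=1)
        lp += self._loglik_random(mu, tau, z)
        return lp

    def _loglik_fixed(self, mu: np.ndarray) -> np.ndarray:
        W = mu.shape[0]
        ll = np.zeros(W)
        for t in range(self.k):
            resid = self.theta[t][None, :] - mu  # (W, d)
            S = self.Sigma[t]
            if self.d == 1:
                v = S[0, 0]
                ll += -0.5 * (np.log(2 * np.pi * v) + resid[:, 0] ** 2 / v)
            else:
                sign, logdet = np.linalg.slogdet(S)
                sol = np.linalg.solve(S, resid.T)  # (d, W)
                quad = np.sum(resid.T * sol, axis=0)
                ll += -0.5 * (self.d * np.log(2 * np.pi) + logdet + quad)
        return ll

    def _loglik_random(self, mu: np.ndarray, tau: np.ndarray, z: np.ndarray) -> np.ndarray:
        W = mu.shape[0]
        if self.d == 1:
            tau2 = tau[:, 0] ** 2  # (W,)
            s2 = self.Sigma[:, 0, 0]  # (k,)
            v = s2[None, :] + tau2[:, None]  # (W, k)
            resid = self.theta[:, 0][None, :] - mu  # (W, k)
            return -0.5 * np.sum(np.log(2 * np.pi * v) + resid**2 / v, axis=1)
        if self.d == 2:
            return self._loglik_random_2d(mu, tau, z)
        ll = np.zeros(W)
        for w in range(W):
            L = _corr_chol(z[w], self.d)
            C = L @ L.T
            T = np.outer(tau[w], tau[w]) * C
            for t in range(self.k):
                V = self.Sigma[t] + T
                sign, logdet = np.linalg.slogdet(V)
                if sign <= 0:
                    return np.full(W, -np.inf)
                resid = self.theta[t] - mu[w]
                quad = resid @ np.linalg.solve(V, resid)
                ll[w] += -0.5 * (self.d * np.log(2 * np.pi) + logdet + quad)
        return ll

    def _loglik_random_2d(self, mu: np.ndarray, tau: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Closed-form 2x2 determinant/inverse, vectorised over walkers."""
        W = mu.shape[0]
        r = np.tanh(z[:, 0])
        T11 = tau[:, 0] ** 2
        T22 = tau[:, 1] ** 2
        T12 = r * tau[:, 0] * tau[:, 1]
        ll = np.zeros(W)
        for t in range(self.k):
            S = self.Sigma[t]
            a = S[0, 0] + T11
            b = S[0, 1] + T12
            c = S[1, 1] + T22
            det = a * c - b * b
            ok = det > 0
            r1 = self.theta[t, 0] - mu[:, 0]
            r2 = self.theta[t, 1] - mu[:, 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                quad = (c * r1**2 - 2 * b * r1 * r2 + a * r2**2) / det
                contrib = -0.5 * (2 * np.log(2 * np.pi) + np.log(det) + quad)
            ll += np.where(ok, contrib, -np.inf)
        return ll

    def between_cov(self, tau_w: np.ndarray, z_w: np.ndarray) -> np.ndarray:
        if self.d == 1:
            return np.array([[tau_w[0] ** 2]])
        L = _corr_chol(z_w, self.d)
        return np.outer(tau_w, tau_w) * (L @ L.T)


def _initial_state(model: _MarginalModel, rng: np.random.Generator) -> np.ndarray:
    """Walkers start around the inverse-variance (GLS) fixed-effect point."""
    k, d = model.k, model.d
    prec = np.zeros((d, d))
    mom = np.zeros(d)
    for t in range(k):
        # tiny jitter guards against exactly singular exported covariances
        Wt = np.linalg.inv(model.Sigma[t] + 1e-12 * np.eye(d))
        prec += Wt
        mom += Wt @ model.theta[t]
    prec += np.eye(d) / model.cfg.prior_mu_scale**2
    mu0 = np.linalg.solve(prec, mom)
    sd0 = np.sqrt(np.diag(np.linalg.inv(prec)))
    W = model.cfg.nwalkers
    p0 = np.empty((W, model.ndim))
    p0[:, :d] = mu0[None, :] + sd0[None, :] * rng.normal(size=(W, d))
    if model.random:
        p0[:, d : 2 * d] = np.log(0.1) + 0.4 * rng.normal(size=(W, d))
        if model.n_z:
            p0[:, 2 * d :] = 0.2 * rng.normal(size=(W, model.n_z))
    return p0


def _run_sampler(model: _MarginalModel, seed: int) -> np.ndarray:
    """Run the ensemble sampler; returns draws of shape (chain, draw, ndim)."""
    import emcee

    cfg = model.cfg
    rng = np.random.default_rng(seed)
    p0 = _initial_state(model, rng)
    # differential-evolution moves mix markedly better than the default
    # stretch move on these few-parameter, sometimes funnel-shaped posteriors
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        cfg.nwalkers, model.ndim, model.log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(seed % (2**32)).get_state()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sampler.run_mcmc(p0, cfg.nsteps, progress=False)
    chain = sampler.get_chain()  # (nsteps, nwalkers, ndim)
    return np.swapaxes(chain[cfg.burn :], 0, 1)  # (chain, draw, ndim)


def _diagnostics(draws: np.ndarray, labels: Sequence[str]) -> dict:
    import arviz as az

    ds = az.convert_to_dataset({lbl: draws[:, :, j] for j, lbl in enumerate(labels)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    max_rhat = float(max(rhat[v].values for v in rhat.data_vars))
    min_ess = float(min(ess[v].values for v in ess.data_vars))
    return {"max_rhat": max_rhat, "min_ess": min_ess, "divergences": 0}


def meta_analyse(
    minput: MetaInput,
    effects_model: str = "auto",
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    sensitivity: bool = False,
    threshold: int = 5,
) -> MetaResult:
    """Pool one group's coefficient vectors and summarise the posterior.

    ``effects_model`` may be "fixed", "random", or "auto" (apply the trial
    count rule).  Posterior means and central 95% credible intervals are
    computed per coefficient; random-effects fits additionally summarise the
    between-trial SDs and the shrunken trial-specific effects
    E[mu + b_t | data].
    """
    if minput.k < 1:
        raise ConfigurationError("meta_analyse requires at least one trial")
    if len(minput.labels) == 0:
        raise ConfigurationError("coefficient subset must be non-empty")
    if effects_model == "auto":
        effects_model = select_effects_model(minput.k, sensitivity, threshold)
    if effects_model not in ("fixed", "random"):
        raise ConfigurationError(f"unknown effects_model {effects_model!r}")
    cfg = mcmc or MCMCConfig()

    model = _MarginalModel(minput, effects_model, cfg)
    draws = _run_sampler(model, seed)
    names = [f"p{j}" for j in range(model.ndim)]
    diag = _diagnostics(draws, names)
    if cfg.check_convergence:
        if diag["max_rhat"] > cfg.rhat_max:
            raise ConvergenceError(
                f"split-R-hat {diag['max_rhat']:.4f} exceeds gate {cfg.rhat_max}; "
                "increase nsteps/burn or inspect the inputs"
            )
        if diag["min_ess"] < cfg.ess_min:
            raise ConvergenceError(
                f"bulk ESS {diag['min_ess']:.0f} below gate {cfg.ess_min:.0f}; "
                "increase nsteps or walkers"
            )

    flat = draws.reshape(-1, model.ndim)
    d = minput.d
    mu_draws = flat[:, :d]
    mean = mu_draws.mean(axis=0)
    lower, upper = np.percentile(mu_draws, [2.5, 97.5], axis=0)

    tau_mean = tau_lower = tau_upper = None
    trial_means = None
    if effects_model == "random":
        tau_draws = np.exp(flat[:, d : 2 * d])
        tau_mean = tau_draws.mean(axis=0)
        tau_lower, tau_upper = np.percentile(tau_draws, [2.5, 97.5], axis=0)
        trial_means = _shrunken_trial_means(model, flat)

    return MetaResult(
        indication=minput.indication,
        comparison=minput.comparison,
        labels=minput.labels,
        mean=mean,
        lower=lower,
        upper=upper,
        effects_model=effects_model,
        k_trials=minput.k,
        tau_mean=tau_mean,
        tau_lower=tau_lower,
        tau_upper=tau_upper,
        diagnostics=diag,
        seed=seed,
        scale="mcid",
        analysis=minput.analysis,
        trial_posterior_means=trial_means,
        mu_draws=mu_draws,
    )


def _shrunken_trial_means(model: _MarginalModel, flat: np.ndarray) -> np.ndarray:
    """Posterior mean of mu + b_t per trial via the conjugate conditional
    E[b_t | mu, T, theta_t] = T (T + Sigma_t)^{-1} (theta_t - mu), averaged
    over (thinned) posterior draws."""
    d, k = model.d, model.k
    sub = flat[:: max(1, len(flat) // 2000)]
    acc = np.zeros((k, d))
    for row in sub:
        mu = row[:d]
        T = model.between_cov(np.exp(row[d : 2 * d]), row[2 * d :])
        for t in range(k):
            gain = T @ np.linalg.inv(T + model.Sigma[t])
            acc[t] += mu + gain @ (model.theta[t] - mu)
    return acc / len(sub)


def pool_ratio_scale(
    minput: MetaInput,
    effects_model: str = "auto",
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    **kwargs,
) -> MetaResult:
    """Pool log rate/odds-ratio coefficients and report exponentiated summaries.

    Pooling is identical to :func:`meta_analyse` on the log scale; the
    reported mean and interval endpoints are exponentiated, giving the ratio
    per one-unit covariate increase (values above 1 indicate worse outcomes
    in the intervention arm).
    """
    res = meta_analyse(minput, effects_model, mcmc, seed, **kwargs)
    res.mean = np.exp(res.mean)
    res.lower = np.exp(res.lower)
    res.upper = np.exp(res.upper)
    if res.trial_posterior_means is not None:
        res.trial_posterior_means = np.exp(res.trial_posterior_means)
    res.scale = "ratio"
    return res


def meta_input_from_exports(
    exports: Sequence[CoefficientExport], labels: Sequence[str]
) -> MetaInput:
    """Assemble a pooling input from one group's standardized exports."""
    if not exports:
        raise ConfigurationError("no exports supplied")
    indications = {e.indication for e in exports}
    comparisons = {e.comparison for e in exports}
    if len(indications) > 1 or len(comparisons) > 1:
        raise ConfigurationError(
            f"exports span multiple groups: {indications} x {comparisons}"
        )
    est, cov = zip(*(e.subset(labels) for e in exports))
    return MetaInput(
        indication=exports[0].indication,
        comparison=exports[0].comparison,
        labels=tuple(labels),
        estimates=np.stack(est),
        covariances=np.stack(cov),
        ns=tuple(e.n for e in exports),
        analysis=exports[0].spec.family,
    )
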