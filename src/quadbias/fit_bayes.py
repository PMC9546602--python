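"""Hierarchical Bayesian (beta-MPT) estimation of the Quad model.

Each participant i has a parameter vector theta_i in (0,1)^5; for every
process parameter p, the population distribution is
``theta_{i,p} ~ Beta(alpha_p, beta_p)`` independently across parameters,
with group-level mean ``mu_p = alpha_p / (alpha_p + beta_p)`` and
concentration ``kappa_p = alpha_p + beta_p``.  Hyperpriors are weakly
informative: ``mu_p ~ Uniform(0, 1)`` and ``kappa_p = 2 + Exponential(rate
0.1)`` (a Gamma(1, 0.1) shifted so the Beta stays unimodal-or-flat).

Sampling is a blocked Metropolis-within-Gibbs scheme: a joint random-walk
update of each participant's logit(theta_i) (vectorized across
participants, who are conditionally independent), random-walk updates of
each (mu_p, kappa_p) on the (logit, log-shifted) scale, and an
interleaved *non-centered* update per process parameter that proposes new
hyperparameters while carrying every participant's theta along its
population quantile (theta' = F^{-1}_{alpha',beta'}(F_{alpha,beta}(theta))).
The centered and non-centered moves are complementary: the former mixes
individuals given the population, the latter moves the population and the
individuals coherently through the likelihood ridge between association
and overcoming-bias parameters.  Step sizes adapt toward a target
acceptance rate during warmup and are frozen afterwards, so the retained
draws satisfy detailed balance.  Identical configuration and seed give
identical draws.

Absolute fit is assessed with the posterior-predictive discrepancy T1:
the chi-square-style distance between observed and model-expected counts
over the 16 (cell x outcome) frequencies, compared against the same
distance for posterior-predictive replicated datasets; the posterior
predictive p-value (ppp) is the fraction of replicated discrepancies at
least as large as the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betainc, betaincinv, betaln, expit, logit

from .iat_data import ResponseCountTable
from .quad_core import PARAM_NAMES, QuadSpecification, cell_probability_array

__all__ = [
    "HierarchicalConfig",
    "PosteriorSummary",
    "T1Result",
    "FitClassification",
    "ContrastResult",
    "fit_hierarchical",
    "t1_fit",
    "classify_by_fit",
    "contrast_posterior",
    "param_vs_zero",
]


@dataclass(frozen=True)
class HierarchicalConfig:
    n_chains: int = 2
    n_warmup: int = 500
    n_samples: int = 1000  # retained per chain (after thinning)
    thinning: int = 1
    seed: int = 0
    kappa_prior_rate: float = 0.1  # kappa = 2 + Exponential(rate)
    target_accept: float = 0.35
    rhat_limit: float = 1.05
    ess_limit: float = 400.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains * self.n_samples < 2000:
            raise ValueError(
                "total retained draws must be >= 2000 for reported intervals"
            )


@dataclass
class PosteriorSummary:
    """Posterior draws and diagnostics from one hierarchical fit."""

    participant_ids: list[str]
    spec: QuadSpecification
    config: HierarchicalConfig
    group_mean_draws: dict[str, np.ndarray]  # param -> (chains, draws) in [0,1]
    kappa_draws: dict[str, np.ndarray]  # param -> (chains, draws)
    individual_draws: np.ndarray  # (chains, draws, n_participants, 5)
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def individual_estimates(self) -> np.ndarray:
        """(n_participants, 5) posterior means of theta_i."""
        return self.individual_draws.mean(axis=(0, 1))

    def pooled_group_means(self, param: str) -> np.ndarray:
        return np.concatenate(self.group_mean_draws[param])


@dataclass(frozen=True)
class T1Result:
    t1_observed: float
    t1_replicated: np.ndarray
    ppp: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ppp <= 1.0:
            raise ValueError("ppp must be in [0, 1]")


@dataclass(frozen=True)
class ContrastResult:
    mean_difference: float
    bci_low: float
    bci_high: float
    excludes_zero: bool


class FitClassification:
    OUTGROUP_BIASED = "outgroup_biased"
    INGROUP_BIASED = "ingroup_biased"
    EXCLUDED = "excluded"


# ---------------------------------------------------------------------------
# sampler internals


def _participant_loglik(theta: np.ndarray, spec: QuadSpecification,
                        nc: np.ndarray, ni: np.ndarray) -> np.ndarray:
    """Log-likelihood per participant; theta (N,5) -> (N,)."""
    p = cell_probability_array(theta, spec)
    np.clip(p, 1e-12, 1 - 1e-12, out=p)
    return np.sum(nc * np.log(p) + ni * np.log1p(-p), axis=-1)


def _beta_logpdf(theta: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return (
        (alpha - 1) * np.log(theta)
        + (beta - 1) * np.log1p(-theta)
        - betaln(alpha, beta)
    )


def _run_chain(nc, ni, spec, config, rng, n_participants):
    n_iter = config.n_warmup + config.n_samples * config.thinning
    N = n_participants

    z = rng.normal(0.0, 0.5, size=(N, 5))  # logit(theta)
    mu = rng.uniform(0.3, 0.7, size=5)
    kappa = 2.0 + rng.exponential(5.0, size=5)

    step_theta = 0.4
    step_mu = np.full(5, 0.3)
    step_kappa = np.full(5, 0.4)
    step_nc = 0.2  # scale of the joint non-centered hyper move
    chol_nc = np.eye(10)  # proposal shape, adapted during warmup
    hyper_history: list[np.ndarray] = []

    theta = expit(z)
    ll = _participant_loglik(theta, spec, nc, ni)

    keep_mu = np.empty((config.n_samples, 5))
    keep_kappa = np.empty((config.n_samples, 5))
    keep_theta = np.empty((config.n_samples, N, 5))

    acc_theta = acc_mu = acc_kappa = acc_nc = 0.0
    n_theta = n_mu = n_kappa = n_nc = 0

    adapt_theta_acc, adapt_theta_n = 0.0, 0
    adapt_mu_acc = np.zeros(5)
    adapt_kappa_acc = np.zeros(5)
    adapt_nc_acc = 0.0
    adapt_hyper_n = 0

    kept = 0
    for it in range(n_iter):
        warm = it < config.n_warmup
        alpha = mu * kappa
        beta = (1.0 - mu) * kappa

        # -- participant block: joint RW on logit(theta_i), vectorized over i
        z_prop = z + step_theta * rng.normal(size=(N, 5))
        theta_prop = expit(z_prop)
        ll_prop = _participant_loglik(theta_prop, spec, nc, ni)
        # prior on logit scale: Beta(theta) * theta(1-theta)
        logprior = np.sum(
            _beta_logpdf(theta, alpha, beta) + np.log(theta) + np.log1p(-theta),
            axis=1,
        )
        logprior_prop = np.sum(
            _beta_logpdf(theta_prop, alpha, beta)
            + np.log(theta_prop)
            + np.log1p(-theta_prop),
            axis=1,
        )
        log_ratio = (ll_prop + logprior_prop) - (ll + logprior)
        accept = np.log(rng.uniform(size=N)) < log_ratio
        z[accept] = z_prop[accept]
        theta = expit(z)
        ll = np.where(accept, ll_prop, ll)
        rate = float(np.mean(accept))
        if warm:
            adapt_theta_acc += rate
            adapt_theta_n += 1
        else:
            acc_theta += rate
            n_theta += 1

        # -- hyperparameter block, per process parameter
        for p in range(5):
            th = theta[:, p]
            lth = np.log(th)
            l1th = np.log1p(-th)

            def beta_ll(m, k):
                a, b = m * k, (1.0 - m) * k
                return np.sum((a - 1) * lth + (b - 1) * l1th) - N * betaln(a, b)

            # mu_p | rest  (uniform prior; logit-scale RW with jacobian)
            lm = logit(mu[p]) + step_mu[p] * rng.normal()
            m_prop = expit(lm)
            log_ratio = (
                beta_ll(m_prop, kappa[p]) - beta_ll(mu[p], kappa[p])
                + math.log(m_prop * (1 - m_prop)) - math.log(mu[p] * (1 - mu[p]))
            )
            if math.log(rng.uniform()) < log_ratio:
                mu[p] = m_prop
                if warm:
                    adapt_mu_acc[p] += 1
                else:
                    acc_mu += 1

            # kappa_p | rest  (shifted-exponential prior; log-scale RW)
            lk = math.log(kappa[p] - 2.0) + step_kappa[p] * rng.normal()
            k_prop = 2.0 + math.exp(lk)
            log_ratio = (
                beta_ll(mu[p], k_prop) - beta_ll(mu[p], kappa[p])
                - config.kappa_prior_rate * (k_prop - kappa[p])
                + math.log(k_prop - 2.0) - math.log(kappa[p] - 2.0)
            )
            if math.log(rng.uniform()) < log_ratio:
                kappa[p] = k_prop
                if warm:
                    adapt_kappa_acc[p] += 1
                else:
                    acc_kappa += 1
        if warm:
            adapt_hyper_n += 1
        else:
            n_mu += 5
            n_kappa += 5

        # -- joint non-centered move: propose all hyperparameters at once
        #    (warmup-adapted covariance, so the proposal can travel along
        #    likelihood ridges), carrying every theta along its population
        #    quantile; the Beta population terms cancel by construction
        v = np.concatenate([logit(mu), np.log(kappa - 2.0)])
        v_prop = v + step_nc * (chol_nc @ rng.normal(size=10))
        mu_prop = expit(v_prop[:5])
        kappa_prop = 2.0 + np.exp(v_prop[5:])
        a1, b1 = mu * kappa, (1.0 - mu) * kappa
        a2, b2 = mu_prop * kappa_prop, (1.0 - mu_prop) * kappa_prop
        u = betainc(a1, b1, theta)
        theta_prop = betaincinv(a2, b2, u)
        np.clip(theta_prop, 1e-12, 1.0 - 1e-12, out=theta_prop)
        ll_prop = _participant_loglik(theta_prop, spec, nc, ni)
        log_ratio = (
            float(np.sum(ll_prop - ll))
            - config.kappa_prior_rate * float(np.sum(kappa_prop - kappa))
            + float(np.sum(np.log(mu_prop * (1 - mu_prop))
                           - np.log(mu * (1 - mu))))
            + float(np.sum(np.log(kappa_prop - 2.0) - np.log(kappa - 2.0)))
        )
        if math.log(rng.uniform()) < log_ratio:
            mu, kappa = mu_prop, kappa_prop
            theta = theta_prop
            z = logit(theta)
            ll = ll_prop
            if warm:
                adapt_nc_acc += 1
            else:
                acc_nc += 1
        if warm:
            hyper_history.append(np.concatenate([logit(mu), np.log(kappa - 2.0)]))
        else:
            n_nc += 1

        # -- step-size adaptation (warmup only, every 50 iterations)
        if warm and (it + 1) % 50 == 0:
            if adapt_theta_n:
                r = adapt_theta_acc / adapt_theta_n
                step_theta *= math.exp(2.0 * (r - config.target_accept))
                adapt_theta_acc, adapt_theta_n = 0.0, 0
            if adapt_hyper_n:
                r_mu = adapt_mu_acc / adapt_hyper_n
                r_k = adapt_kappa_acc / adapt_hyper_n
                r_nc = adapt_nc_acc / adapt_hyper_n
                step_mu *= np.exp(2.0 * (r_mu - config.target_accept))
                step_kappa *= np.exp(2.0 * (r_k - config.target_accept))
                # multivariate proposal: aim lower than the scalar target
                step_nc *= math.exp(2.0 * (r_nc - 0.234))
                adapt_mu_acc[:] = 0.0
                adapt_kappa_acc[:] = 0.0
                adapt_nc_acc = 0.0
                adapt_hyper_n = 0
            if len(hyper_history) >= 200:
                hist = np.asarray(hyper_history[-500:])
                cov = np.cov(hist.T) + 1e-6 * np.eye(10)
                try:
                    chol_nc = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass

        if not warm and (it - config.n_warmup + 1) % config.thinning == 0:
            keep_mu[kept] = mu
            keep_kappa[kept] = kappa
            keep_theta[kept] = theta
            kept += 1

    acceptance = {
        "theta": acc_theta / max(n_theta, 1),
        "mu": acc_mu / max(n_mu, 1),
        "kappa": acc_kappa / max(n_kappa, 1),
        "noncentered": acc_nc / max(n_nc, 1),
    }
    return keep_mu, keep_kappa, keep_theta, acceptance


def fit_hierarchical(
    tables: Sequence[ResponseCountTable],
    spec: QuadSpecification,
    config: HierarchicalConfig = HierarchicalConfig(),
    participant_ids: Sequence[str] | None = None,
) -> PosteriorSummary:
    """Fit the beta-MPT hierarchy to per-participant count tables.

    Runs ``config.n_chains`` independent chains from dispersed random
    starts; convergence is summarized by split-R-hat and bulk ESS on the
    group-level means and concentrations (via ArviZ).  When any group-level
    R-hat exceeds the configured limit the summary is returned flagged
    (``converged = False``) rather than raising.
    """
    if len(tables) < 2:
        raise ValueError("hierarchical fit requires >= 2 participants")
    for i, t in enumerate(tables):
        if t.n_total == 0:
            raise ValueError(f"participant index {i} has zero trials")
    if participant_ids is None:
        participant_ids = [f"p{i}" for i in range(len(tables))]
    if len(participant_ids) != len(tables):
        raise ValueError("participant_ids must match tables")

    nc = np.stack([t.as_arrays()[0] for t in tables])
    ni = np.stack([t.as_arrays()[1] for t in tables])

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    mus, kappas, thetas, accs = [], [], [], []
    for s in seeds:
        rng = np.random.default_rng(s)
        m, k, th, acc = _run_chain(nc, ni, spec, config, rng, len(tables))
        mus.append(m)
        kappas.append(k)
        thetas.append(th)
        accs.append(acc)

    mu_arr = np.stack(mus)  # (chains, draws, 5)
    kappa_arr = np.stack(kappas)
    theta_arr = np.stack(thetas)  # (chains, draws, N, 5)

    group_mean_draws = {p: mu_arr[..., j] for j, p in enumerate(PARAM_NAMES)}
    kappa_draws = {p: kappa_arr[..., j] for j, p in enumerate(PARAM_NAMES)}

    import arviz as az

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for j, p in enumerate(PARAM_NAMES):
        for label, arr in ((f"mu_{p}", mu_arr[..., j]), (f"kappa_{p}", kappa_arr[..., j])):
            rhat[label] = float(az.rhat(arr.copy()))
            ess[label] = float(az.ess(arr.copy()))
    converged = all(r <= config.rhat_limit for r in rhat.values()) and all(
        e >= config.ess_limit for e in ess.values()
    )

    mean_acc = {k: float(np.mean([a[k] for a in accs])) for k in accs[0]}
    return PosteriorSummary(
        participant_ids=list(participant_ids),
        spec=spec,
        config=config,
        group_mean_draws=group_mean_draws,
        kappa_draws=kappa_draws,
        individual_draws=theta_arr,
        rhat=rhat,
        ess=ess,
        converged=converged,
        acceptance=mean_acc,
    )


# ---------------------------------------------------------------------------
# posterior-predictive fit (T1)

_T1_EPS = 0.5


def _t1_stat(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Sum over the 16 (cell x outcome) counts of (obs-exp)^2 / max(exp, eps)."""
    denom = np.maximum(expected, _T1_EPS)
    return np.sum((observed - expected) ** 2 / denom, axis=(-2, -1))


def t1_fit(
    posterior: PosteriorSummary,
    tables: Sequence[ResponseCountTable],
    level: str = "group",
    n_draws: int = 500,
    seed: int | None = None,
) -> T1Result | list[T1Result]:
    """Posterior-predictive T1 fit at group or participant level.

    For each posterior draw, expected counts are the per-cell trial totals
    times that draw's model probabilities; a replicated dataset with
    matched trial counts is simulated from the same draw.  ``ppp`` is the
    fraction of draws whose replicated T1 is at least the observed T1.
    Group level sums counts over participants before comparing.
    """
    if level not in ("group", "participant"):
        raise ValueError("level must be 'group' or 'participant'")
    chains, draws, n_part, _ = posterior.individual_draws.shape
    if len(tables) != n_part:
        raise ValueError("tables must match the fitted participants")
    rng = np.random.default_rng(posterior.config.seed + 1 if seed is None else seed)

    theta = posterior.individual_draws.reshape(chains * draws, n_part, 5)
    total = theta.shape[0]
    take = min(n_draws, total)
    idx = np.linspace(0, total - 1, take).astype(int)
    theta = theta[idx]  # (D, N, 5)

    nc = np.stack([t.as_arrays()[0] for t in tables])  # (N, 8)
    ni = np.stack([t.as_arrays()[1] for t in tables])
    n = nc + ni
    obs = np.stack([nc, ni], axis=-1)  # (N, 8, 2)

    p = cell_probability_array(theta, posterior.spec)  # (D, N, 8)
    np.clip(p, 1e-12, 1 - 1e-12, out=p)
    exp_c = n[None, :, :] * p
    expected = np.stack([exp_c, n[None, :, :] - exp_c], axis=-1)  # (D, N, 8, 2)

    rep_c = rng.binomial(n.astype(int)[None, :, :], p)
    replicated = np.stack([rep_c, n[None, :, :] - rep_c], axis=-1).astype(float)

    if level == "group":
        t1_obs = _t1_stat(obs.sum(axis=0)[None], expected.sum(axis=1))
        t1_rep = _t1_stat(replicated.sum(axis=1), expected.sum(axis=1))
        return T1Result(
            float(np.mean(t1_obs)),
            t1_rep,
            float(np.mean(t1_rep >= t1_obs)),
        )

    results = []
    for i in range(n_part):
        t1_obs = _t1_stat(obs[i][None], expected[:, i])
        t1_rep = _t1_stat(replicated[:, i], expected[:, i])
        results.append(
            T1Result(
                float(np.mean(t1_obs)),
                t1_rep,
                float(np.mean(t1_rep >= t1_obs)),
            )
        )
    return results


def classify_by_fit(
    tables: Sequence[ResponseCountTable],
    fit_outgroup: PosteriorSummary,
    fit_ingroup: PosteriorSummary,
    tie_epsilon: float = 0.01,
    fit_threshold: float = 0.05,
    t1_seed: int | None = None,
) -> list[str]:
    """Dual-specification T1 classification of each participant.

    A specification "fits" a participant when their posterior-predictive
    p-value is at least ``fit_threshold``.  If neither specification fits
    the participant is excluded; if both fit and the ppp difference is
    within ``tie_epsilon`` they are excluded as fitting equally well;
    otherwise the better-fitting specification's bias direction wins.
    """
    if fit_outgroup.participant_ids != fit_ingroup.participant_ids:
        raise ValueError("fits cover different participants")
    t1_out = t1_fit(fit_outgroup, tables, level="participant", seed=t1_seed)
    t1_in = t1_fit(fit_ingroup, tables, level="participant", seed=t1_seed)
    labels = []
    for r_out, r_in in zip(t1_out, t1_in):
        fits_out = r_out.ppp >= fit_threshold
        fits_in = r_in.ppp >= fit_threshold
        if not fits_out and not fits_in:
            labels.append(FitClassification.EXCLUDED)
        elif fits_out and fits_in and abs(r_out.ppp - r_in.ppp) <= tie_epsilon:
            labels.append(FitClassification.EXCLUDED)
        elif (r_out.ppp > r_in.ppp and fits_out) or not fits_in:
            labels.append(FitClassification.OUTGROUP_BIASED)
        else:
            labels.append(FitClassification.INGROUP_BIASED)
    return labels


# ---------------------------------------------------------------------------
# contrasts


def contrast_posterior(
    posterior: PosteriorSummary, param_x: str, param_y: str
) -> ContrastResult:
    """Draw-wise difference of two group-level mean posteriors.

    Reports the mean difference and the equal-tailed 95% interval
    (2.5%/97.5% quantiles of x - y over all pooled draws).
    """
    x = posterior.pooled_group_means(param_x)
    y = posterior.pooled_group_means(param_y)
    if x.shape != y.shape:
        raise ValueError("mismatched draw counts")
    diff = x - y
    lo, hi = np.quantile(diff, [0.025, 0.975])
    return ContrastResult(
        float(np.mean(diff)),
        float(lo),
        float(hi),
        not (lo <= 0.0 <= hi),
    )


def param_vs_zero(
    posterior: PosteriorSummary, param: str, near_zero_delta: float = 0.005
) -> tuple[bool, tuple[float, float]]:
    """Is a group-level mean distinguishable from zero?

    Group means live in (0, 1), so the raw 95% interval can never contain
    zero exactly; the operational rule is that the 2.5% quantile must
    exceed ``near_zero_delta``.  The raw interval is always returned.
    """
    draws = posterior.pooled_group_means(param)
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return bool(lo > near_zero_delta), (float(lo), float(hi))
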