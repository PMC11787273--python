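"""Bayesian univariate mixed-effects logistic screening of candidate
predictors, with collinearity filtering, prior sensitivity analysis and the
power-by-simulation calculation.

Model, per candidate predictor x (standardized):

    logit P(adverse_ij) = b0 + b1 * x_ij + u_i,   u_i ~ Normal(0, sigma_u^2)

with i indexing patients and j their catheterizations. The patient random
intercepts are integrated out by Gauss-Hermite quadrature, leaving a
three-parameter marginal posterior over (b0, b1, log sigma_u) under
weakly-informative priors. Two posterior approximations are provided:

* ``laplace`` — MAP plus a normal approximation from the numerical Hessian.
  Deterministic, milliseconds per fit; used for the heavily replicated
  simulation studies (type-I calibration, power curves).
* ``mcmc`` — affine-invariant ensemble sampling (emcee) on the same marginal
  posterior, initialized at the MAP; reports a split-R-hat diagnostic.

A predictor is "selected" when its two-sided posterior tail probability
p_B = 2 min(P(b1 > 0), P(b1 < 0)) falls below 0.05, equivalently when the
central 95% credible interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import binomtest, norm, pearsonr

from .cohort import Cohort

__all__ = [
    "PriorSpec",
    "SamplerSettings",
    "PosteriorSummary",
    "fit_univariate",
    "fit_mixed_logistic",
    "screen_all",
    "collinearity_filter",
    "prior_sensitivity",
    "power_by_simulation",
    "PowerEstimate",
]

# Variables whose raw value *decreases* risk in the clinical direction;
# they are negated before standardization so every reported coefficient
# points along "higher = riskier".
RISK_NEGATED = frozenset({"age_years"})


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors on the standardized scale.

    coefficient ~ Normal(0, coef_sd^2); intercept ~ Normal(0, intercept_sd^2);
    random-intercept SD ~ Half-Normal(re_sd_scale).
    """

    coef_sd: float = 2.5
    intercept_sd: float = 10.0
    re_sd_scale: float = 1.0

    def __post_init__(self):
        if min(self.coef_sd, self.intercept_sd, self.re_sd_scale) <= 0:
            raise ValueError("all prior scales must be positive")


@dataclass(frozen=True)
class SamplerSettings:
    """Posterior-approximation settings.

    ``chains``/``draws``/``warmup`` parameterize the MCMC budget (total
    post-warmup draws = chains x draws, spread over an ensemble of walkers);
    ``quad_points`` is the Gauss-Hermite order for the random-intercept
    integral.
    """

    method: str = "mcmc"  # "mcmc" | "laplace"
    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    quad_points: int = 15
    rhat_threshold: float = 1.01

    def __post_init__(self):
        if self.method not in ("mcmc", "laplace"):
            raise ValueError(f"unknown method {self.method!r}")


FAST = SamplerSettings(method="laplace")


@dataclass(frozen=True)
class PosteriorSummary:
    """Screening result for one candidate predictor."""

    variable: str
    beta_median: float
    ci_low: float
    ci_high: float
    p_tail: float
    selected: bool
    sigma_u: float
    n_used: int
    method: str
    rhat: float | None = None
    converged: bool = True
    note: str = ""

    @property
    def ci_excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


class _MarginalPosterior:
    """Log posterior of (b0, b1, log sigma_u) with random intercepts
    integrated out per patient by Gauss-Hermite quadrature."""

    def __init__(self, x: np.ndarray, y: np.ndarray, groups: np.ndarray,
                 prior: PriorSpec, quad_points: int):
        order = np.argsort(groups, kind="stable")
        self.x = np.asarray(x, dtype=float)[order]
        self.y = np.asarray(y, dtype=float)[order]
        g = np.asarray(groups)[order]
        # reduceat boundaries for per-patient sums
        change = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
        self.starts = change
        self.n_groups = change.size
        self.prior = prior
        nodes, weights = np.polynomial.hermite.hermgauss(quad_points)
        self.z = np.sqrt(2.0) * nodes  # standard-normal abscissae
        self.logw = np.log(weights) - 0.5 * np.log(np.pi)

    def __call__(self, theta: np.ndarray) -> float:
        b0, b1, log_su = theta
        if not np.all(np.isfinite(theta)) or abs(log_su) > 15:
            return -np.inf
        su = np.exp(log_su)
        eta = b0 + b1 * self.x  # (n,)
        # (n, Q): linear predictor at each quadrature node
        t = eta[:, None] + su * self.z[None, :]
        ll_obs = self.y[:, None] * t - np.logaddexp(0.0, t)
        ll_pat = np.add.reduceat(ll_obs, self.starts, axis=0)  # (J, Q)
        ll = float(np.sum(logsumexp(ll_pat + self.logw[None, :], axis=1)))
        p = self.prior
        log_prior = (
            -0.5 * (b0 / p.intercept_sd) ** 2
            - 0.5 * (b1 / p.coef_sd) ** 2
            - 0.5 * (su / p.re_sd_scale) ** 2
            + log_su  # Jacobian of the log-SD parameterization
        )
        return ll + log_prior

    def neg(self, theta: np.ndarray) -> float:
        return -self(theta)


def _map_fit(post: _MarginalPosterior) -> tuple[np.ndarray, np.ndarray]:
    """MAP point and covariance (inverse numerical Hessian)."""
    p_marginal = np.clip(np.mean(post.y), 1e-3, 1 - 1e-3)
    start = np.array([np.log(p_marginal / (1 - p_marginal)), 0.0, np.log(0.5)])
    res = minimize(post.neg, start, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    theta = res.x
    hess = _numerical_hessian(post.neg, theta)
    try:
        cov = np.linalg.inv(hess)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        # ridge the Hessian; flagged upstream via wide intervals
        cov = np.linalg.inv(hess + 1e-6 * np.eye(3))
        cov = np.abs(cov)
    return theta, cov


def _numerical_hessian(f: Callable, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def _split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R-hat on an (n_chains, n_draws) array."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    if half < 2:
        return np.inf
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _sample_mcmc(post: _MarginalPosterior, settings: SamplerSettings,
                 seed: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Affine-invariant ensemble MCMC: ``settings.chains`` independent
    ensembles (so the R-hat comparison is across genuinely independent
    chains), each initialized near the MAP."""
    import emcee

    theta_map, cov = _map_fit(post)
    ndim = 3
    nwalkers = 8
    steps_post = max(4, int(np.ceil(settings.draws / nwalkers)))
    steps_warm = max(100, int(np.ceil(settings.warmup / nwalkers)))
    scale = np.sqrt(np.clip(np.diag(cov), 1e-6, None))

    per_chain = []
    for c in range(settings.chains):
        chain_seed = (seed * 1000003 + c) % (2**31)
        rng = np.random.default_rng(chain_seed)
        p0 = theta_map + 0.5 * scale * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, post,
            moves=[(emcee.moves.DEMove(), 0.8),
                   (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(chain_seed).get_state()
        sampler.run_mcmc(p0, steps_warm + steps_post, progress=False)
        per_chain.append(sampler.get_chain()[steps_warm:])  # (steps, w, ndim)

    b1_chains = np.stack([ch[:, :, 1].reshape(-1) for ch in per_chain])
    rhat = _split_rhat(b1_chains)
    flat = np.concatenate([ch.reshape(-1, ndim) for ch in per_chain])
    return flat[:, 1], np.exp(flat[:, 2]), rhat


def _prepare(cohort: Cohort, variable: str):
    x = cohort.predictor(variable)
    y = cohort.adverse().astype(float)
    groups = cohort.patient_ids()
    keep = np.isfinite(x)
    x, y, groups = x[keep], y[keep], groups[keep]
    if x.size < 20:
        raise ValueError(
            f"{variable}: only {x.size} records with data (need >= 20)"
        )
    if y.min() == y.max():
        raise ValueError(f"{variable}: outcome is constant in available records")
    if variable in RISK_NEGATED:
        x = -x
    sd = np.std(x)
    if sd == 0:
        raise ValueError(f"{variable}: predictor is constant")
    x_std = (x - np.mean(x)) / sd
    return x_std, y, groups


def fit_univariate(
    cohort: Cohort,
    variable: str,
    prior: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> PosteriorSummary:
    """Fit the univariate mixed-effects logistic model for one predictor.

    The predictor is standardized (and sign-flipped for variables such as
    age where lower raw values carry higher risk), so the reported log-odds
    ratio is per SD in the direction of increasing risk.
    """
    x, y, groups = _prepare(cohort, variable)
    return fit_mixed_logistic(x, y, groups, variable=variable, prior=prior,
                              settings=settings, seed=seed)


def fit_mixed_logistic(
    x: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    variable: str = "x",
    prior: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> PosteriorSummary:
    """Array-level mixed-effects logistic fit (predictor already prepared).

    ``x`` is used as given — standardize or recode before calling if a
    per-SD or per-category coefficient is wanted.
    """
    prior = prior or PriorSpec()
    settings = settings or SamplerSettings()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError(f"{variable}: outcome is constant")
    post = _MarginalPosterior(x, y, groups, prior, settings.quad_points)

    if settings.method == "laplace":
        theta, cov = _map_fit(post)
        b1, se = theta[1], float(np.sqrt(cov[1, 1]))
        z = norm.ppf(0.975)
        p_tail = float(2 * norm.sf(abs(b1) / se)) if se > 0 else 0.0
        return PosteriorSummary(
            variable=variable,
            beta_median=float(b1),
            ci_low=float(b1 - z * se),
            ci_high=float(b1 + z * se),
            p_tail=p_tail,
            selected=p_tail < 0.05,
            sigma_u=float(np.exp(theta[2])),
            n_used=int(y.size),
            method="laplace",
        )

    b1_draws, su_draws, rhat = _sample_mcmc(post, settings, seed)
    ci_low, ci_high = np.quantile(b1_draws, [0.025, 0.975])
    p_pos = np.mean(b1_draws > 0)
    p_tail = 2 * min(p_pos, 1 - p_pos)
    p_tail = max(float(p_tail), 2.0 / (b1_draws.size + 1))
    converged = rhat < settings.rhat_threshold
    if not converged:
        warnings.warn(
            f"{variable}: split-R-hat {rhat:.3f} exceeds "
            f"{settings.rhat_threshold}; increase draws",
            stacklevel=2,
        )
    return PosteriorSummary(
        variable=variable,
        beta_median=float(np.median(b1_draws)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_tail=p_tail,
        selected=p_tail < 0.05,
        sigma_u=float(np.median(su_draws)),
        n_used=int(y.size),
        method="mcmc",
        rhat=rhat,
        converged=bool(converged),
    )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def screen_all(
    cohort: Cohort,
    variables: Sequence[str],
    prior: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> list[PosteriorSummary]:
    """Screen every candidate predictor; per-variable failures become
    flagged entries rather than aborting the screen."""
    if not variables:
        raise ValueError("candidate variable list is empty")
    seeds = _spawn_seeds(seed, len(variables))
    out = []
    for var, sub_seed in zip(variables, seeds):
        try:
            out.append(fit_univariate(cohort, var, prior, settings, sub_seed))
        except ValueError as err:
            out.append(
                PosteriorSummary(
                    variable=var, beta_median=np.nan, ci_low=np.nan,
                    ci_high=np.nan, p_tail=np.nan, selected=False,
                    sigma_u=np.nan, n_used=0, method="failed",
                    converged=False, note=str(err),
                )
            )
    return out


def collinearity_filter(
    selected: Sequence[PosteriorSummary],
    cohort: Cohort,
    threshold: float = 0.6,
) -> tuple[list[PosteriorSummary], pd.DataFrame]:
    """Drop, from each highly correlated pair of selected predictors, the one
    with the weaker (larger) posterior tail probability.

    Pairs with |Pearson r| >= ``threshold`` over pairwise-complete records
    are processed in descending |r|. Returns the surviving summaries (input
    order preserved) and a report of dropped pairs.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    summaries = list(selected)
    cols = [cohort.predictor(s.variable) for s in summaries]
    pairs = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            xa, xb = cols[i], cols[j]
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < 3:
                warnings.warn(
                    f"fewer than 3 paired observations for "
                    f"{summaries[i].variable}/{summaries[j].variable}; "
                    f"pair skipped",
                    stacklevel=2,
                )
                continue
            if np.std(xa[ok]) == 0 or np.std(xb[ok]) == 0:
                r = 1.0 if np.array_equal(xa[ok], xb[ok]) else 0.0
            else:
                r = pearsonr(xa[ok], xb[ok]).statistic
            pairs.append((abs(r), r, i, j))
    pairs.sort(reverse=True)

    dropped: dict[int, dict] = {}
    for abs_r, r, i, j in pairs:
        if abs_r < threshold:
            break
        if i in dropped or j in dropped:
            continue
        # weaker evidence (larger p_tail) loses; ties drop the later entry
        lose, keep = (i, j) if summaries[i].p_tail > summaries[j].p_tail else (j, i)
        dropped[lose] = {
            "dropped": summaries[lose].variable,
            "kept": summaries[keep].variable,
            "r": r,
        }
    report = pd.DataFrame(list(dropped.values()),
                          columns=["dropped", "kept", "r"])
    kept = [s for k, s in enumerate(summaries) if k not in dropped]
    return kept, report


def prior_sensitivity(
    cohort: Cohort,
    variable: str,
    priors: Sequence[PriorSpec],
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> dict:
    """Refit one predictor under each prior; report the summaries and the
    maximum pairwise absolute difference in the posterior-median log-OR."""
    if len(priors) < 2:
        raise ValueError("need at least 2 priors for a sensitivity analysis")
    fits = [
        fit_univariate(cohort, variable, prior, settings, seed)
        for prior in priors
    ]
    betas = [f.beta_median for f in fits]
    table = pd.DataFrame(
        {
            "coef_sd": [p.coef_sd for p in priors],
            "re_sd_scale": [p.re_sd_scale for p in priors],
            "beta_median": betas,
            "ci_low": [f.ci_low for f in fits],
            "ci_high": [f.ci_high for f in fits],
            "p_tail": [f.p_tail for f in fits],
            "selected": [f.selected for f in fits],
        }
    )
    diffs = [abs(a - b) for i, a in enumerate(betas) for b in betas[i + 1:]]
    return {"table": table, "fits": fits, "max_abs_diff": max(diffs)}


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    reps: int
    n_failed: int = 0


def power_by_simulation(
    true_effect: float,
    n_patients: int = 93,
    caths_per_patient: float = 1.7,
    prevalence: float = 0.10,
    reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    variable: str = "tr_vmax",
    settings: SamplerSettings = FAST,
) -> PowerEstimate:
    """Power of the univariate screen by simulation: the fraction of
    synthetic cohorts in which the screen selects a predictor carrying
    ``true_effect`` (log-OR per SD). Clopper-Pearson binomial interval."""
    from .simulate import SimConfig, simulate_cohort

    if reps < 100:
        raise ValueError("use at least 100 replicates")
    config = SimConfig(
        n_patients=n_patients,
        mean_caths_per_patient=caths_per_patient,
        target_prevalence=prevalence,
    ).single_effect(variable, true_effect)

    seeds = _spawn_seeds(seed, reps)
    hits = failed = 0
    for sub_seed in seeds:
        cohort = simulate_cohort(config, sub_seed)
        try:
            fit = fit_univariate(cohort, variable, None, settings, sub_seed)
        except ValueError:
            failed += 1
            continue
        if fit.p_tail < alpha:
            hits += 1
    n_ok = reps - failed
    ci = binomtest(hits, n_ok).proportion_ci(confidence_level=0.95)
    return PowerEstimate(
        power=hits / n_ok,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        reps=n_ok,
        n_failed=failed,
    )
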