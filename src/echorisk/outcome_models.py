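"""Post-hoc models on the computed risk score.

Per-outcome Bayesian logistic risk curves (complication, escalation, no
adverse event) over the observed score range, a mixed-effects confirmation
of the score-outcome association, covariate association checks, and a
rank-based comparison of scores between groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm, rankdata

from .cohort import Cohort
from .screening import (
    PosteriorSummary,
    PriorSpec,
    SamplerSettings,
    fit_mixed_logistic,
    _numerical_hessian,
)

__all__ = [
    "RiskCurve",
    "outcome_indicators",
    "fit_risk_curves",
    "confirm_association",
    "covariate_check",
    "CovariateResult",
    "group_compare",
    "GroupComparison",
]


@dataclass(frozen=True)
class RiskCurve:
    """Bayesian logistic risk curve for one outcome versus the score.

    ``slope`` is on the logit scale per score point. The predicted-risk
    bands are pointwise central 95% credible intervals over the observed
    score range only (no extrapolation)."""

    outcome: str
    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    grid: np.ndarray
    risk_median: np.ndarray
    risk_low: np.ndarray
    risk_high: np.ndarray
    n_events: int


def outcome_indicators(
    cohort: Cohort, overlapping: bool = True
) -> dict[str, np.ndarray]:
    """Binary indicators for the three reported outcomes.

    ``overlapping=True`` (default) lets a catheterization count as both a
    complication and an escalation when both occurred; the exclusive coding
    assigns such records to the complication group only.
    """
    comp = np.array([r.outcome.complication for r in cohort], dtype=int)
    esc = np.array([r.outcome.escalation for r in cohort], dtype=int)
    adverse = cohort.adverse()
    if not overlapping:
        esc = esc & ~comp
    return {
        "complication": comp,
        "escalation": esc,
        "no_adverse_event": 1 - adverse,
    }


def _bayes_logistic_draws(
    x: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec,
    seed: int,
    n_draws: int = 4000,
) -> np.ndarray:
    """Posterior draws of (b0, b1) for a plain Bayesian logistic model via a
    Laplace (normal) approximation around the MAP."""

    def neg_log_post(theta):
        b0, b1 = theta
        t = b0 + b1 * x
        ll = np.sum(y * t - np.logaddexp(0.0, t))
        lp = -0.5 * (b0 / prior.intercept_sd) ** 2 - 0.5 * (b1 / prior.coef_sd) ** 2
        return -(ll + lp)

    res = minimize(neg_log_post, np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
    hess = _numerical_hessian(neg_log_post, res.x)
    cov = np.linalg.inv(hess)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(res.x, cov, size=n_draws)


def fit_risk_curves(
    scores,
    outcomes: Mapping[str, np.ndarray] | None = None,
    prior: PriorSpec | None = None,
    seed: int = 0,
    cohort: Cohort | None = None,
    min_events: int = 3,
    n_grid: int = 101,
) -> list[RiskCurve]:
    """One Bayesian logistic fit per outcome versus the score.

    ``outcomes`` maps outcome names to binary labels; alternatively pass a
    ``cohort`` and the three standard indicators are derived. Outcomes with
    fewer than ``min_events`` events are skipped with a warning entry
    omitted (reported via the returned list simply not containing them).
    """
    import warnings

    prior = prior or PriorSpec()
    s = np.asarray(scores, dtype=float)
    if outcomes is None:
        if cohort is None:
            raise ValueError("provide either outcomes or a cohort")
        outcomes = outcome_indicators(cohort)

    # standardize the score for a stable fit; slope mapped back per point
    mu, sd = float(np.mean(s)), float(np.std(s))
    if sd == 0:
        raise ValueError("scores are constant; no curve to fit")
    z = (s - mu) / sd
    grid = np.linspace(s.min(), s.max(), n_grid)
    zg = (grid - mu) / sd

    curves = []
    for k, (name, y) in enumerate(outcomes.items()):
        y = np.asarray(y).astype(int)
        n_events = int(y.sum())
        if n_events < min_events or n_events > y.size - 1:
            warnings.warn(
                f"outcome {name!r}: {n_events} events; curve skipped",
                stacklevel=2,
            )
            continue
        draws = _bayes_logistic_draws(z, y, prior, seed + k)
        risk = expit(draws[:, 0][:, None] + draws[:, 1][:, None] * zg[None, :])
        slope_draws = draws[:, 1] / sd
        lo, hi = np.quantile(slope_draws, [0.025, 0.975])
        curves.append(
            RiskCurve(
                outcome=name,
                intercept=float(np.median(draws[:, 0] - draws[:, 1] * mu / sd)),
                slope=float(np.median(slope_draws)),
                slope_ci=(float(lo), float(hi)),
                grid=grid,
                risk_median=np.median(risk, axis=0),
                risk_low=np.quantile(risk, 0.025, axis=0),
                risk_high=np.quantile(risk, 0.975, axis=0),
                n_events=n_events,
            )
        )
    return curves


def confirm_association(
    cohort: Cohort,
    scores,
    prior: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> PosteriorSummary:
    """Mixed-effects logistic confirmation that the score predicts the
    composite adverse event, with a patient-level random intercept. The
    score is standardized, so the coefficient is per SD of score."""
    s = np.asarray(scores, dtype=float)
    sd = np.std(s)
    if sd == 0:
        raise ValueError("scores are constant")
    z = (s - np.mean(s)) / sd
    return fit_mixed_logistic(
        z, cohort.adverse(), cohort.patient_ids(),
        variable="risk_score", prior=prior, settings=settings, seed=seed,
    )


@dataclass(frozen=True)
class CovariateResult:
    covariate: str
    beta: float
    ci_low: float
    ci_high: float
    odds_ratio: float | None
    or_ci: tuple[float, float] | None
    binary: bool
    separated: bool
    summary: PosteriorSummary


def covariate_check(
    cohort: Cohort,
    covariate: str,
    prior: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> CovariateResult:
    """Mixed-effects logistic association of the adverse event with one
    covariate. Binary covariates keep their 0/1 coding so the odds ratio is
    reported directly; continuous covariates are standardized."""
    x = cohort.predictor(covariate)
    y = cohort.adverse()
    groups = cohort.patient_ids()
    keep = np.isfinite(x)
    x, y, groups = x[keep], y[keep], groups[keep]
    if x.size < 20:
        raise ValueError(
            f"{covariate}: only {x.size} records with data (need >= 20)"
        )
    values = np.unique(x)
    binary = values.size == 2 and set(values) <= {0.0, 1.0}
    separated = False
    if binary:
        # perfect separation: an empty cell in the 2x2 table
        table = np.array(
            [[np.sum((x == a) & (y == b)) for b in (0, 1)] for a in (0, 1)]
        )
        separated = bool((table == 0).any())
        x_fit = x
    else:
        sd = np.std(x)
        if sd == 0:
            raise ValueError(f"{covariate}: covariate is constant")
        x_fit = (x - np.mean(x)) / sd
        separated = bool(
            np.min(x_fit[y == 1]) > np.max(x_fit[y == 0])
            or np.max(x_fit[y == 1]) < np.min(x_fit[y == 0])
        )
    summary = fit_mixed_logistic(
        x_fit, y, groups, variable=covariate, prior=prior,
        settings=settings, seed=seed,
    )
    odds_ratio = or_ci = None
    if binary:
        odds_ratio = math.exp(summary.beta_median)
        or_ci = (math.exp(summary.ci_low), math.exp(summary.ci_high))
    return CovariateResult(
        covariate=covariate,
        beta=summary.beta_median,
        ci_low=summary.ci_low,
        ci_high=summary.ci_high,
        odds_ratio=odds_ratio,
        or_ci=or_ci,
        binary=binary,
        separated=separated,
        summary=summary,
    )


@dataclass(frozen=True)
class GroupComparison:
    z: float
    p: float
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    n_a: int
    n_b: int
    exact: bool


def group_compare(
    scores_group_a: Sequence[float],
    scores_group_b: Sequence[float],
    exact_threshold: int = 12,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of scores between two groups.

    The z statistic uses the normal approximation with tie correction and a
    continuity correction; its sign is positive when group A tends to score
    higher. For small samples (combined n <= ``exact_threshold``) the
    p-value comes from the exhaustive permutation distribution of the rank
    sum instead of the normal tail. Group medians and inter-quartile ranges
    are reported alongside.
    """
    a = np.asarray(scores_group_a, dtype=float)
    b = np.asarray(scores_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        z = 0.0
        p = 1.0
        exact = False
    else:
        sd = math.sqrt(var)
        z = (w - mu) / sd
        z_cc = max(abs(w - mu) - 0.5, 0.0) / sd
        p = 2 * norm.sf(z_cc)
        exact = n <= exact_threshold
        if exact:
            # exhaustive permutation of which ranks belong to group A
            dev = abs(w - mu)
            count = total = 0
            for idx in itertools.combinations(range(n), n1):
                total += 1
                if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
                    count += 1
            p = count / total
    q = lambda v: (float(np.median(v)),
                   (float(np.percentile(v, 25)), float(np.percentile(v, 75))))
    med_a, iqr_a = q(a)
    med_b, iqr_b = q(b)
    return GroupComparison(
        z=float(z), p=float(min(p, 1.0)),
        median_a=med_a, iqr_a=iqr_a,
        median_b=med_b, iqr_b=iqr_b,
        n_a=n1, n_b=n2, exact=exact,
    )
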