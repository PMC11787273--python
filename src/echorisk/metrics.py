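"""Discrimination metrics and internal validation.

ROC AUC is computed as the tie-corrected Mann-Whitney probability that a
random event catheterization outscores a random event-free one; a trapezoidal
ROC integration is kept alongside as an internal cross-check (the two are
mathematically identical). PR AUC is average precision with tied scores
grouped, so a constant scorer scores exactly the outcome prevalence — the
"no-skill" baseline.

Optimism correction follows Harrell's bootstrap: refit the *entire* score-
development pipeline on each bootstrap cohort, measure how much better it
looks on its own bootstrap sample than on the original cohort, and subtract
the average of that gap from the apparent performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .cohort import Cohort

__all__ = [
    "roc_auc",
    "pr_auc",
    "bootstrap_ci",
    "optimism_correct",
    "OptimismResult",
    "EvalReport",
    "evaluate_scores",
]


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    y = y.astype(int)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    return s, y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney estimate, ties counted 1/2)."""
    s, y = _check(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(s)  # average ranks handle ties
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc_trapezoid(scores, labels) -> float:
    """ROC AUC by explicit trapezoidal integration over distinct-score
    thresholds. Agrees with :func:`roc_auc` to machine precision; kept as an
    independent route for cross-checking."""
    s, y = _check(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    boundary = np.r_[np.flatnonzero(np.diff(s_sorted)), s.size - 1]
    tp = np.cumsum(y_sorted)[boundary]
    fp = np.cumsum(1 - y_sorted)[boundary]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return float(np.trapezoid(tpr, fpr))


def pr_auc(scores, labels) -> float:
    """Average precision with ties grouped at distinct score values.

    Sum over descending thresholds of (recall increment x precision at that
    threshold). For a constant scorer there is a single step at recall 1
    with precision equal to prevalence, so the value is the prevalence.
    """
    s, y = _check(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("need at least one positive outcome")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    boundary = np.r_[np.flatnonzero(np.diff(s_sorted)), s.size - 1]
    tp = np.cumsum(y_sorted)[boundary].astype(float)
    n_at = (boundary + 1).astype(float)
    precision = tp / n_at
    recall_inc = np.diff(np.r_[0.0, tp]) / n_pos
    return float(np.sum(recall_inc * precision))


def bootstrap_ci(
    scores,
    labels,
    metric: Callable[[np.ndarray, np.ndarray], float] = roc_auc,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a discrimination metric.

    Rows are resampled with replacement; resamples that lose an outcome
    class are redrawn (at most 10 extra attempts each).
    """
    if B < 200:
        raise ValueError("use at least 200 bootstrap resamples")
    s, y = _check(scores, labels)
    rng = np.random.default_rng(seed)
    n = s.size
    stats = np.empty(B)
    for b in range(B):
        for attempt in range(11):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
        else:
            raise RuntimeError(
                "bootstrap resamples repeatedly lost an outcome class"
            )
        stats[b] = metric(s[idx], yb)
    lo = (1 - level) / 2
    return (
        float(np.quantile(stats, lo)),
        float(np.quantile(stats, 1 - lo)),
    )


@dataclass(frozen=True)
class OptimismResult:
    apparent: float
    optimism: float
    corrected: float
    B: int
    n_redrawn: int


def optimism_correct(
    cohort: Cohort,
    pipeline: Callable[[Cohort], Callable[[Cohort], np.ndarray]],
    metric: Callable[[np.ndarray, np.ndarray], float] = roc_auc,
    B: int = 200,
    seed: int = 0,
) -> OptimismResult:
    """Harrell bootstrap optimism correction of a score-development pipeline.

    ``pipeline(cohort)`` must return a scorer — a callable mapping a cohort
    to per-record scores — fitted on that cohort. The pipeline is treated as
    one unit (category binning, bootstrap-PLS, rescaling, everything), so
    every data-driven choice is repeated inside each bootstrap resample.
    """
    if B < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    y = cohort.adverse()
    scorer = pipeline(cohort)
    apparent = metric(scorer(cohort), y)

    records = cohort.records
    n = len(records)
    optimisms = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        for attempt in range(11):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if not 0 < yb.sum() < n:
                n_redrawn += 1
                continue
            boot = Cohort(
                records=tuple(
                    _reindexed(records[i], k) for k, i in enumerate(idx)
                )
            )
            try:
                scorer_b = pipeline(boot)
            except Exception:
                n_redrawn += 1
                continue
            break
        else:
            raise RuntimeError(
                "pipeline repeatedly failed on bootstrap resamples"
            )
        optimisms[b] = metric(scorer_b(boot), yb) - metric(scorer_b(cohort), y)
    optimism = float(np.mean(optimisms))
    return OptimismResult(
        apparent=float(apparent),
        optimism=optimism,
        corrected=float(apparent - optimism),
        B=B,
        n_redrawn=n_redrawn,
    )


def _reindexed(record, k: int):
    from dataclasses import replace

    return replace(record, cath_id=f"B{k:05d}")


@dataclass(frozen=True)
class EvalReport:
    """Discrimination report for a set of scores against the composite
    outcome: apparent ROC/PR AUCs with their no-skill baselines and
    percentile-bootstrap intervals; optimism-corrected values and the
    permutation p-value are attached when computed."""

    auc_roc: float
    auc_pr: float
    baseline_auc_roc: float
    baseline_auc_pr: float
    ci_roc: tuple[float, float]
    ci_pr: tuple[float, float]
    B: int
    level: float
    seed: int
    corrected_auc_roc: float | None = None
    corrected_auc_pr: float | None = None
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        d = {
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "baseline_auc_roc": self.baseline_auc_roc,
            "baseline_auc_pr": self.baseline_auc_pr,
            "ci_roc_low": self.ci_roc[0],
            "ci_roc_high": self.ci_roc[1],
            "ci_pr_low": self.ci_pr[0],
            "ci_pr_high": self.ci_pr[1],
            "bootstrap_B": self.B,
            "level": self.level,
            "seed": self.seed,
        }
        if self.corrected_auc_roc is not None:
            d["corrected_auc_roc"] = self.corrected_auc_roc
        if self.corrected_auc_pr is not None:
            d["corrected_auc_pr"] = self.corrected_auc_pr
        if self.permutation_p is not None:
            d["permutation_p"] = self.permutation_p
        return d


def evaluate_scores(
    scores,
    labels,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> EvalReport:
    """Apparent discrimination of per-record scores with bootstrap intervals."""
    s, y = _check(scores, labels)
    return EvalReport(
        auc_roc=roc_auc(s, y),
        auc_pr=pr_auc(s, y),
        baseline_auc_roc=0.5,
        baseline_auc_pr=float(y.mean()),
        ci_roc=bootstrap_ci(s, y, roc_auc, B, level, seed),
        ci_pr=bootstrap_ci(s, y, pr_auc, B, level, seed + 1),
        B=B,
        level=level,
        seed=seed,
    )
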