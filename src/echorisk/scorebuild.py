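"""Score development: risk-category binning, bootstrapped partial least
squares, rescaling to a 0/50/100-anchored point system, pragmatic rounding,
record scoring and permutation inference.

The development recipe: each selected predictor is divided into low / medium
/ high risk categories (coded 0/1/2), a one-component PLS regression of the
composite outcome on the category codes is fitted on each of B bootstrap
resamples, per-variable median coefficients are extracted, and the
coefficients are rescaled so that a catheterization in the lowest category
of every variable scores 0 points, all-medium scores 50 and all-high scores
100. Rounding the point values to integers ("pragmatic" system) may perturb
the three anchor sums by at most half a point per variable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, EchoExam
from .metrics import roc_auc

__all__ = [
    "SCORE_VARIABLES",
    "CutpointRule",
    "RiskCutpoints",
    "DEFAULT_CUTPOINTS",
    "ScoringSystem",
    "PLSFit",
    "assign_categories",
    "nipals_pls",
    "fit_pls_bootstrap",
    "rescale_to_points",
    "make_pragmatic",
    "score_records",
    "permutation_test",
    "save_system",
    "load_system",
]

SCORE_VARIABLES: tuple[str, ...] = (
    "age_years",
    "rv_dysfunction",
    "rv_dilatation",
    "tr_severity",
    "tr_vmax",
    "pr_severity",
    "pr_vmax",
)

CATEGORY_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class CutpointRule:
    """Three-way split of one predictor with a *closed* middle interval.

    For ``direction=+1`` (risk increases with the value): x < lower -> low,
    lower <= x <= upper -> medium, x > upper -> high. ``direction=-1``
    mirrors this (used for age, where younger means higher risk), so exact
    boundary values always land in the medium band.
    """

    lower: float
    upper: float
    direction: int = 1

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower cutpoint exceeds upper")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def code(self, x: float) -> int:
        if self.lower <= x <= self.upper:
            return 1
        above = x > self.upper
        return (2 if above else 0) if self.direction == 1 else (0 if above else 2)

    def code_array(self, x: np.ndarray) -> np.ndarray:
        out = np.full(x.shape, np.nan)
        ok = np.isfinite(x)
        mid = ok & (x >= self.lower) & (x <= self.upper)
        hi = ok & (x > self.upper)
        lo = ok & (x < self.lower)
        out[mid] = 1
        if self.direction == 1:
            out[hi], out[lo] = 2, 0
        else:
            out[hi], out[lo] = 0, 2
        return out


# Unified category boundaries: qualitative severities none-mild / mild-mod-
# to-moderate / mod-severe-to-severe (on the Likert scale), age in years
# (younger = riskier), Doppler velocities in m/s.
_ORDINAL_RULE = CutpointRule(lower=1.5, upper=2.0, direction=1)
_VELOCITY_RULE = CutpointRule(lower=3.0, upper=5.0, direction=1)
_AGE_RULE = CutpointRule(lower=3.0, upper=7.0, direction=-1)


@dataclass(frozen=True)
class RiskCutpoints:
    """Per-variable low/medium/high category rules."""

    rules: Mapping[str, CutpointRule]

    def __post_init__(self):
        object.__setattr__(self, "rules", dict(self.rules))

    def rule(self, variable: str) -> CutpointRule:
        try:
            return self.rules[variable]
        except KeyError:
            raise KeyError(f"no cutpoint rule for variable {variable!r}") from None


DEFAULT_CUTPOINTS = RiskCutpoints(
    rules={
        "age_years": _AGE_RULE,
        "rv_dysfunction": _ORDINAL_RULE,
        "rv_dilatation": _ORDINAL_RULE,
        "tr_severity": _ORDINAL_RULE,
        "tr_vmax": _VELOCITY_RULE,
        "pr_severity": _ORDINAL_RULE,
        "pr_vmax": _VELOCITY_RULE,
        # not a Table-2 variable, but a screening candidate that needs a
        # rule if it ever survives the collinearity filter
        "pr_edv": _VELOCITY_RULE,
    }
)


@dataclass(frozen=True)
class ScoringSystem:
    """Per-variable low/medium/high point values with 0/50/100 anchors.

    ``anchor_tolerance`` is 0 for unrounded systems and up to 3.5 (half a
    point per variable) for integer-rounded ones.
    """

    points: Mapping[str, tuple[float, float, float]]
    provenance: str = "fitted"
    anchor_tolerance: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "points", dict(self.points))
        for var, (lo, med, hi) in self.points.items():
            if not lo <= med <= hi:
                raise ValueError(
                    f"{var}: points must be non-decreasing low->medium->high, "
                    f"got {(lo, med, hi)}"
                )
        dev = self.anchor_deviation()
        worst = max(abs(d) for d in dev.values())
        if worst > self.anchor_tolerance + 1e-9:
            raise ValueError(
                f"anchor sums deviate from (0, 50, 100) by {dev} "
                f"(tolerance {self.anchor_tolerance})"
            )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.points)

    def anchor_sums(self) -> tuple[float, float, float]:
        cols = np.array(list(self.points.values()), dtype=float)
        return tuple(float(s) for s in cols.sum(axis=0))

    def anchor_deviation(self) -> dict[str, float]:
        lo, med, hi = self.anchor_sums()
        return {"low": lo - 0.0, "medium": med - 50.0, "high": hi - 100.0}

    def points_for(self, variable: str, code: int) -> float:
        return self.points[variable][code]


@dataclass(frozen=True)
class PLSFit:
    """Bootstrapped PLS result: per-variable median coefficient plus the
    full bootstrap coefficient distributions (B x p)."""

    variables: tuple[str, ...]
    median_coefs: dict[str, float]
    distributions: np.ndarray
    n_components: int
    B: int

    def __post_init__(self):
        if self.B < 1 or self.distributions.shape != (self.B, len(self.variables)):
            raise ValueError("coefficient distributions must be B x p")


def assign_categories(
    cohort: Cohort,
    cutpoints: RiskCutpoints = DEFAULT_CUTPOINTS,
    variables: Sequence[str] = SCORE_VARIABLES,
) -> pd.DataFrame:
    """Code each record's variables as 0 (low), 1 (medium) or 2 (high risk);
    missing values propagate as NaN for the downstream missing policy."""
    data = {
        var: cutpoints.rule(var).code_array(cohort.predictor(var))
        for var in variables
    }
    return pd.DataFrame(data, index=[r.cath_id for r in cohort])


def nipals_pls(
    X: np.ndarray, y: np.ndarray, n_components: int = 1, tol: float = 1e-12
) -> np.ndarray:
    """PLS1 regression coefficients by NIPALS on centered X and y.

    Returns coefficients b such that (y - mean y) ~ (X - mean X) @ b. With a
    single component and orthogonal columns, b is proportional to the vector
    of predictor-outcome covariances. Components whose weight vector norm
    falls below ``tol`` (rank deficiency) terminate the loop early.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    a_used = 0
    for a in range(n_components):
        w = Xc.T @ yc
        norm_w = np.linalg.norm(w)
        if norm_w < tol:
            break
        w /= norm_w
        t = Xc @ w
        tt = float(t @ t)
        if tt < tol:
            break
        p_load = Xc.T @ t / tt
        q = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q * t
        W[:, a], P[:, a], Q[a] = w, p_load, q
        a_used += 1
    if a_used == 0:
        return np.zeros(p)
    W, P, Q = W[:, :a_used], P[:, :a_used], Q[:a_used]
    return W @ np.linalg.solve(P.T @ W, Q)


def fit_pls_bootstrap(
    codes: pd.DataFrame,
    outcomes: np.ndarray,
    n_components: int = 1,
    B: int = 1000,
    resample_unit: str = "cath",
    seed: int = 0,
    patient_ids: np.ndarray | None = None,
    resample: bool = True,
) -> PLSFit:
    """Fit PLS on B bootstrap resamples and extract median coefficients.

    ``resample_unit`` is ``"cath"`` (rows with replacement, the default) or
    ``"patient"`` (cluster bootstrap over ``patient_ids``). ``resample=False``
    fits once on the full data regardless of B (testing hook). Resamples
    with a constant outcome are redrawn, at most 10 times each.
    """
    if codes.isna().any().any():
        bad = codes.columns[codes.isna().any()].tolist()
        raise ValueError(
            f"missing category codes in {bad}; apply a missing policy first"
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    if resample_unit not in ("cath", "patient"):
        raise ValueError(f"unknown resample unit {resample_unit!r}")
    if resample_unit == "patient" and patient_ids is None:
        raise ValueError("patient resampling requires patient_ids")

    X = codes.to_numpy(dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; nothing to fit")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    coefs = np.empty((B, X.shape[1]))

    if resample_unit == "patient":
        patient_ids = np.asarray(patient_ids)
        uniq = pd.unique(patient_ids)
        groups = {pid: np.flatnonzero(patient_ids == pid) for pid in uniq}

    for b in range(B):
        if not resample:
            idx = np.arange(n)
        else:
            for attempt in range(11):
                if resample_unit == "cath":
                    idx = rng.integers(0, n, n)
                else:
                    chosen = rng.choice(uniq, size=len(uniq), replace=True)
                    idx = np.concatenate([groups[pid] for pid in chosen])
                yb = y[idx]
                if yb.min() != yb.max():
                    break
            else:
                raise RuntimeError(
                    "bootstrap resamples repeatedly produced a constant outcome"
                )
        coefs[b] = nipals_pls(X[idx], y[idx], n_components)

    medians = np.median(coefs, axis=0)
    return PLSFit(
        variables=tuple(codes.columns),
        median_coefs={v: float(m) for v, m in zip(codes.columns, medians)},
        distributions=coefs,
        n_components=n_components,
        B=B,
    )


def rescale_to_points(
    fit: PLSFit,
    offsets: Mapping[str, float] | None = None,
    clip_negative: bool = False,
) -> ScoringSystem:
    """Rescale median PLS coefficients into a 0/50/100-anchored point system.

    With linear category codes c in {0, 1, 2}, each variable contributes
    s * beta_v * c points where s = 100 / (2 * sum beta_v), so all-low,
    all-medium and all-high records total exactly 0, 50 and 100. Optional
    per-variable zero-sum ``offsets`` shift the displayed values without
    changing any total.

    Categories are coded in the risk direction, so median coefficients are
    expected to be non-negative; ``clip_negative=True`` floors noise-driven
    negative coefficients at zero (that variable then contributes no
    points) instead of rejecting the fit.
    """
    betas = np.array([fit.median_coefs[v] for v in fit.variables])
    if clip_negative:
        betas = np.maximum(betas, 0.0)
    elif np.any(betas < 0):
        neg = [v for v, b in zip(fit.variables, betas) if b < 0]
        raise ValueError(
            f"negative median coefficient(s) for {neg}; categories must be "
            f"risk-oriented (or pass clip_negative=True)"
        )
    total = betas.sum()
    if total <= 0:
        raise ValueError(
            f"sum of median coefficients is {total:.4g} <= 0; no "
            f"risk-increasing signal to anchor the 0-100 scale"
        )
    s = 100.0 / (2.0 * total)
    offsets = dict(offsets or {})
    if offsets:
        off_sum = sum(offsets.get(v, 0.0) for v in fit.variables)
        if abs(off_sum) > 1e-9:
            raise ValueError(f"offsets must sum to zero, got {off_sum}")
    points = {}
    for v, beta in zip(fit.variables, betas):
        o = offsets.get(v, 0.0)
        step = s * beta
        points[v] = (o, o + step, o + 2 * step)
    return ScoringSystem(points=points, provenance="optimized",
                         anchor_tolerance=1e-9)


def make_pragmatic(
    system: ScoringSystem,
    cutpoints: RiskCutpoints = DEFAULT_CUTPOINTS,
) -> tuple[ScoringSystem, RiskCutpoints, dict[str, float]]:
    """Round a fitted system to whole points over the unified category
    boundaries; returns the rounded system, the unified cutpoints, and the
    anchor-sum deviations introduced by rounding (each bounded by half a
    point per variable)."""
    points = {
        v: tuple(float(np.rint(p)) for p in pts)
        for v, pts in system.points.items()
    }
    pragmatic = ScoringSystem(points=points, provenance="pragmatic",
                              anchor_tolerance=3.5)
    return pragmatic, cutpoints, pragmatic.anchor_deviation()


def score_records(
    cohort: Cohort,
    system: ScoringSystem,
    cutpoints: RiskCutpoints = DEFAULT_CUTPOINTS,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Total score per record: sum over variables of the point value of the
    record's risk category.

    ``missing_policy='error'`` rejects records with missing score variables
    (naming record and variable); ``'assume_low'`` scores missing variables
    as low risk and flags the record.
    """
    if missing_policy not in ("error", "assume_low"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    codes = assign_categories(cohort, cutpoints, system.variables)
    if codes.isna().any().any():
        if missing_policy == "error":
            r, c = np.argwhere(codes.isna().to_numpy())[0]
            raise ValueError(
                f"record {codes.index[r]!r} is missing score variable "
                f"{codes.columns[c]!r} (missing_policy='error')"
            )
        imputed_low = codes.isna().any(axis=1)
        codes = codes.fillna(0)
    else:
        imputed_low = pd.Series(False, index=codes.index)

    point_matrix = np.array(
        [system.points[v] for v in system.variables]
    )  # (p, 3)
    code_arr = codes.to_numpy(dtype=int)
    totals = point_matrix[np.arange(len(system.variables)), code_arr].sum(axis=1)
    out = codes.copy()
    out["total"] = totals
    out["imputed_low"] = imputed_low.to_numpy()
    return out


def permutation_test(
    scores, outcomes, B: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation inference for score discrimination.

    The statistic is the ROC AUC of the scores for the composite outcome;
    the null distribution permutes outcome labels across catheterizations.
    Returns (observed AUC, p) with the add-one estimator
    p = (1 + #{AUC_perm >= AUC_obs}) / (B + 1).
    """
    if B < 200:
        raise ValueError("use at least 200 permutations")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    observed = roc_auc(s, y)  # validates both classes present

    from scipy.stats import rankdata

    ranks = rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    rng = np.random.default_rng(seed)
    # permuting labels == choosing which entries are positive
    perm_sums = np.empty(B)
    for b in range(B):
        idx = rng.choice(y.size, size=n_pos, replace=False)
        perm_sums[b] = ranks[idx].sum()
    perm_auc = (perm_sums - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    exceed = int(np.sum(perm_auc >= observed - 1e-12))
    return observed, (1 + exceed) / (B + 1)


# ---------------------------------------------------------------------------
# Scoring-system files (structured text, round-trip safe)
# ---------------------------------------------------------------------------

def save_system(
    system: ScoringSystem,
    path: str | Path,
    cutpoints: RiskCutpoints = DEFAULT_CUTPOINTS,
) -> None:
    payload = {
        "provenance": system.provenance,
        "anchor_tolerance": system.anchor_tolerance,
        "variables": [
            {
                "name": v,
                "points": list(system.points[v]),
                "rule": {
                    "lower": cutpoints.rule(v).lower,
                    "upper": cutpoints.rule(v).upper,
                    "direction": cutpoints.rule(v).direction,
                },
            }
            for v in system.variables
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_system(path: str | Path) -> tuple[ScoringSystem, RiskCutpoints]:
    payload = json.loads(Path(path).read_text())
    points = {
        entry["name"]: tuple(entry["points"])
        for entry in payload["variables"]
    }
    rules = {
        entry["name"]: CutpointRule(**entry["rule"])
        for entry in payload["variables"]
    }
    system = ScoringSystem(
        points=points,
        provenance=payload["provenance"],
        anchor_tolerance=payload["anchor_tolerance"],
    )
    return system, RiskCutpoints(rules=rules)
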