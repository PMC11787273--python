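"""The published pragmatic scoring system, hard-coded and bit-exact.

Seven pre-operative echocardiographic variables each fall into a low /
medium / high risk band and contribute a fixed number of points; the three
column sums are exactly 0, 50 and 100, so a child with uniformly low-risk
findings scores 0 and one with uniformly high-risk findings scores 100.

Bands: age > 7 y is low risk, 3-7 y medium, < 3 y high (younger children are
at higher risk); qualitative severities none-mild / mild-moderate-to-
moderate / moderate-severe-to-severe; Doppler velocities < 3.0 m/s /
3.0-5.0 m/s / > 5.0 m/s. The middle intervals are closed: age exactly 3 or
7 years and velocities exactly 3.0 or 5.0 m/s are medium risk.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import EchoExam
from .scorebuild import (
    DEFAULT_CUTPOINTS,
    SCORE_VARIABLES,
    RiskCutpoints,
    ScoringSystem,
)

__all__ = [
    "TABLE_POINTS",
    "PRAGMATIC_SYSTEM",
    "PRAGMATIC_CUTPOINTS",
    "ScoreItem",
    "pragmatic_total",
    "explain_score",
]

# (low, medium, high) points per variable; columns sum to 0 / 50 / 100.
TABLE_POINTS: dict[str, tuple[int, int, int]] = {
    "age_years": (-17, -13, -9),
    "rv_dysfunction": (5, 14, 24),
    "rv_dilatation": (3, 11, 19),
    "tr_severity": (0, 5, 9),
    "tr_vmax": (2, 9, 16),
    "pr_severity": (7, 19, 31),
    "pr_vmax": (0, 5, 10),
}

PRAGMATIC_SYSTEM = ScoringSystem(
    points={v: tuple(float(p) for p in TABLE_POINTS[v]) for v in SCORE_VARIABLES},
    provenance="reference",
    anchor_tolerance=0.0,
)

PRAGMATIC_CUTPOINTS: RiskCutpoints = DEFAULT_CUTPOINTS


@dataclass(frozen=True)
class ScoreItem:
    variable: str
    value: float
    category: str
    points: float
    running_total: float


def _echo_value(echo: EchoExam, variable: str) -> float | None:
    v = getattr(echo, variable)
    return v.value if variable.endswith("severity") or variable.startswith("rv_") else v


def pragmatic_total(echo: EchoExam, missing_policy: str = "error") -> float:
    """Total pragmatic risk score (0-100) for one echocardiogram.

    ``missing_policy='error'`` (default) rejects exams missing any of the
    seven score variables; ``'assume_low'`` scores missing variables as low
    risk (use only for exploration — the total is then a lower bound).
    """
    return explain_score(echo, missing_policy)[-1].running_total


def explain_score(
    echo: EchoExam, missing_policy: str = "error"
) -> list[ScoreItem]:
    """Itemized score breakdown: per-variable category, points and running
    total. The final running total equals :func:`pragmatic_total`."""
    if missing_policy not in ("error", "assume_low"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    items: list[ScoreItem] = []
    total = 0.0
    for variable in SCORE_VARIABLES:
        value = _echo_value(echo, variable)
        if value is None:
            if missing_policy == "error":
                raise ValueError(
                    f"score variable {variable!r} is missing "
                    f"(missing_policy='error')"
                )
            code, category = 0, "low (assumed: missing)"
        else:
            code = PRAGMATIC_CUTPOINTS.rule(variable).code(value)
            category = ("low", "medium", "high")[code]
        points = float(TABLE_POINTS[variable][code])
        total += points
        items.append(
            ScoreItem(
                variable=variable,
                value=float("nan") if value is None else float(value),
                category=category,
                points=points,
                running_total=total,
            )
        )
    return items
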