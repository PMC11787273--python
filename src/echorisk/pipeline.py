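"""End-to-end score development and the reproducible run directory.

``develop_score`` chains the full statistical recipe on one cohort:
univariate mixed-effects screening -> collinearity filter -> risk-category
binning -> bootstrapped PLS -> 0/50/100 rescaling -> pragmatic rounding ->
permutation inference. ``run_pipeline`` drives simulate/load -> develop ->
score -> evaluate -> report and writes every table plus a manifest with all
seeds and parameters, so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, summarize_cohort, write_cohort
from .metrics import evaluate_scores, optimism_correct, roc_auc
from .outcome_models import confirm_association, covariate_check, fit_risk_curves, group_compare
from .pragmatic import PRAGMATIC_SYSTEM
from .scorebuild import (
    DEFAULT_CUTPOINTS,
    SCORE_VARIABLES,
    RiskCutpoints,
    ScoringSystem,
    assign_categories,
    fit_pls_bootstrap,
    make_pragmatic,
    permutation_test,
    rescale_to_points,
    save_system,
    score_records,
)
from .screening import (
    FAST,
    PosteriorSummary,
    PriorSpec,
    SamplerSettings,
    collinearity_filter,
    screen_all,
)
from .simulate import SimConfig, simulate_cohort

__all__ = [
    "DEFAULT_CANDIDATES",
    "DevelopmentResult",
    "develop_score",
    "score_development_pipeline",
    "RunConfig",
    "StageError",
    "run_pipeline",
]

DEFAULT_CANDIDATES: tuple[str, ...] = SCORE_VARIABLES + ("pr_edv",)


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class DevelopmentResult:
    screening: list[PosteriorSummary]
    selected: list[PosteriorSummary]
    kept: list[PosteriorSummary]
    dropped: pd.DataFrame
    system: ScoringSystem
    pragmatic_system: ScoringSystem
    cutpoints: RiskCutpoints
    scores: pd.DataFrame
    auc_roc: float
    permutation_p: float

    @property
    def score_values(self) -> np.ndarray:
        return self.scores["total"].to_numpy()

    def screening_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.screening]
        )


def develop_score(
    cohort: Cohort,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    prior: PriorSpec | None = None,
    settings: SamplerSettings = FAST,
    cutpoints: RiskCutpoints = DEFAULT_CUTPOINTS,
    collinearity_threshold: float = 0.6,
    B_pls: int = 1000,
    B_perm: int = 999,
    resample_unit: str = "cath",
    missing_policy: str = "error",
    seed: int = 0,
) -> DevelopmentResult:
    """Run the full score-development recipe on one cohort."""
    screening = screen_all(cohort, list(candidates), prior, settings, seed)
    selected = [s for s in screening if s.selected]
    if not selected:
        raise StageError("screening", "no predictor passed the univariate screen")
    kept, dropped = collinearity_filter(selected, cohort, collinearity_threshold)

    variables = [s.variable for s in kept]
    codes = assign_categories(cohort, cutpoints, variables)
    if codes.isna().any().any():
        if missing_policy == "error":
            bad = codes.columns[codes.isna().any()].tolist()
            raise StageError(
                "binning", f"missing values in score variables {bad}"
            )
        codes = codes.fillna(0)
    fit = fit_pls_bootstrap(
        codes,
        cohort.adverse(),
        B=B_pls,
        resample_unit=resample_unit,
        seed=seed,
        patient_ids=cohort.patient_ids(),
    )
    system = rescale_to_points(fit, clip_negative=True)
    pragmatic, cutpoints, _deviation = make_pragmatic(system, cutpoints)
    scores = score_records(cohort, pragmatic, cutpoints, missing_policy)
    auc, p_perm = permutation_test(
        scores["total"].to_numpy(), cohort.adverse(), B=B_perm, seed=seed
    )
    return DevelopmentResult(
        screening=screening,
        selected=selected,
        kept=kept,
        dropped=dropped,
        system=system,
        pragmatic_system=pragmatic,
        cutpoints=cutpoints,
        scores=scores,
        auc_roc=auc,
        permutation_p=p_perm,
    )


def score_development_pipeline(
    variables: Sequence[str] = SCORE_VARIABLES,
    cutpoints: RiskCutpoints = DEFAULT_CUTPOINTS,
    B_pls: int = 200,
    seed: int = 0,
    on_degenerate: str = "uniform",
) -> Callable[[Cohort], Callable[[Cohort], np.ndarray]]:
    """The binning -> bootstrap-PLS -> rescale procedure as a single unit,
    packaged for optimism correction: ``pipeline(cohort)`` fits the scoring
    system on that cohort and returns a scorer for any cohort.

    When every clipped coefficient is zero (possible on noise-only
    resamples), ``on_degenerate='uniform'`` substitutes the data-independent
    equal-points system so the resample still yields a score;
    ``'raise'`` propagates the error instead."""

    p = len(variables)
    uniform = ScoringSystem(
        points={v: (0.0, 50.0 / p, 100.0 / p) for v in variables},
        provenance="fitted",
        anchor_tolerance=1e-9,
    )

    def pipeline(cohort: Cohort) -> Callable[[Cohort], np.ndarray]:
        codes = assign_categories(cohort, cutpoints, variables)
        fit = fit_pls_bootstrap(
            codes, cohort.adverse(), B=B_pls, seed=seed,
            patient_ids=cohort.patient_ids(),
        )
        try:
            system = rescale_to_points(fit, clip_negative=True)
        except ValueError:
            if on_degenerate != "uniform":
                raise
            system = uniform

        def scorer(target: Cohort) -> np.ndarray:
            return score_records(target, system, cutpoints)["total"].to_numpy()

        return scorer

    return pipeline


@dataclass
class RunConfig:
    """Parameters of one end-to-end run; flags override config-file values
    upstream in the CLI, and everything lands in the manifest."""

    out_dir: str = "run"
    seed: int = 0
    cohort_path: str | None = None  # None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    prior_coef_sd: float = 2.5
    prior_re_sd_scale: float = 1.0
    method: str = "laplace"
    B_pls: int = 1000
    B_perm: int = 999
    B_boot: int = 500
    B_optimism: int = 200
    collinearity_threshold: float = 0.6
    missing_policy: str = "error"
    optimism: bool = True

    def prior(self) -> PriorSpec:
        return PriorSpec(coef_sd=self.prior_coef_sd,
                         re_sd_scale=self.prior_re_sd_scale)

    def settings(self) -> SamplerSettings:
        return SamplerSettings(method=self.method)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        d["python"] = platform.python_version()
        return d


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate/load -> develop -> score -> evaluate -> report.

    Returns the run directory. On a stage failure, partial outputs are kept
    next to a ``FAILED`` marker naming the stage, and the error re-raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "input"
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
        else:
            cohort = simulate_cohort(config.sim, config.seed)
            write_cohort(cohort, out / "cohort.csv")
        _df_to_csv(summarize_cohort(cohort), out / "cohort_summary.csv")

        stage = "develop"
        try:
            dev = develop_score(
                cohort,
                candidates=config.candidates,
                prior=config.prior(),
                settings=config.settings(),
                collinearity_threshold=config.collinearity_threshold,
                B_pls=config.B_pls,
                B_perm=config.B_perm,
                missing_policy=config.missing_policy,
                seed=config.seed,
            )
        except StageError:
            raise
        except ValueError as err:
            raise StageError("develop", str(err)) from err
        _df_to_csv(dev.screening_table(), out / "screening.csv")
        _df_to_csv(dev.dropped, out / "collinearity_dropped.csv")
        save_system(dev.system, out / "scoring_system.json", dev.cutpoints)
        save_system(dev.pragmatic_system, out / "pragmatic_system.json",
                    dev.cutpoints)
        dev.scores.to_csv(out / "scores.csv", float_format="%.10g")

        stage = "evaluate"
        y = cohort.adverse()
        scores = dev.score_values
        report = evaluate_scores(scores, y, B=config.B_boot, seed=config.seed)
        eval_dict = report.to_dict()
        eval_dict["permutation_p"] = dev.permutation_p
        if config.optimism:
            opt = optimism_correct(
                cohort,
                score_development_pipeline(
                    variables=tuple(s.variable for s in dev.kept),
                    cutpoints=dev.cutpoints,
                    B_pls=min(config.B_pls, 100),
                    seed=config.seed,
                ),
                metric=roc_auc,
                B=config.B_optimism,
                seed=config.seed,
            )
            eval_dict["optimism_auc_roc"] = opt.optimism
            eval_dict["corrected_auc_roc"] = opt.corrected
        (out / "eval.json").write_text(json.dumps(eval_dict, indent=2))

        stage = "report"
        curves = fit_risk_curves(scores, cohort=cohort, seed=config.seed)
        curve_rows = []
        for c in curves:
            for g, m, lo, hi in zip(c.grid, c.risk_median, c.risk_low, c.risk_high):
                curve_rows.append(
                    {"outcome": c.outcome, "score": g, "risk": m,
                     "risk_low": lo, "risk_high": hi}
                )
        _df_to_csv(pd.DataFrame(curve_rows), out / "risk_curves.csv")
        assoc = confirm_association(cohort, scores, config.prior(),
                                    config.settings(), config.seed)
        adverse_mask = y.astype(bool)
        comparison = group_compare(scores[adverse_mask], scores[~adverse_mask])
        report_extra = {
            "score_association": dataclasses.asdict(assoc),
            "group_compare_adverse_vs_not": dataclasses.asdict(comparison),
        }
        try:
            sept = covariate_check(cohort, "septostomy",
                                   config.prior(), config.settings(),
                                   config.seed)
            report_extra["septostomy"] = {
                "odds_ratio": sept.odds_ratio,
                "or_ci": sept.or_ci,
                "separated": sept.separated,
            }
        except ValueError as err:
            report_extra["septostomy"] = {"skipped": str(err)}
        (out / "report.json").write_text(json.dumps(report_extra, indent=2))

        stage = "manifest"
        (out / "manifest.json").write_text(
            json.dumps(config.to_manifest(), indent=2)
        )
    except Exception as err:
        marker = err.stage if isinstance(err, StageError) else stage
        (out / "FAILED").write_text(f"stage: {marker}\n{err}\n")
        raise
    return out
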