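"""Synthetic cohort generator.

Emulates a pediatric idiopathic-PAH catheterization cohort: ~93 patients with
repeated catheterizations (~1.7 per patient), ordinal echo severities driven
by a patient-level latent disease-severity factor, Doppler regurgitant
velocities correlated with that factor (and with each other: the two
pulmonary-regurgitation velocities at r ~ 0.68), and a ~10% adverse-event
rate drawn from a logistic model with a patient-level random intercept.

All randomness flows from a single ``numpy`` generator seeded by the caller,
so cohorts are reproducible bit-for-bit. The logistic intercept is calibrated
by Monte-Carlo so the marginal event rate hits the configured prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .cohort import (
    CathRecord,
    Cohort,
    EchoExam,
    HemoRecord,
    OutcomeFlags,
    SEVERITY_LABELS,
    SeverityGrade,
)

__all__ = ["SimConfig", "simulate_cohort", "calibrate_intercept"]

# Log-odds ratios per SD of each (standardized) predictor. Signs follow the
# clinical direction: younger age and worse right-heart findings raise risk.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "age_years": -0.8,
    "rv_dysfunction": 0.9,
    "rv_dilatation": 0.8,
    "tr_severity": 0.7,
    "tr_vmax": 0.8,
    "pr_severity": 0.7,
    "pr_vmax": 0.7,
    "pr_edv": 0.0,  # collinear with pr_vmax; risk carried by pr_vmax
}

# Loadings of each echo measure on the patient-level severity factor,
# chosen to reproduce the observed inter-correlation range (r ~ 0.5-0.6
# between echo pressure surrogates and invasive mPAP).
DEFAULT_LATENT_LOADINGS: dict[str, float] = {
    "rv_dysfunction": 0.75,
    "rv_dilatation": 0.70,
    "tr_severity": 0.65,
    "tr_vmax": 0.60,
    "pr_severity": 0.55,
    "pr_vmax": 0.50,
    "pr_edv": 0.50,
    "mpap": 0.80,
}

# Marginal grade distribution for ordinal severities: cumulative probability
# up to and including each grade below "severe" (most catheterizations show
# none-to-mild disease, a minority moderate-or-worse).
_GRADE_CUMPROBS = np.array([0.40, 0.50, 0.70, 0.76, 0.85, 0.93])
_GRADE_THRESHOLDS = norm.ppf(_GRADE_CUMPROBS)

# Observed-scale moments for the quantitative echo measures (m/s; years).
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 8.8, 4.6, 0.2, 18.0
_TR_VMAX_MEAN, _TR_VMAX_SD = 4.1, 1.0
_PR_VMAX_MEAN, _PR_VMAX_SD = 2.8, 1.0
_PR_EDV_MEAN, _PR_EDV_SD = 2.5, 0.7

_MPAP_MEAN, _MPAP_SD = 48.0, 23.0

_CALIBRATION_SEED = 709551  # internal stream for intercept calibration only


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the study conditions: 93 patients, ~1.7
    catheterizations each, 10% adverse-event prevalence, unit random-
    intercept SD on the logit scale, and r = 0.68 between the two
    pulmonary-regurgitation velocities.
    """

    n_patients: int = 93
    mean_caths_per_patient: float = 1.7
    target_prevalence: float = 0.10
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    random_intercept_sd: float = 1.0
    latent_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_LOADINGS)
    )
    pr_velocity_corr: float = 0.68

    def __post_init__(self):
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not -1 < self.pr_velocity_corr < 1:
            raise ValueError("pr_velocity_corr must lie in (-1, 1)")
        if self.mean_caths_per_patient < 1:
            raise ValueError("mean_caths_per_patient must be >= 1")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        unknown = set(self.effect_sizes) - set(DEFAULT_EFFECT_SIZES)
        if unknown:
            raise ValueError(f"unknown effect-size variables {sorted(unknown)}")

    def null(self) -> "SimConfig":
        """A copy with every predictor effect set to zero."""
        return replace(self, effect_sizes={k: 0.0 for k in self.effect_sizes})

    def single_effect(self, variable: str, beta: float) -> "SimConfig":
        """A copy in which only ``variable`` carries (log-OR) effect ``beta``."""
        effects = {k: 0.0 for k in DEFAULT_EFFECT_SIZES}
        effects[variable] = beta
        return replace(self, effect_sizes=effects)

    def _key(self) -> tuple:
        return (
            self.n_patients,
            self.mean_caths_per_patient,
            self.target_prevalence,
            tuple(sorted(self.effect_sizes.items())),
            self.random_intercept_sd,
            tuple(sorted(self.latent_loadings.items())),
            self.pr_velocity_corr,
        )


def _pr_residual_corr(config: SimConfig) -> float:
    """Residual correlation between pr_vmax and pr_edv noise terms needed so
    the total correlation (latent-shared plus residual) hits the target."""
    lp = config.latent_loadings.get("pr_vmax", 0.0)
    le = config.latent_loadings.get("pr_edv", 0.0)
    denom = np.sqrt((1 - lp**2) * (1 - le**2))
    if denom <= 0:
        return 0.0
    r = (config.pr_velocity_corr - lp * le) / denom
    return float(np.clip(r, -0.999, 0.999))


def _draw_predictors(config: SimConfig, f: np.ndarray, rng: np.random.Generator):
    """Draw per-catheterization predictors given the patient latent factor
    ``f`` (already expanded to one entry per catheterization)."""
    n = f.size
    load = config.latent_loadings

    def latent(name: str, eps: np.ndarray) -> np.ndarray:
        lam = load.get(name, 0.0)
        return lam * f + np.sqrt(max(0.0, 1 - lam**2)) * eps

    cols: dict[str, np.ndarray] = {}
    for name in ("rv_dysfunction", "rv_dilatation", "tr_severity", "pr_severity"):
        z = latent(name, rng.standard_normal(n))
        cols[name] = np.searchsorted(_GRADE_THRESHOLDS, z).astype(float)

    cols["tr_vmax"] = np.clip(
        _TR_VMAX_MEAN + _TR_VMAX_SD * latent("tr_vmax", rng.standard_normal(n)),
        0.5, 7.5,
    )
    # pr_vmax / pr_edv share the latent factor plus a correlated residual
    r_e = _pr_residual_corr(config)
    e1 = rng.standard_normal(n)
    e2 = r_e * e1 + np.sqrt(1 - r_e**2) * rng.standard_normal(n)
    cols["pr_vmax"] = np.clip(
        _PR_VMAX_MEAN + _PR_VMAX_SD * latent("pr_vmax", e1), 0.3, 7.5
    )
    cols["pr_edv"] = np.clip(
        _PR_EDV_MEAN + _PR_EDV_SD * latent("pr_edv", e2), 0.3, 7.5
    )
    cols["mpap"] = np.clip(
        _MPAP_MEAN + _MPAP_SD * latent("mpap", rng.standard_normal(n)), 12.0, 130.0
    )
    return cols


def _draw_ages(config: SimConfig, n_caths: np.ndarray, rng: np.random.Generator):
    """Patient base ages (truncated normal) expanded to per-cath ages that
    drift upward slightly across repeat catheterizations."""
    a, b = (_AGE_LO - _AGE_MEAN) / _AGE_SD, (_AGE_HI - _AGE_MEAN) / _AGE_SD
    base = truncnorm.rvs(
        a, b, loc=_AGE_MEAN, scale=_AGE_SD, size=config.n_patients,
        random_state=rng,
    )
    ages = []
    for pat_age, k in zip(base, n_caths):
        drift = 0.5 * np.arange(k) + 0.1 * rng.random(k)
        ages.append(np.clip(pat_age + drift, 0.3, 17.9))
    return np.concatenate(ages)


# Ordinal severity codes map to Likert values for standardization & scoring.
_CODE_TO_LIKERT = np.array(
    [0.0, 0.25, 1.0, 1.5, 2.0, 2.5, 3.0]
)


def _predictor_values(cols: Mapping[str, np.ndarray], ages: np.ndarray):
    """Assemble the model-scale predictor matrix (grades on the Likert scale)."""
    out = {"age_years": ages}
    for name, x in cols.items():
        if name in ("rv_dysfunction", "rv_dilatation", "tr_severity", "pr_severity"):
            out[name] = _CODE_TO_LIKERT[x.astype(int)]
        else:
            out[name] = x
    return out


_calibration_cache: dict[tuple, dict] = {}


def _calibration(config: SimConfig, n_mc: int = 200_000) -> dict:
    """Monte-Carlo calibration: predictor means/SDs on the population scale
    and the intercept alpha matching the target prevalence.

    Deterministic for a given config (private RNG stream, independent of the
    cohort seed); cached, since it is shared by every cohort drawn from the
    same config.
    """
    key = config._key()
    if key in _calibration_cache:
        return _calibration_cache[key]

    rng = np.random.default_rng(_CALIBRATION_SEED)
    f = rng.standard_normal(n_mc)
    cols = _draw_predictors(config, f, rng)
    a, b = (_AGE_LO - _AGE_MEAN) / _AGE_SD, (_AGE_HI - _AGE_MEAN) / _AGE_SD
    ages = truncnorm.rvs(a, b, loc=_AGE_MEAN, scale=_AGE_SD, size=n_mc,
                         random_state=rng)
    values = _predictor_values(cols, ages)

    moments = {
        name: (float(np.mean(x)), float(np.std(x)))
        for name, x in values.items()
    }
    g = np.zeros(n_mc)
    for name, beta in config.effect_sizes.items():
        if beta == 0.0:
            continue
        m, s = moments[name]
        g += beta * (values[name] - m) / s
    if config.random_intercept_sd > 0:
        g += config.random_intercept_sd * rng.standard_normal(n_mc)

    target = config.target_prevalence

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + g))) - target

    try:
        alpha = brentq(gap, -30.0, 30.0, xtol=1e-10)
    except ValueError as err:
        raise RuntimeError(
            f"intercept calibration failed to bracket the target prevalence "
            f"{target}: {err}"
        ) from None
    achieved = target + gap(alpha)
    if abs(achieved - target) > 0.005:
        raise RuntimeError(
            f"intercept calibration off target: achieved {achieved:.4f} "
            f"vs target {target:.4f}"
        )
    out = {"alpha": float(alpha), "moments": moments}
    _calibration_cache[key] = out
    return out


def calibrate_intercept(config: SimConfig) -> float:
    """Intercept (logit scale) at which the marginal adverse-event
    probability, averaged over predictors and random intercepts, equals the
    configured target prevalence to within +/-0.005."""
    return _calibration(config)["alpha"]


def simulate_cohort(config: SimConfig, seed: int) -> Cohort:
    """Draw one synthetic cohort. Deterministic given ``(config, seed)``."""
    calib = _calibration(config)
    rng = np.random.default_rng(seed)

    n_caths = 1 + rng.poisson(config.mean_caths_per_patient - 1.0,
                              config.n_patients)
    total = int(n_caths.sum())
    patient_index = np.repeat(np.arange(config.n_patients), n_caths)

    f_pat = rng.standard_normal(config.n_patients)
    u_pat = config.random_intercept_sd * rng.standard_normal(config.n_patients)
    f = f_pat[patient_index]
    u = u_pat[patient_index]

    ages = _draw_ages(config, n_caths, rng)
    cols = _draw_predictors(config, f, rng)
    values = _predictor_values(cols, ages)

    eta = np.full(total, calib["alpha"]) + u
    for name, beta in config.effect_sizes.items():
        if beta == 0.0:
            continue
        m, s = calib["moments"][name]
        eta += beta * (values[name] - m) / s
    adverse = rng.random(total) < expit(eta)

    # Split the composite: complications in ~10/16 of event catheterizations,
    # escalations in ~12/16 (both can co-occur); at least one must hold.
    comp = adverse & (rng.random(total) < 0.625)
    esc = adverse & (rng.random(total) < 0.75)
    fix = adverse & ~comp & ~esc
    esc = esc | fix

    septostomy = rng.random(total) < 0.16

    records = []
    for i in range(total):
        grades = {
            name: SeverityGrade.from_value(_CODE_TO_LIKERT[int(cols[name][i])])
            for name in ("rv_dysfunction", "rv_dilatation", "tr_severity",
                         "pr_severity")
        }
        echo = EchoExam(
            age_years=round(float(ages[i]), 2),
            tr_vmax=round(float(cols["tr_vmax"][i]), 2),
            pr_vmax=round(float(cols["pr_vmax"][i]), 2),
            pr_edv=round(float(cols["pr_edv"][i]), 2),
            **grades,
        )
        labels: tuple[str, ...] = ()
        if comp[i]:
            labels += ("pulmonary_hypertensive_crisis",)
        if esc[i]:
            labels += ("emergency_icu_admission",)
        outcome = OutcomeFlags(
            complication=bool(comp[i]),
            escalation=bool(esc[i]),
            event_labels=labels,
        )
        hemo = HemoRecord(mpap=round(float(cols["mpap"][i]), 1))
        records.append(
            CathRecord(
                patient_id=f"P{patient_index[i]:04d}",
                cath_id=f"C{i:05d}",
                echo=echo,
                hemo=hemo,
                septostomy=bool(septostomy[i]),
                outcome=outcome,
            )
        )
    return Cohort(records=tuple(records))
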