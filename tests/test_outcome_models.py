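"""Post-hoc outcome models: risk curves, mixed-effects confirmation,
covariate checks and the rank-sum group comparison."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy.special import expit

from echorisk.cohort import CathRecord, Cohort, OutcomeFlags
from echorisk.outcome_models import (
    covariate_check,
    confirm_association,
    fit_risk_curves,
    group_compare,
    outcome_indicators,
)
from echorisk.pragmatic import PRAGMATIC_SYSTEM
from echorisk.scorebuild import score_records
from echorisk.screening import FAST
from echorisk.simulate import SimConfig, simulate_cohort

from conftest import make_echo, make_record


class TestRiskCurves:
    def test_separable_outcome_direction(self, rng):
        scores = rng.uniform(0, 100, 200)
        y = (scores > np.median(scores)).astype(int)
        curves = fit_risk_curves(scores, {"adverse": y}, seed=1)
        c = curves[0]
        assert c.slope > 0
        assert c.risk_median[0] < 0.1 and c.risk_median[-1] > 0.9
        assert c.grid[0] == scores.min() and c.grid[-1] == scores.max()

    def test_complementary_outcome_flips_slope(self, rng):
        scores = rng.uniform(0, 100, 300)
        p = expit(-3 + 0.05 * scores)
        y = (rng.random(300) < p).astype(int)
        curves = fit_risk_curves(
            scores, {"adverse": y, "no_adverse": 1 - y}, seed=2
        )
        assert curves[0].slope > 0 > curves[1].slope

    def test_bands_bracket_median_within_unit_interval(self, study_cohort):
        scores = score_records(study_cohort, PRAGMATIC_SYSTEM)["total"].to_numpy()
        for c in fit_risk_curves(scores, cohort=study_cohort, seed=3):
            assert np.all((c.risk_low >= 0) & (c.risk_high <= 1))
            assert np.all(c.risk_low <= c.risk_median)
            assert np.all(c.risk_median <= c.risk_high)

    def test_sparse_outcome_skipped_with_warning(self, rng):
        scores = rng.uniform(0, 100, 50)
        y = np.zeros(50, int)
        y[:2] = 1  # below min_events
        with pytest.warns(UserWarning, match="skipped"):
            curves = fit_risk_curves(scores, {"rare": y}, seed=0)
        assert curves == []

    def test_slope_interval_coverage_under_the_null(self, rng):
        """Score-independent outcomes: the 95% slope interval should cover
        zero in roughly 95% of replicates."""
        covered = 0
        reps = 200
        for i in range(reps):
            scores = rng.uniform(0, 100, 158)
            y = np.zeros(158, int)
            y[rng.choice(158, 16, replace=False)] = 1
            c = fit_risk_curves(scores, {"adverse": y}, seed=i)[0]
            lo, hi = c.slope_ci
            covered += lo <= 0 <= hi
        assert 0.90 <= covered / reps <= 0.99

    def test_overlapping_vs_exclusive_indicators(self, study_cohort):
        over = outcome_indicators(study_cohort, overlapping=True)
        excl = outcome_indicators(study_cohort, overlapping=False)
        assert (excl["escalation"] <= over["escalation"]).all()
        both = over["complication"] & over["escalation"]
        assert (excl["escalation"][both.astype(bool)] == 0).all()


class TestConfirmAssociation:
    def test_recovers_signal_from_generating_model(self, study_cohort):
        scores = score_records(study_cohort, PRAGMATIC_SYSTEM)["total"].to_numpy()
        fit = confirm_association(study_cohort, scores, settings=FAST)
        assert fit.selected
        assert fit.beta_median > 0

    def test_deterministic(self, study_cohort):
        scores = score_records(study_cohort, PRAGMATIC_SYSTEM)["total"].to_numpy()
        a = confirm_association(study_cohort, scores, settings=FAST, seed=4)
        b = confirm_association(study_cohort, scores, settings=FAST, seed=4)
        assert a == b

    def test_permuted_scores_rarely_selected(self, study_cohort):
        scores = score_records(study_cohort, PRAGMATIC_SYSTEM)["total"].to_numpy()
        rng = np.random.default_rng(0)
        hits = 0
        reps = 120
        for _ in range(reps):
            fit = confirm_association(
                study_cohort, rng.permutation(scores), settings=FAST
            )
            hits += fit.selected
        assert hits / reps <= 0.11  # ~5% nominal


def _binary_covariate_cohort(n=5000, log_or=np.log(2.0), seed=0):
    """Single-cath patients; septostomy doubles the odds of an event."""
    rng = np.random.default_rng(seed)
    sept = rng.random(n) < 0.4
    p = expit(-2.0 + log_or * sept)
    y = rng.random(n) < p
    records = tuple(
        CathRecord(
            patient_id=f"p{i}",
            cath_id=f"c{i}",
            echo=make_echo(),
            septostomy=bool(sept[i]),
            outcome=OutcomeFlags(complication=bool(y[i]), escalation=False),
        )
        for i in range(n)
    )
    return Cohort(records=records)


class TestCovariateCheck:
    def test_recovers_doubled_odds_at_large_n(self):
        res = covariate_check(_binary_covariate_cohort(), "septostomy",
                              settings=FAST)
        assert res.binary
        assert 1.7 <= res.odds_ratio <= 2.4
        assert not res.separated

    def test_null_covariate_interval_coverage(self):
        """Independent covariate: the 95% interval should cover zero in
        most replicates (a single draw can legitimately miss)."""
        covered = 0
        reps = 20
        for i in range(reps):
            cohort = _binary_covariate_cohort(n=600, log_or=0.0, seed=100 + i)
            res = covariate_check(cohort, "septostomy", settings=FAST)
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered >= 16

    def test_separation_detected_and_kept_finite(self):
        rng = np.random.default_rng(1)
        records = tuple(
            CathRecord(
                patient_id=f"p{i}", cath_id=f"c{i}", echo=make_echo(),
                septostomy=i < 30,
                outcome=OutcomeFlags(complication=i < 30, escalation=False),
            )
            for i in range(200)
        )
        res = covariate_check(Cohort(records=records), "septostomy",
                              settings=FAST)
        assert res.separated
        assert np.isfinite(res.beta)


class TestGroupCompare:
    def test_identical_groups(self):
        out = group_compare([3, 3, 3], [3, 3, 3])
        assert out.z == 0
        assert out.p == 1.0

    def test_extreme_separation_matches_exhaustive_permutation(self):
        out = group_compare([1, 2, 3], [10, 11, 12])
        # brute force: rank-sum of group A over all 3-subsets of 6 ranks
        ranks = np.arange(1, 7)
        mu = 3 * 7 / 2
        obs_dev = abs(6 - mu)
        count = sum(
            abs(sum(c) - mu) >= obs_dev
            for c in itertools.combinations(ranks, 3)
        )
        assert out.exact
        assert out.p == pytest.approx(count / 20)
        assert out.z < -1.9
        assert out.median_b == 11

    def test_exact_matches_scipy_for_tie_free_samples(self):
        from scipy.stats import mannwhitneyu

        a, b = [1.0, 4.0, 6.0, 7.0], [2.0, 3.0, 5.0, 8.0]
        ours = group_compare(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p == pytest.approx(ref.pvalue)

    def test_large_sample_z_matches_scipy_asymptotics(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.integers(0, 15, 40).astype(float)
        b = rng.integers(3, 18, 55).astype(float)
        ours = group_compare(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
        assert not ours.exact
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_swapping_groups_negates_z_keeps_p(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(1.0, 1.0, size=25)
        ab = group_compare(a, b)
        ba = group_compare(b, a)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])
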