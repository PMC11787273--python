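"""Score development: category binning, NIPALS PLS against closed-form and
library oracles, anchored rescaling, pragmatic rounding, record scoring and
permutation inference."""

import numpy as np
import pandas as pd
import pytest

from echorisk.cohort import Cohort
from echorisk.pragmatic import PRAGMATIC_SYSTEM, TABLE_POINTS
from echorisk.scorebuild import (
    DEFAULT_CUTPOINTS,
    SCORE_VARIABLES,
    PLSFit,
    ScoringSystem,
    assign_categories,
    fit_pls_bootstrap,
    load_system,
    make_pragmatic,
    nipals_pls,
    permutation_test,
    rescale_to_points,
    save_system,
    score_records,
)

from conftest import make_echo, make_record, make_simple_cohort


class TestAssignCategories:
    @pytest.mark.parametrize(
        "variable, value, code",
        [
            ("age_years", 8.8, 0),
            ("age_years", 7.0, 1),
            ("age_years", 3.0, 1),
            ("age_years", 2.9, 2),
            ("tr_vmax", 4.2, 1),
            ("tr_vmax", 2.99, 0),
            ("tr_vmax", 3.0, 1),
            ("tr_vmax", 5.0, 1),
            ("tr_vmax", 5.01, 2),
        ],
    )
    def test_boundary_conventions(self, variable, value, code):
        assert DEFAULT_CUTPOINTS.rule(variable).code(value) == code

    @pytest.mark.parametrize(
        "likert, code",
        [(0.0, 0), (0.25, 0), (1.0, 0), (1.5, 1), (2.0, 1), (2.5, 2), (3.0, 2)],
    )
    def test_ordinal_bands(self, likert, code):
        assert DEFAULT_CUTPOINTS.rule("rv_dysfunction").code(likert) == code

    def test_matrix_shape_and_codes(self, study_cohort):
        codes = assign_categories(study_cohort)
        assert codes.shape == (len(study_cohort), len(SCORE_VARIABLES))
        assert codes.isin([0, 1, 2]).all().all()


class TestNipals:
    def test_covariance_direction_on_orthogonal_design(self, rng):
        """One-component PLS on orthogonal centered predictors points along
        the predictor-outcome covariance vector (brute-force oracle)."""
        n = 64
        # orthogonal +/-1 design columns
        X = np.array(
            [[1, 1, -1], [1, -1, 1], [-1, 1, 1], [-1, -1, -1]] * (n // 4),
            dtype=float,
        )
        y = rng.normal(size=n)
        b = nipals_pls(X, y, n_components=1)
        cov = np.array([np.cov(X[:, j], y, bias=True)[0, 1] for j in range(3)])
        assert b / np.linalg.norm(b) == pytest.approx(
            np.sign(cov @ b) * cov / np.linalg.norm(cov), abs=1e-10
        )

    def test_matches_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60) + X[:, 0]
        for k in (1, 2, 3):
            ours = nipals_pls(X, y, n_components=k)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert ours == pytest.approx(ref.coef_.ravel(), abs=1e-8)

    def test_duplicate_columns_share_coefficient(self, rng):
        x = rng.normal(size=(50, 1))
        X = np.hstack([x, x, rng.normal(size=(50, 1))])
        y = rng.normal(size=50) + x[:, 0]
        b = nipals_pls(X, y, 1)
        assert b[0] == pytest.approx(b[1], abs=1e-12)

    def test_zero_signal_gives_zero_coefs(self):
        X = np.ones((10, 3))  # centered X is identically zero
        y = np.arange(10.0)
        assert nipals_pls(X, y, 1) == pytest.approx(np.zeros(3))


@pytest.fixture(scope="module")
def codes_and_outcome():
    cohort = make_simple_cohort(60, n_adverse=9)
    codes = assign_categories(cohort)
    return cohort, codes, cohort.adverse()


class TestBootstrapPLS:
    def test_no_resample_equals_single_fit(self, codes_and_outcome):
        _, codes, y = codes_and_outcome
        fit = fit_pls_bootstrap(codes, y, B=1, resample=False)
        direct = nipals_pls(codes.to_numpy(float), y, 1)
        assert list(fit.median_coefs.values()) == pytest.approx(direct)

    def test_deterministic_given_seed(self, codes_and_outcome):
        _, codes, y = codes_and_outcome
        a = fit_pls_bootstrap(codes, y, B=50, seed=4)
        b = fit_pls_bootstrap(codes, y, B=50, seed=4)
        assert np.array_equal(a.distributions, b.distributions)

    def test_patient_cluster_resampling(self, codes_and_outcome):
        cohort, codes, y = codes_and_outcome
        fit = fit_pls_bootstrap(
            codes, y, B=20, resample_unit="patient", seed=1,
            patient_ids=cohort.patient_ids(),
        )
        assert fit.distributions.shape == (20, codes.shape[1])

    def test_constant_outcome_rejected(self, codes_and_outcome):
        _, codes, _ = codes_and_outcome
        with pytest.raises(ValueError, match="constant"):
            fit_pls_bootstrap(codes, np.zeros(len(codes)), B=5)

    def test_missing_codes_rejected(self, codes_and_outcome):
        _, codes, y = codes_and_outcome
        holed = codes.copy()
        holed.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_pls_bootstrap(holed, y, B=5)


def _fit_with(coefs: dict) -> PLSFit:
    return PLSFit(
        variables=tuple(coefs),
        median_coefs=dict(coefs),
        distributions=np.array([list(coefs.values())]),
        n_components=1,
        B=1,
    )


class TestRescale:
    def test_single_variable_anchors(self):
        system = rescale_to_points(_fit_with({"x": 0.37}))
        assert system.points["x"] == pytest.approx((0.0, 50.0, 100.0))

    def test_seven_equal_betas_share_the_span(self):
        coefs = {v: 0.2 for v in SCORE_VARIABLES}
        system = rescale_to_points(_fit_with(coefs))
        for v in SCORE_VARIABLES:
            lo, med, hi = system.points[v]
            assert hi - lo == pytest.approx(100 / 7)

    def test_anchor_sums_exact(self, codes_and_outcome, rng):
        _, codes, y = codes_and_outcome
        fit = fit_pls_bootstrap(codes, y, B=25, seed=8)
        system = rescale_to_points(fit, clip_negative=True)
        lo, med, hi = system.anchor_sums()
        assert (lo, med, hi) == pytest.approx((0.0, 50.0, 100.0), abs=1e-9)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError, match="signal"):
            rescale_to_points(
                _fit_with({"a": -0.2, "b": -0.1}), clip_negative=True
            )

    def test_negative_coefficient_needs_clip(self):
        fit = _fit_with({"a": -0.2, "b": 0.6})
        with pytest.raises(ValueError, match="negative"):
            rescale_to_points(fit)
        system = rescale_to_points(fit, clip_negative=True)
        assert system.points["a"] == pytest.approx((0.0, 0.0, 0.0))
        assert system.points["b"] == pytest.approx((0.0, 50.0, 100.0))

    def test_zero_sum_offsets_preserve_totals(self):
        coefs = {"a": 0.3, "b": 0.5}
        plain = rescale_to_points(_fit_with(coefs))
        shifted = rescale_to_points(
            _fit_with(coefs), offsets={"a": -5.0, "b": 5.0}
        )
        assert shifted.anchor_sums() == pytest.approx(plain.anchor_sums())
        assert shifted.points["a"][0] == -5.0
        with pytest.raises(ValueError, match="sum to zero"):
            rescale_to_points(_fit_with(coefs), offsets={"a": 1.0})


class TestPragmaticRounding:
    def test_reference_table_round_trips_with_zero_deviation(self):
        system, _, deviation = make_pragmatic(PRAGMATIC_SYSTEM)
        assert system.points == PRAGMATIC_SYSTEM.points
        assert all(d == 0 for d in deviation.values())

    def test_fractional_points_become_integers(self):
        coefs = {v: 0.1 + 0.03 * i for i, v in enumerate(SCORE_VARIABLES)}
        rounded, _, deviation = make_pragmatic(rescale_to_points(_fit_with(coefs)))
        for pts in rounded.points.values():
            assert all(float(p).is_integer() for p in pts)
        assert all(abs(d) <= 3.5 for d in deviation.values())


class TestScoringSystemInvariants:
    def test_non_monotone_rows_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            ScoringSystem(points={"x": (10.0, 5.0, 100.0)},
                          anchor_tolerance=100)

    def test_broken_anchors_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            ScoringSystem(points={"x": (0.0, 10.0, 100.0)})

    def test_save_load_round_trip(self, tmp_path):
        path = tmp_path / "system.json"
        save_system(PRAGMATIC_SYSTEM, path)
        system, cutpoints = load_system(path)
        assert system == PRAGMATIC_SYSTEM
        assert cutpoints.rule("age_years") == DEFAULT_CUTPOINTS.rule("age_years")


class TestScoreRecords:
    def test_extreme_records_hit_the_anchors(self):
        low = make_record("lo", echo=make_echo())
        high = make_record(
            "hi",
            echo=make_echo(
                age=2.0, rv_dysfunction="severe", rv_dilatation="severe",
                tr_severity="moderate/severe", tr_vmax=5.5,
                pr_severity="severe", pr_vmax=6.0,
            ),
        )
        table = score_records(Cohort(records=(low, high)), PRAGMATIC_SYSTEM)
        assert table.loc["lo", "total"] == 0
        assert table.loc["hi", "total"] == 100

    def test_hand_summed_mixed_record(self):
        """Category-by-category sum of the published table for a mid-risk
        child: -13 + 14 + 3 + 5 + 9 + 7 + 0 = 25."""
        rec = make_record(
            "mix",
            echo=make_echo(
                age=5.0, rv_dysfunction="moderate", rv_dilatation="mild",
                tr_severity="moderate", tr_vmax=4.2,
                pr_severity="mild", pr_vmax=2.5,
            ),
        )
        table = score_records(Cohort(records=(rec,)), PRAGMATIC_SYSTEM)
        assert table.loc["mix", "total"] == 25

    def test_single_upgrade_never_decreases_total(self, study_cohort):
        codes = assign_categories(study_cohort)
        point_arr = {v: PRAGMATIC_SYSTEM.points[v] for v in SCORE_VARIABLES}
        base = score_records(study_cohort, PRAGMATIC_SYSTEM)["total"]
        for v in SCORE_VARIABLES:
            c = codes[v].to_numpy(int)
            upgrade = np.where(c < 2, c + 1, c)
            delta = (
                np.array([point_arr[v][k] for k in upgrade])
                - np.array([point_arr[v][k] for k in c])
            )
            assert (delta >= 0).all()
        assert base.between(0, 100).all()

    def test_missing_policy_error_names_offender(self):
        rec = make_record("m1", echo=make_echo(tr_vmax=None))
        with pytest.raises(ValueError, match="m1.*tr_vmax"):
            score_records(Cohort(records=(rec,)), PRAGMATIC_SYSTEM)

    def test_missing_policy_assume_low_flags(self):
        rec = make_record("m1", echo=make_echo(tr_vmax=None))
        table = score_records(
            Cohort(records=(rec,)), PRAGMATIC_SYSTEM,
            missing_policy="assume_low",
        )
        assert table.loc["m1", "imputed_low"]
        assert table.loc["m1", "total"] == 0


class TestPermutation:
    def test_perfect_separation_minimal_p(self, rng):
        scores = np.concatenate([rng.uniform(0, 40, 140), rng.uniform(60, 100, 18)])
        labels = np.r_[np.zeros(140), np.ones(18)]
        auc, p = permutation_test(scores, labels, B=999, seed=0)
        assert auc == 1.0
        assert p == pytest.approx(1 / 1000)

    def test_identical_scores_p_one(self):
        scores = np.full(100, 7.0)
        labels = np.r_[np.ones(10), np.zeros(90)]
        auc, p = permutation_test(scores, labels, B=499, seed=1)
        assert auc == 0.5
        assert p == 1.0

    def test_deterministic(self, rng):
        scores = rng.normal(size=120)
        labels = rng.integers(0, 2, 120)
        assert permutation_test(scores, labels, B=299, seed=5) == \
            permutation_test(scores, labels, B=299, seed=5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0, 2.0], [1, 1], B=299)
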