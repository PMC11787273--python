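"""Data model: Likert encoding, derived hemodynamics, composite outcome,
file round-trips and the baseline summary."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echorisk.cohort import (
    COMPLICATION_EVENTS,
    ESCALATION_EVENTS,
    LIKERT_SCALE,
    SEVERITY_LABELS,
    Cohort,
    EchoExam,
    OutcomeFlags,
    SeverityGrade,
    classify_outcome,
    compute_pvr,
    likert_decode,
    likert_encode,
    read_cohort,
    relative_change,
    summarize_cohort,
    write_cohort,
)
from echorisk.simulate import SimConfig, simulate_cohort

from conftest import make_echo, make_record, make_simple_cohort


class TestLikert:
    @pytest.mark.parametrize(
        "label, value",
        [
            ("none", 0.0),
            ("severe", 3.0),
            ("mild/moderate", 1.5),
            ("Mild-Moderate", 1.5),
            ("  TRIVIAL ", 0.25),
            ("moderate/severe", 2.5),
        ],
    )
    def test_encode(self, label, value):
        assert likert_encode(label) == value

    def test_unknown_label_is_named(self):
        with pytest.raises(ValueError, match="bananas"):
            likert_encode("bananas")
        with pytest.raises(ValueError):
            likert_decode(0.7)

    def test_strictly_monotone_bijection(self):
        values = [likert_encode(lbl) for lbl in SEVERITY_LABELS]
        assert values == sorted(values)
        assert len(set(values)) == len(values)
        for lbl in SEVERITY_LABELS:
            assert likert_decode(likert_encode(lbl)) == lbl

    def test_grade_ordering_follows_values(self):
        grades = [SeverityGrade.from_label(lbl) for lbl in SEVERITY_LABELS]
        assert grades == sorted(grades)


class TestPVR:
    @pytest.mark.parametrize(
        "mpap, pcwp, co, expected",
        [(25, 10, 3.0, 5.0), (44, 9, 2.5, 14.0), (12, 12, 4.0, 0.0)],
    )
    def test_values(self, mpap, pcwp, co, expected):
        assert compute_pvr(mpap, pcwp, co) == pytest.approx(expected)

    def test_rejects_nonpositive_co(self):
        with pytest.raises(ValueError, match="cardiac output"):
            compute_pvr(25, 10, 0)

    def test_rejects_wedge_above_mpap(self):
        with pytest.raises(ValueError, match="inconsisten"):
            compute_pvr(10, 25, 3)

    @given(
        gradient=st.floats(0.1, 80),
        pcwp=st.floats(0, 25),
        co=st.floats(0.5, 10),
        k=st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_in_gradient(self, gradient, pcwp, co, k):
        base = compute_pvr(pcwp + gradient, pcwp, co)
        scaled = compute_pvr(pcwp + k * gradient, pcwp, co)
        assert scaled == pytest.approx(k * base, rel=1e-9)


class TestRelativeChange:
    @pytest.mark.parametrize(
        "intra, adm, expected", [(80, 100, -20), (55, 55, 0), (68, 100, -32)]
    )
    def test_values(self, intra, adm, expected):
        assert relative_change(intra, adm) == pytest.approx(expected)

    def test_rejects_nonpositive_admission(self):
        with pytest.raises(ValueError):
            relative_change(80, 0)


class TestClassifyOutcome:
    def test_complication_only(self):
        out = classify_outcome(["pulmonary_hypertensive_crisis"])
        assert (out.complication, out.escalation, out.adverse) == (True, False, True)

    def test_both_arms(self):
        out = classify_outcome(["icu_admission", "cardiac_arrest"])
        assert out.complication and out.escalation and out.adverse

    def test_empty(self):
        out = classify_outcome([])
        assert not out.adverse and not out.complication and not out.escalation

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="spontaneous_combustion"):
            classify_outcome(["spontaneous_combustion"])

    def test_adverse_is_or_over_all_small_subsets(self):
        vocab = sorted(COMPLICATION_EVENTS | ESCALATION_EVENTS)
        for size in range(4):
            for subset in itertools.combinations(vocab, size):
                out = classify_outcome(list(subset))
                assert out.adverse == (out.complication or out.escalation)
                assert out.complication == any(
                    s in COMPLICATION_EVENTS for s in subset
                )
                assert out.escalation == any(
                    s in ESCALATION_EVENTS for s in subset
                )


class TestIO:
    def test_roundtrip_simulated(self, tmp_path, study_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(study_cohort, path)
        again = read_cohort(path)
        assert again == study_cohort

    def test_fixture_file_row_count(self, tmp_path):
        cohort = make_simple_cohort(5)
        path = tmp_path / "five.csv"
        write_cohort(cohort, path)
        assert len(read_cohort(path)) == 5

    def test_unknown_severity_token_names_row_and_token(self, tmp_path):
        cohort = make_simple_cohort(3)
        path = tmp_path / "bad.csv"
        write_cohort(cohort, path)
        df = pd.read_csv(path)
        df.loc[1, "tr_severity"] = "extreme"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 1") as err:
            read_cohort(path)
        assert "extreme" in str(err.value)

    def test_missing_mandatory_column(self, tmp_path):
        cohort = make_simple_cohort(3)
        path = tmp_path / "trunc.csv"
        write_cohort(cohort, path)
        df = pd.read_csv(path).drop(columns=["tr_vmax"])
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="tr_vmax"):
            read_cohort(path)

    def test_severity_cells_accept_numeric_likert(self, tmp_path):
        cohort = make_simple_cohort(2)
        path = tmp_path / "numeric.csv"
        write_cohort(cohort, path)
        df = pd.read_csv(path)
        df["rv_dysfunction"] = 1.5
        df.to_csv(path, index=False)
        again = read_cohort(path)
        assert again.records[0].echo.rv_dysfunction.label == "mild_moderate"

    def test_duplicate_cath_id_rejected(self):
        rec = make_record("c1")
        with pytest.raises(ValueError, match="duplicate"):
            Cohort(records=(rec, rec))


class TestSummary:
    def test_degenerate_cohort_has_zero_sd(self):
        records = tuple(make_record(f"c{i}") for i in range(6))
        table = summarize_cohort(Cohort(records=records))
        quant = table[table.kind == "quantitative"]
        assert (quant["sd"].fillna(0) == 0).all()

    def test_grade_counts_sum_to_available(self, study_cohort):
        table = summarize_cohort(study_cohort)
        ordinal = table[table.kind == "ordinal"]
        count_cols = [c for c in table.columns if c.startswith("n_") and
                      c not in ("n_available", "n_events")]
        for _, row in ordinal.iterrows():
            assert row[count_cols].sum() == row["n_available"]

    def test_event_rate_rounds_to_ten_percent(self):
        cohort = make_simple_cohort(158, n_adverse=16)
        table = summarize_cohort(cohort)
        rate = table.loc[table.variable == "adverse", "event_rate_pct"].item()
        assert rate == 10


class TestValidation:
    def test_age_must_be_positive(self):
        with pytest.raises(ValueError, match="age"):
            make_echo(age=0)

    def test_velocity_range(self):
        with pytest.raises(ValueError, match="tr_vmax"):
            make_echo(tr_vmax=9.0)

    def test_outcome_flags_adverse_is_or(self):
        assert OutcomeFlags(True, False).adverse
        assert OutcomeFlags(False, True).adverse
        assert not OutcomeFlags(False, False).adverse
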