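import numpy as np
import pytest

from echorisk.cohort import (
    CathRecord,
    Cohort,
    EchoExam,
    OutcomeFlags,
    SeverityGrade,
)
from echorisk.simulate import SimConfig, simulate_cohort


def make_echo(
    age=10.0,
    rv_dysfunction="none",
    rv_dilatation="none",
    tr_severity="none",
    tr_vmax=2.5,
    pr_severity="none",
    pr_vmax=2.0,
    **extra,
):
    """Convenience EchoExam builder with low-risk defaults."""
    return EchoExam(
        age_years=age,
        rv_dysfunction=SeverityGrade.from_label(rv_dysfunction),
        rv_dilatation=SeverityGrade.from_label(rv_dilatation),
        tr_severity=SeverityGrade.from_label(tr_severity),
        tr_vmax=tr_vmax,
        pr_severity=SeverityGrade.from_label(pr_severity),
        pr_vmax=pr_vmax,
        **extra,
    )


def make_record(cath_id, patient_id=None, adverse=False, echo=None, **echo_kwargs):
    return CathRecord(
        patient_id=patient_id or f"pt_{cath_id}",
        cath_id=str(cath_id),
        echo=echo if echo is not None else make_echo(**echo_kwargs),
        outcome=OutcomeFlags(complication=adverse, escalation=False),
    )


def make_simple_cohort(n=20, n_adverse=2, n_patients=None):
    """Deterministic hand-built cohort: n records, the first n_adverse with
    an adverse event; echo values vary mildly with the index."""
    n_patients = n_patients or n
    records = []
    for i in range(n):
        records.append(
            CathRecord(
                patient_id=f"p{i % n_patients:03d}",
                cath_id=f"c{i:03d}",
                echo=make_echo(
                    age=4.0 + (i % 12),
                    tr_vmax=2.0 + 0.2 * (i % 10),
                    pr_vmax=1.5 + 0.1 * (i % 10),
                ),
                outcome=OutcomeFlags(
                    complication=i < n_adverse, escalation=False
                ),
            )
        )
    return Cohort(records=tuple(records))


@pytest.fixture(scope="session")
def study_cohort():
    """One synthetic cohort under the study conditions (default config)."""
    return simulate_cohort(SimConfig(), seed=11)


@pytest.fixture(scope="session")
def large_cohort():
    """~10,000 catheterizations for large-sample checks."""
    from dataclasses import replace

    return simulate_cohort(replace(SimConfig(), n_patients=5900), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
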