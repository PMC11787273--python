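"""Cohort data model: echo severity grades, catheterization records, derived
hemodynamics, composite outcome classification, and delimited-text I/O.

One row / record per cardiac catheterization; patients may contribute several
catheterizations (repeated measures), so ``patient_id`` can repeat while
``cath_id`` is unique within a cohort.

Qualitative echocardiographic severities (none ... severe, with half-grades)
are encoded on a fixed ordinal Likert scale; see :data:`LIKERT_SCALE`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIKERT_SCALE",
    "SEVERITY_LABELS",
    "COMPLICATION_EVENTS",
    "ESCALATION_EVENTS",
    "SeverityGrade",
    "EchoExam",
    "HemoRecord",
    "OutcomeFlags",
    "CathRecord",
    "Cohort",
    "likert_encode",
    "likert_decode",
    "normalize_severity_label",
    "compute_pvr",
    "relative_change",
    "classify_outcome",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]

# Ordinal Likert encoding of qualitative echo severities. Half-grades sit at
# the midpoint of their neighbours; "trivial" sits close to "none" so that
# pooling none/trivial (as baseline tables commonly do) loses almost nothing.
LIKERT_SCALE: dict[str, float] = {
    "none": 0.0,
    "trivial": 0.25,
    "mild": 1.0,
    "mild_moderate": 1.5,
    "moderate": 2.0,
    "moderate_severe": 2.5,
    "severe": 3.0,
}

SEVERITY_LABELS: tuple[str, ...] = tuple(LIKERT_SCALE)

_VALUE_TO_LABEL = {v: k for k, v in LIKERT_SCALE.items()}


def normalize_severity_label(label: str) -> str:
    """Normalize case, whitespace and separators of a severity label.

    Accepts e.g. ``"Mild/Moderate"``, ``"mild-moderate"``, ``"mild moderate"``
    and returns the canonical token ``"mild_moderate"``.
    """
    token = re.sub(r"[\s/\-]+", "_", str(label).strip().lower())
    return token


def likert_encode(label: str) -> float:
    """Map a severity label to its ordinal Likert value.

    Raises
    ------
    ValueError
        If the (normalized) label is not in the controlled vocabulary; the
        offending token is named in the message.
    """
    token = normalize_severity_label(label)
    try:
        return LIKERT_SCALE[token]
    except KeyError:
        raise ValueError(
            f"unknown severity label {label!r} (normalized: {token!r}); "
            f"expected one of {sorted(LIKERT_SCALE)}"
        ) from None


def likert_decode(value: float) -> str:
    """Inverse of :func:`likert_encode`."""
    try:
        return _VALUE_TO_LABEL[float(value)]
    except KeyError:
        raise ValueError(
            f"value {value!r} is not on the Likert scale "
            f"{sorted(_VALUE_TO_LABEL)}"
        ) from None


@dataclass(frozen=True, order=True)
class SeverityGrade:
    """An ordinal echo severity grade (label plus fixed numeric value)."""

    value: float
    label: str = field(compare=False)

    @classmethod
    def from_label(cls, label: str) -> "SeverityGrade":
        token = normalize_severity_label(label)
        return cls(value=likert_encode(token), label=token)

    @classmethod
    def from_value(cls, value: float) -> "SeverityGrade":
        return cls(value=float(value), label=likert_decode(value))

    @classmethod
    def coerce(cls, raw) -> "SeverityGrade":
        """Build a grade from a label, a numeric Likert value, or a grade."""
        if isinstance(raw, SeverityGrade):
            return raw
        if isinstance(raw, (int, float, np.floating, np.integer)):
            return cls.from_value(float(raw))
        # numeric strings are accepted, e.g. "1.5" in a data file
        try:
            return cls.from_value(float(raw))
        except (TypeError, ValueError):
            return cls.from_label(raw)


def compute_pvr(mpap: float, pcwp: float, co: float) -> float:
    """Pulmonary vascular resistance in Wood units: (mPAP - PCWP) / CO.

    ``mpap`` and ``pcwp`` in mmHg, ``co`` (cardiac output) in L/min.
    """
    if co <= 0:
        raise ValueError(f"cardiac output must be positive, got {co}")
    if pcwp < 0:
        raise ValueError(f"wedge pressure must be non-negative, got {pcwp}")
    if mpap < pcwp:
        raise ValueError(
            f"physiologic inconsistency: mPAP ({mpap} mmHg) below "
            f"PCWP ({pcwp} mmHg)"
        )
    return (mpap - pcwp) / co


def relative_change(intraop_value: float, admission_value: float) -> float:
    """Intra-operative value as a percent change from the admission value."""
    if admission_value <= 0:
        raise ValueError(
            f"admission value must be positive, got {admission_value}"
        )
    return 100.0 * (intraop_value - admission_value) / admission_value


# Controlled vocabulary for the composite outcome. Complications and
# unforeseen escalations of care are disjoint lists; a single procedure may
# record events from both. "adverse" is their union.
COMPLICATION_EVENTS: frozenset[str] = frozenset(
    {
        "arrhythmia",
        "cardiac_arrest",
        "pulmonary_hypertensive_crisis",
        "hypotension_premature_termination",
        "death",
        "bronchospasm",
        "laryngospasm",
        "difficult_intubation",
    }
)

ESCALATION_EVENTS: frozenset[str] = frozenset(
    {
        "iv_vasoactive_therapy",
        "inhaled_vasoactive_therapy",
        "failed_extubation",
        "reintubation",
        "postop_invasive_ventilation",
        "postop_noninvasive_ventilation",
        "emergency_icu_admission",
    }
)

# Synonyms normalized at read time.
_EVENT_SYNONYMS: dict[str, str] = {
    "icu_admission": "emergency_icu_admission",
    "unplanned_icu_admission": "emergency_icu_admission",
    "cpr": "cardiac_arrest",
    "cardiopulmonary_resuscitation": "cardiac_arrest",
    "arrest": "cardiac_arrest",
    "ph_crisis": "pulmonary_hypertensive_crisis",
    "arrhythmias": "arrhythmia",
    "niv": "postop_noninvasive_ventilation",
    "invasive_ventilation": "postop_invasive_ventilation",
    "noninvasive_ventilation": "postop_noninvasive_ventilation",
    "iv_vasoactive": "iv_vasoactive_therapy",
    "inhaled_vasoactive": "inhaled_vasoactive_therapy",
}


def _normalize_event(label: str) -> str:
    token = re.sub(r"[\s/\-]+", "_", str(label).strip().lower())
    return _EVENT_SYNONYMS.get(token, token)


@dataclass(frozen=True)
class OutcomeFlags:
    """Composite peri-operative outcome for one catheterization."""

    complication: bool
    escalation: bool
    event_labels: tuple[str, ...] = ()

    @property
    def adverse(self) -> bool:
        return self.complication or self.escalation


def classify_outcome(event_labels: Iterable[str]) -> OutcomeFlags:
    """Classify a list of event labels into the composite outcome.

    ``complication`` is true iff at least one complication event occurred,
    ``escalation`` iff at least one unforeseen escalation of care occurred;
    the composite adverse-event flag is their OR. Unknown labels are rejected.
    """
    normalized = tuple(_normalize_event(lbl) for lbl in event_labels)
    unknown = [
        lbl
        for lbl in normalized
        if lbl not in COMPLICATION_EVENTS and lbl not in ESCALATION_EVENTS
    ]
    if unknown:
        raise ValueError(
            f"unknown event label(s) {unknown}; expected labels from "
            f"{sorted(COMPLICATION_EVENTS | ESCALATION_EVENTS)}"
        )
    return OutcomeFlags(
        complication=any(lbl in COMPLICATION_EVENTS for lbl in normalized),
        escalation=any(lbl in ESCALATION_EVENTS for lbl in normalized),
        event_labels=normalized,
    )


@dataclass(frozen=True)
class EchoExam:
    """Pre-operative trans-thoracic echocardiogram.

    Holds the seven scoring predictors (age, RV dysfunction/dilatation, TR
    severity and velocity, PR severity and velocity) plus the pulmonary
    end-diastolic regurgitant velocity and optional auxiliary measures that
    are carried through but unused by the score. Velocities in m/s, age in
    decimal years.
    """

    age_years: float
    rv_dysfunction: SeverityGrade
    rv_dilatation: SeverityGrade
    tr_severity: SeverityGrade
    tr_vmax: float | None
    pr_severity: SeverityGrade
    pr_vmax: float | None
    pr_edv: float | None = None
    tapse_z: float | None = None
    fac_percent: float | None = None
    lv_ef_percent: float | None = None

    def __post_init__(self):
        if not self.age_years > 0:
            raise ValueError(f"age must be positive, got {self.age_years}")
        for name in ("tr_vmax", "pr_vmax", "pr_edv"):
            v = getattr(self, name)
            if v is not None and not (0 < v < 8):
                raise ValueError(
                    f"{name}={v} m/s outside the plausible Doppler "
                    f"range (0, 8)"
                )


@dataclass(frozen=True)
class HemoRecord:
    """Invasive hemodynamics at catheterization (pressures in mmHg, CO in
    L/min). PVR in Wood units is derived, never stored."""

    mpap: float | None = None
    pcwp: float | None = None
    cardiac_output: float | None = None
    bsa: float | None = None

    @property
    def pvr(self) -> float | None:
        if None in (self.mpap, self.pcwp, self.cardiac_output):
            return None
        return compute_pvr(self.mpap, self.pcwp, self.cardiac_output)


@dataclass(frozen=True)
class CathRecord:
    """One elective cardiac catheterization under general anesthesia."""

    patient_id: str
    cath_id: str
    echo: EchoExam
    outcome: OutcomeFlags
    hemo: HemoRecord | None = None
    septostomy: bool = False


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of catheterization records."""

    records: tuple[CathRecord, ...]

    def __post_init__(self):
        if not self.records:
            raise ValueError("a cohort must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.cath_id in seen:
                raise ValueError(f"duplicate cath_id {rec.cath_id!r}")
            seen.add(rec.cath_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CathRecord]:
        return iter(self.records)

    @property
    def n_patients(self) -> int:
        return len({r.patient_id for r in self.records})

    def patient_ids(self) -> np.ndarray:
        return np.array([r.patient_id for r in self.records])

    def adverse(self) -> np.ndarray:
        return np.array([r.outcome.adverse for r in self.records], dtype=int)

    def predictor(self, name: str) -> np.ndarray:
        """Extract one predictor column as floats (NaN where missing).

        Severity grades are returned as their Likert values.
        """
        out = np.empty(len(self.records))
        for i, rec in enumerate(self.records):
            v = _get_predictor(rec, name)
            out[i] = np.nan if v is None else v
        return out


_SEVERITY_FIELDS = ("rv_dysfunction", "rv_dilatation", "tr_severity", "pr_severity")
_ECHO_NUMERIC_FIELDS = (
    "age_years",
    "tr_vmax",
    "pr_vmax",
    "pr_edv",
    "tapse_z",
    "fac_percent",
    "lv_ef_percent",
)
_HEMO_FIELDS = ("mpap", "pcwp", "cardiac_output", "bsa")


def _get_predictor(rec: CathRecord, name: str) -> float | None:
    if name in _SEVERITY_FIELDS:
        return getattr(rec.echo, name).value
    if name in _ECHO_NUMERIC_FIELDS:
        return getattr(rec.echo, name)
    if name in _HEMO_FIELDS:
        return None if rec.hemo is None else getattr(rec.hemo, name)
    if name == "pvr":
        return None if rec.hemo is None else rec.hemo.pvr
    if name == "septostomy":
        return float(rec.septostomy)
    raise KeyError(f"unknown predictor {name!r}")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = (
    "patient_id",
    "cath_id",
    "age_years",
    "rv_dysfunction",
    "rv_dilatation",
    "tr_severity",
    "tr_vmax",
    "pr_severity",
    "pr_vmax",
    "complication",
    "escalation",
)

OPTIONAL_COLUMNS = (
    "pr_edv",
    "tapse_z",
    "fac_percent",
    "lv_ef_percent",
    "mpap",
    "pcwp",
    "cardiac_output",
    "bsa",
    "septostomy",
    "event_labels",
)


def _opt_float(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    if isinstance(cell, str) and cell.strip() == "":
        return None
    return float(cell)


def _parse_bool(cell) -> bool:
    if isinstance(cell, (bool, np.bool_)):
        return bool(cell)
    token = str(cell).strip().lower()
    if token in {"1", "true", "yes", "y"}:
        return True
    if token in {"0", "false", "no", "n", ""}:
        return False
    raise ValueError(f"unparseable boolean {cell!r}")


def record_to_row(rec: CathRecord) -> dict:
    row: dict = {
        "patient_id": rec.patient_id,
        "cath_id": rec.cath_id,
        "age_years": rec.echo.age_years,
    }
    for name in _SEVERITY_FIELDS:
        row[name] = getattr(rec.echo, name).label
    for name in ("tr_vmax", "pr_vmax", "pr_edv", "tapse_z", "fac_percent", "lv_ef_percent"):
        row[name] = getattr(rec.echo, name)
    hemo = rec.hemo or HemoRecord()
    for name in _HEMO_FIELDS:
        row[name] = getattr(hemo, name)
    row["septostomy"] = rec.septostomy
    row["complication"] = rec.outcome.complication
    row["escalation"] = rec.outcome.escalation
    row["event_labels"] = ";".join(rec.outcome.event_labels)
    return row


def row_to_record(row: Mapping, *, context: str = "") -> CathRecord:
    def fail(col: str, err: Exception):
        raise ValueError(f"{context}column {col!r}: {err}") from None

    grades = {}
    for name in _SEVERITY_FIELDS:
        try:
            grades[name] = SeverityGrade.coerce(row[name])
        except ValueError as err:
            fail(name, err)
    numerics = {}
    for name in ("age_years", "tr_vmax", "pr_vmax", "pr_edv", "tapse_z",
                 "fac_percent", "lv_ef_percent"):
        try:
            numerics[name] = _opt_float(row.get(name))
        except ValueError as err:
            fail(name, err)
    if numerics["age_years"] is None:
        fail("age_years", ValueError("mandatory value missing"))
    echo = EchoExam(
        age_years=numerics["age_years"],
        tr_vmax=numerics["tr_vmax"],
        pr_vmax=numerics["pr_vmax"],
        pr_edv=numerics["pr_edv"],
        tapse_z=numerics["tapse_z"],
        fac_percent=numerics["fac_percent"],
        lv_ef_percent=numerics["lv_ef_percent"],
        **grades,
    )
    hemo_vals = {}
    for name in _HEMO_FIELDS:
        try:
            hemo_vals[name] = _opt_float(row.get(name))
        except ValueError as err:
            fail(name, err)
    hemo = HemoRecord(**hemo_vals)
    if all(v is None for v in hemo_vals.values()):
        hemo = None

    labels_cell = row.get("event_labels", "")
    if labels_cell is None or (isinstance(labels_cell, float) and math.isnan(labels_cell)):
        labels_cell = ""
    labels = tuple(t for t in str(labels_cell).split(";") if t.strip())
    try:
        complication = _parse_bool(row.get("complication", False))
        escalation = _parse_bool(row.get("escalation", False))
    except ValueError as err:
        fail("complication/escalation", err)
    if labels:
        try:
            outcome = classify_outcome(labels)
        except ValueError as err:
            fail("event_labels", err)
        # explicit flags win if present, but must be consistent supersets
        outcome = OutcomeFlags(
            complication=complication or outcome.complication,
            escalation=escalation or outcome.escalation,
            event_labels=outcome.event_labels,
        )
    else:
        outcome = OutcomeFlags(complication=complication, escalation=escalation)

    try:
        septostomy = _parse_bool(row.get("septostomy", False))
    except ValueError as err:
        fail("septostomy", err)

    return CathRecord(
        patient_id=str(row["patient_id"]),
        cath_id=str(row["cath_id"]),
        echo=echo,
        hemo=hemo,
        septostomy=septostomy,
        outcome=outcome,
    )


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame([record_to_row(r) for r in cohort])


def frame_to_cohort(df: pd.DataFrame, *, source: str = "<frame>") -> Cohort:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing mandatory column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        context = f"{source}, row {idx}: "
        records.append(row_to_record(row, context=context))
    return Cohort(records=tuple(records))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as UTF-8 comma-delimited text with a header row."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort file written by :func:`write_cohort` (or hand-made in
    the same layout). Severity cells may hold labels or numeric Likert
    values. Errors name the offending row and column."""
    df = pd.read_csv(path, dtype={"patient_id": str, "cath_id": str})
    return frame_to_cohort(df, source=str(path))


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Baseline summary table: mean +/- sd for quantitative variables, per-
    grade counts (and percentages) for ordinal ones, with availability."""
    n = len(cohort)
    rows = []
    for name in ("age_years", "tr_vmax", "pr_vmax", "pr_edv", "tapse_z",
                 "fac_percent", "lv_ef_percent", "mpap", "pcwp",
                 "cardiac_output", "pvr"):
        x = cohort.predictor(name)
        avail = np.isfinite(x)
        n_avail = int(avail.sum())
        rows.append(
            {
                "variable": name,
                "kind": "quantitative",
                "mean": float(np.mean(x[avail])) if n_avail else np.nan,
                "sd": float(np.std(x[avail], ddof=1)) if n_avail > 1 else 0.0,
                "n_available": n_avail,
                "pct_available": round(100.0 * n_avail / n),
            }
        )
    for name in _SEVERITY_FIELDS:
        x = cohort.predictor(name)
        avail = np.isfinite(x)
        n_avail = int(avail.sum())
        counts = {
            f"n_{label}": int(np.sum(x[avail] == value))
            for label, value in LIKERT_SCALE.items()
        }
        rows.append(
            {
                "variable": name,
                "kind": "ordinal",
                "n_available": n_avail,
                "pct_available": round(100.0 * n_avail / n),
                **counts,
            }
        )
    adverse = cohort.adverse()
    comp = np.array([r.outcome.complication for r in cohort], dtype=int)
    esc = np.array([r.outcome.escalation for r in cohort], dtype=int)
    for name, x in (("adverse", adverse), ("complication", comp), ("escalation", esc)):
        rows.append(
            {
                "variable": name,
                "kind": "outcome",
                "n_events": int(x.sum()),
                "n_available": n,
                "pct_available": 100,
                "event_rate_pct": round(100.0 * x.mean()),
            }
        )
    return pd.DataFrame(rows)
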