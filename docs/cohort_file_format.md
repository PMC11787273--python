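# Cohort file format

Comma-delimited UTF-8 text with a header row; one row per cardiac
catheterization. `read_cohort` / `write_cohort` round-trip this format
losslessly. Missing cells are allowed for every optional column.

## Mandatory columns

| column | type | units / values |
|---|---|---|
| `patient_id` | string | may repeat (repeated measures per patient) |
| `cath_id` | string | unique within the file |
| `age_years` | float | decimal years, > 0 |
| `rv_dysfunction` | severity | label or Likert value (see below) |
| `rv_dilatation` | severity | label or Likert value |
| `tr_severity` | severity | tricuspid regurgitation severity |
| `tr_vmax` | float | m/s, in (0, 8); may be empty |
| `pr_severity` | severity | pulmonary regurgitation severity |
| `pr_vmax` | float | m/s, in (0, 8); may be empty |
| `complication` | bool | `true/false`, `1/0`, `yes/no` |
| `escalation` | bool | as above |

## Optional columns

| column | type | units |
|---|---|---|
| `pr_edv` | float | pulmonary regurgitation end-diastolic velocity, m/s |
| `tapse_z` | float | TAPSE Z-score |
| `fac_percent` | float | fractional area change, % |
| `lv_ef_percent` | float | LV ejection fraction, % |
| `mpap` | float | mean pulmonary artery pressure, mmHg |
| `pcwp` | float | pulmonary capillary wedge pressure, mmHg |
| `cardiac_output` | float | L/min |
| `bsa` | float | body surface area, m² |
| `septostomy` | bool | balloon atrial septostomy performed |
| `event_labels` | string | `;`-separated controlled-vocabulary events |

PVR (Wood units) is always derived as `(mpap - pcwp) / cardiac_output`,
never stored.

## Severity cells

Accepted labels (case, spaces, `/` and `-` are normalized):
`none`, `trivial`, `mild`, `mild/moderate`, `moderate`, `moderate/severe`,
`severe` — or the corresponding numeric Likert values 0, 0.25, 1, 1.5, 2,
2.5, 3. Unknown tokens are rejected with the row and token named.

## Event labels

Complications: `arrhythmia`, `cardiac_arrest`,
`pulmonary_hypertensive_crisis`, `hypotension_premature_termination`,
`death`, `bronchospasm`, `laryngospasm`, `difficult_intubation`.

Escalations: `iv_vasoactive_therapy`, `inhaled_vasoactive_therapy`,
`failed_extubation`, `reintubation`, `postop_invasive_ventilation`,
`postop_noninvasive_ventilation`, `emergency_icu_admission`.

Common synonyms (`icu_admission`, `cpr`, `niv`, ...) are normalized at read
time. If both `event_labels` and the boolean flags are present, the flags
are OR-ed with the classification derived from the labels.
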