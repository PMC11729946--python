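# Input table schemas

All inputs are UTF-8 CSV, one row per record, ISO-8601 dates, header row
required. Booleans accept `true/false`, `t/f`, `1/0`, `yes/no` (case
insensitive). Empty string means missing.

## persons.csv

| column | type | values |
|---|---|---|
| person_id | string | unique within the dataset |
| birth_year | int | calendar year |
| gender | enum | `male`, `female` |
| ethnicity | enum | `Chinese`, `Malay`, `Indian`, `Others`; empty = missing |
| housing | enum | `rental_public`, `nonrental_public`, `private` |
| chas_tier | enum | `none`, `orange`, `blue` (blue = higher-subsidy tier) |
| pioneer_generation | bool | seniors' benefit-scheme passthrough |
| lives_alone | bool | social risk factor |
| region | enum | `Central`, `Western`, `Eastern` |
| death_date | date | empty if alive |

## conditions.csv

| column | type | values |
|---|---|---|
| person_id | string | |
| condition_code | string | code in the active registry (see `healthscopes.registry`) |
| first_diagnosis_date | date | diagnoses persist from this date onward |
| category | enum | `simple_chronic`, `complex_chronic`, `mental_health`, `cancer`, `obesity`; recomputed from the registry when the code is known |

## programs.csv

| column | type | values |
|---|---|---|
| person_id | string | |
| program | enum | `nursing_home_admission`, `palliative_referral`, `transitional_care_enrollment`, `pediatric_longterm_program` |
| event_date | date | program flags count only events inside the index year |

## encounters.csv

| column | type | values |
|---|---|---|
| person_id | string | |
| setting | enum | `inpatient_acute`, `day_surgery`, `emergency`, `specialist_outpatient`, `polyclinic`, `chas_gp` |
| encounter_date | date | |
| charges | float ≥ 0 | gross unsubsidized bill amount |
| bed_days | int ≥ 0 | 0 for non-inpatient settings |
| icu_flag | bool | |
| specialty | string | optional, may be empty |

## followup.csv (generated)

One row per index-year survivor: `person_id`, next-year counts
`polyclinic`, `specialist_outpatient`, `emergency`, `inpatient_acute`,
`bed_days`, plus `icu` (bool), `died` (bool) and `death_day` (1–365, empty
if alive).
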