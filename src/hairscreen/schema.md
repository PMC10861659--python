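# CSV schemas

## Concentration table (`concentrations.csv`, `truth.csv`)

| column    | type   | meaning                                               |
|-----------|--------|-------------------------------------------------------|
| substance | text   | analyte name                                          |
| matrix    | text   | one of `plasma`, `urine`, `faeces`, `hair`            |
| animal_id | text   | animal identifier (unique within group)               |
| group     | text   | `vehicle`, `half` (1 mg/kg), `one` (2), `two` (4)     |
| day       | int    | study day (0 = baseline; dosing days 1-7)             |
| time_h    | float  | hours post-dose within the day (0 for single samples) |
| value     | float  | ng/mL (plasma, urine) or pg/mg = ng/g (hair, faeces); 0 when censored |
| censored  | bool   | True when below the LOD / not detected                |

One row per sample; (substance, matrix, animal_id, day, time_h) is unique.

## Response table (`responses.csv`)

Same identity columns, plus:

| column         | type  | meaning                                          |
|----------------|-------|--------------------------------------------------|
| role           | text  | `blank`, `calibrator`, `qc`, or `sample`         |
| nominal_conc   | float | spiked concentration for blanks/calibrators/QCs; empty for samples |
| response_ratio | float | analyte-to-internal-standard response ratio      |

## Calibration curves (`calibration_curves.csv`)

analyte, matrix, slope, intercept, r_squared, lod, range_low, range_high,
n_levels, r2_flagged — one row per analyte x matrix.

## PK summaries (`pk_summaries.csv`)

substance, animal_id, group, auc_0_12 (ng·h/mL), cmax (ng/mL), tmax (h).

## Incorporation (`incorporation.csv`)

substance, n, `mean_degree [(pg/mg) / (ng.h/mL)]`, sem, per-dose means.

## Detection grid (`detection_grid.csv`)

substance, matrix, detected, last_detected_day.

## Descriptor table (`descriptors.csv`)

First column: substance name (index). Remaining columns: one numeric
descriptor each; external tables may carry arbitrary feature columns.

## Screening report (`screening.csv`)

substance, in_AD, score (vote fraction, empty when out of AD), prediction
(`detectable` / `undetectable` / `out_of_domain`), high_confidence
(score strictly above 0.9).
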