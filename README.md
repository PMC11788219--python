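# endovalid

Validation of administrative-health-data (ICD-coded) endometriosis
diagnoses against a surgical reference standard.

The package compares a surgically confirmed diagnosis (the reference
method, recorded on a standardized operative form with per-lesion
site/depth detail) against diagnoses derived from ICD-9/ICD-10 claims (the
test method), for the overall diagnosis and for three non-exclusive
subtypes — superficial (SE), ovarian endometrioma (OE), and deep
infiltrating (DE). It computes percent agreement, AUCR (balanced
accuracy), sensitivity, specificity, NPV, PPV, and Cohen's kappa, each
with percentile-bootstrap confidence intervals, plus a false-negative code
profile, a false-positive subtype tally, and race/ethnicity subgroup
analyses. Because the underlying clinical data are restricted, a
synthetic cohort generator with a configurable coding-error model stands
in for them.

## Layout

| module | purpose |
| --- | --- |
| `endovalid.cohort_io` | domain types, CSV readers/writers, YAML run config |
| `endovalid.synthetic_cohort` | cohort generator + hand-written 10-participant fixture |
| `endovalid.surgical_typology` | reference-method subtype classification |
| `endovalid.claims_processing` | ICD code filter, subtype code map, temporal window |
| `endovalid.diagnostic_accuracy` | 2×2 tables, the seven measures, percentile bootstrap |
| `endovalid.analysis_reports` | error/subgroup analyses, pipeline orchestration |
| `endovalid.cli` | `validate` / `synth` console commands |

## CLI

Generate a synthetic cohort (412 participants, 42% prevalence by default):

```sh
synth --out-dir data --seed 1            # or: validate synth ...
```

Run the full validation pipeline:

```sh
validate run --surgical data/surgical.csv --claims data/claims.csv \
    --config cfg.yaml --out reports
```

`cfg.yaml` is optional; every key has a default (`window_days: 30`,
`bootstrap_reps: 1000`, `ci_level: 0.95`, study period 2007–2009, the
built-in subtype code map). The output directory receives
`accuracy_table.csv`/`.txt`, `subgroup_table.csv`, `error_fn.csv`,
`error_fp.csv`, and `run_log.txt`.

## Input formats

`surgical.csv`: `participant_id, surgery_date, endometriosis_confirmed,
rasrm_stage, lesions, culdesac_obliteration, lesion_info_available,
race_group, hispanic`, with lesions encoded as pipe-delimited
`site:depth` tokens (e.g. `ovary:superficial|peritoneum:deep`).

`claims.csv`: `participant_id, code_system, code, service_date, source`.
Dates are ISO 8601 calendar dates.

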