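# edies

Severity scoring and severity-adjusted mortality benchmarking for emergency
department (ED) cohorts.

The package implements:

- an eight-item integer severity score (sex, cause of visit, AVPU
  consciousness level, age, systolic blood pressure, heart rate, respiratory
  rate, SpO2) with the published item table built in (totals 0–39);
- the exclusion cascade used to prepare ED visit records for scoring
  (age < 15, transfers out, arrival in cardiac arrest, missing variables,
  implausible values), with an auditable report;
- a score-table **builder**: maximum-likelihood logistic regression of
  mortality on user-assigned arbitrary bin scores, then integerization via
  `round(2 × coefficient × arbitrary score)`, plus Mann–Whitney AUROC;
- the **W** statistic (excess survivors per 100 patients) and the
  standardized **Ws** statistic with 95% confidence intervals, computed
  against a reference table of per-score survival probabilities and stratum
  fractions (the published 2016-style reference is built in);
- **coverage experiments**: repeated (optionally gamma-severity-reweighted,
  stratified) resampling from a population to measure how often the 95% CI
  of the sample Ws covers the population Ws;
- a **synthetic cohort generator** producing populations with an exact,
  controlled score distribution, Bernoulli survival at a given per-score
  probability, and (optionally) full vital-sign records that score back to
  their assigned value — so the whole pipeline is testable without registry
  data.

## CLI

All commands are under a single `edies` entry point; randomness always flows
from an explicit `--seed`.

```sh
# 1) synthesize a calibrated population of (score, outcome) pairs
edies synth --n 1000000 --seed 7 --out pop.csv

# or full vital-sign records, with rule-violating noise records injected
edies synth --n 10000 --seed 7 --emit-vitals --exclusion-noise 0.01 --out cohort.csv

# 2) score a raw cohort CSV (applies the exclusion cascade first)
edies score --cohort cohort.csv --out scored.csv --report exclusions.json

# 3) standardized W against the built-in reference
edies ws --cohort scored.csv --reference builtin --out ws.json

# 4) derive a new reference table from a scored cohort
edies reference --scored scored.csv --out reference.json

# 5) rebuild a score table from arbitrary bin scores + outcomes
edies build --design design.csv --bins bins.yaml --out table.json

# 6) CI coverage under a severity-reweighted sampling scenario
cat > scenario.yaml <<EOF
mode: gamma
shape: 9.0
rate: 1.0
sample_size: 30000
replicates: 1000
EOF
edies simulate-coverage --population pop.csv --reference builtin \
    --scenario scenario.yaml --seed 42 --out coverage.json
```

Cohort CSVs use the documented column set
(`id,age,sex,cause,avpu,sbp,dbp,hr,rr,bt,spo2,arrival_arrest,transferred_out,ed_result,hospital_result`);
a YAML schema file can remap column names (`edies score --schema map.yaml`).

## Library layout

| module            | contents |
|-------------------|----------|
| `edies.cohort_io` | `PatientRecord`, CSV read/write, `derive_outcome`, `apply_exclusions` |
| `edies.scoring`   | `ScoreTable`, `ReferenceTable`, built-in fixtures, `derive_reference` |
| `edies.builder`   | `fit_logistic`, `integerize`, `auroc`, `BinSpec` |
| `edies.wstats`    | `w_statistic`, `ws_statistic`, `self_consistent_ws`, `WsResult` |
| `edies.sampler`   | `gamma_target_distribution`, `stratified_resample`, `coverage_experiment` |
| `edies.synth`     | `GeneratorSpec`, `generate_population`, `vitals_for_score`, `inject_exclusions` |
| `edies.cli`       | the `edies` command group |

Notes on fidelity choices:

- The published respiratory-rate bins leave (33, 35] unmapped; the default
  table reads the last bin as `>33 → 2`, and
  `builtin_score_table(strict_rr=True)` reproduces the printed gap (scoring
  a value inside it raises).
- The built-in reference keeps the printed survival probability for score
  14 even though it breaks monotonicity; loading it emits a warning and the
  anomaly is exposed as `ReferenceTable.non_monotone_scores`.
- Ws confidence intervals use the null-model Bernoulli variance
  `Σ Ps(1−Ps)`; `variance="observed"` switches to observed stratum
  proportions for sensitivity analysis.

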