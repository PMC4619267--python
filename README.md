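# msabs — multi-state analysis of sickness absence and work

`msabs` implements a five-state event-history pipeline for registry data on
sickness benefits, from raw benefit spells to causal intervention effects:

1. **event histories** (`msabs.event_history`) — clean raw benefit-spell
   records (one-day spells discarded, overlapping registrations resolved
   newest-first, no-benefit gaps before disability attributed to the last
   benefit) into gap-free trajectories over the states *work (1)*,
   *partial sick leave (2)*, *sick leave (3)*, *work assessment allowance
   (4)* and the absorbing *disability pension (5)*, plus the long-format
   transition rows all estimators consume;
2. **transition intensities** (`msabs.intensities`) — per-transition
   cause-specific estimators: Nelson–Aalen (optionally weighted), Cox
   proportional hazards (Breslow ties, delayed entry, case weights,
   cluster-robust variance) and constant additive hazards (identity-link
   Poisson), evaluated at arbitrary covariate values as cumulative
   intensity matrices;
3. **probabilities** (`msabs.probabilities`) — product-integral transition
   probability matrices `P(s,t) = prod (I + dA(u))` (the Aalen–Johansen
   estimator under Nelson–Aalen increments) and state-occupation curves via
   an empirical or logistic initial-state model;
4. **interventions** (`msabs.interventions`) — three causal approaches:
   blocking/rerouting transition intensities (modularity), inverse
   probability of exposure / initial-state weighting, and G-computation
   (standardization) with the average-covariate shortcut, plus person-level
   percentile bootstrap bands;
5. **synthetic cohorts** (`msabs.simulate`) — a generator with covariates, a
   confounded binary exposure, multinomial initial states, constant-rate
   Markov (or Weibull-sojourn semi-Markov) dynamics, administrative
   censoring and raw-spell artifacts, retaining exact ground truth
   (matrix-exponential curves) for validation;
6. **CLI** (`msabs.cli`) — reproducible end-to-end runs with manifests.

## CLI

```sh
# simulate a synthetic cohort from a generator spec (JSON or YAML)
msabs simulate --spec generator.yaml --out sim/

# clean spells and build histories + transition rows + count table
msabs clean --records sim/records.csv --covariates sim/covariates.csv \
            --end-day 1825 --out cleaned/

# fit per-transition models and predict covariate-specific probabilities
msabs fit --rows cleaned/transition_rows.csv --kind cox \
          --covariate age --covariate exposure --out models.json
msabs predict --models models.json --z '{"age": 45, "exposure": 1}' \
              --t-max 1095 --out curves.csv

# everything in one reproducible run (writes a manifest)
msabs run-all --config run.yaml --out run/
msabs report --run-dir run/
```

A `run-all` config looks like:

```yaml
seed: 11
generator: { ... GeneratorSpec as dict ... }   # or records:/covariates:/end_day:
covariate_columns: [z, exposure]
model_kind: additive_constant   # or cox
t_max: 730
bootstrap_B: 200
interventions:
  - name: agreement
    spec: {kind: set_exposure, exposure_value: 1}
    anchor: 4
    destination: 1
  - name: no_full_sick_leave
    spec:
      kind: manipulate_intensity
      actions: [[reroute, 1, 3, 2], [reroute, 4, 3, 2]]
```

Exit codes: 0 ok, 2 input-schema error, 3 model-fit failure.

## Conventions

Time is integer days since baseline with half-open `[start, stop)`
intervals; state 5 is absorbing; transition rows follow the documented CSV
schema (`person_id, from_state, to_state, entry, exit, status, weight` +
covariate columns). Missing answers on the binary questionnaire items
(married / higher education / cooperation agreement) are recoded to "no"
with explicit missingness flags.
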