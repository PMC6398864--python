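# textps

Propensity-score pipelines from unstructured EHR text.

`textps` builds comparative-safety analyses in which the confounders are not
coded variables but *words*: free-text clinical notes are turned into
bag-of-words covariates, an L1-penalized logistic propensity model is fitted
on them, treated episodes are matched to controls by greedy one-to-many
caliper matching, and treatment effects are estimated with Cox
proportional-hazards regression. The worked example throughout is the classic
channeling problem of selective COX-2 inhibitors vs nonselective NSAIDs and
upper-gastrointestinal bleeding.

Because real primary-care EHR corpora are proprietary, the package ships a
first-class synthetic EHR generator with a *known* confounding structure:
a latent gastrointestinal risk drives both treatment choice (channeling) and
outcome hazard, and leaks into the notes only through "proxy" words. The true
hazard ratio is known by construction, so the whole pipeline can be validated
end-to-end: the crude estimate is provably biased, and matching on the
text-based propensity score must pull the estimate back toward the truth.

## Modules

| module | role |
| --- | --- |
| `textps.synthetic_ehr` | synthetic patients, prescriptions, notes, outcomes + ground-truth sidecar |
| `textps.cohort_builder` | new-user treatment episodes (washout, refill chaining, switching, free-text drug-mention exclusion) |
| `textps.text_featurizer` | text normalization and episode x unigram presence matrices over a 6-month lookback |
| `textps.covariate_selector` | covariate selection: document frequency, outcome chi-square, established confounders |
| `textps.propensity_model` | L1-penalized logistic propensity model, scoring, AUC, 3-fold CV |
| `textps.ps_matcher` | greedy iterative one-to-many caliper matching |
| `textps.outcome_analysis` | Cox hazard ratios for the crude / age-matched / PS-matched design grid |
| `textps.pipeline_cli` / `textps.cli` | config-driven orchestration, run manifests, `textps` CLI |
| `textps.experiments` | seeded confounding-recovery simulation study |

## CLI

Every stage is independently runnable; `all` chains them and writes a
manifest (config echo, versions, cohort attrition counts, covariate counts
and cross-validated AUCs per selection method, and the results grid):

```bash
textps all --run-dir runs/demo --config configs/demo.yaml
# or stage by stage:
textps simulate --run-dir runs/demo --config configs/demo.yaml
textps cohort   --run-dir runs/demo --config configs/demo.yaml
...
textps analyze  --run-dir runs/demo --config configs/demo.yaml
```

Outputs in the run directory include `data/` (patients.csv,
prescriptions.csv, notes.jsonl, outcomes.csv plus the ground-truth sidecar),
`episodes.csv`, a MatrixMarket feature matrix with label sidecars, selection
and model YAMLs, `matches_*.csv`, `results.csv` (matching x adjustment grid
of hazard ratios with 95% CIs) and `manifest.yaml`. Re-running with the same
config reproduces every file byte-for-byte.

## Notes on key defaults

- "Six months" = 183 days, "one year" = 365 days; prescription duration =
  quantity / daily dose rounded half up, clamped to >= 1 day.
- Matching caliper 0.01 on the probability scale; ties broken by
  (treated id, control id); a control is consumed permanently once matched.
- The Laplace-prior hyper-parameter is an L1 penalty per coefficient against
  the total log-likelihood (default 0.01, configurable); the intercept is
  unpenalized and binary features are not standardized.
- CV folds are a seeded unstratified random partition.
- Matched analyses fit an unstratified Cox model (Efron ties, Wald CIs) on
  the matched sample; episodes are the independent unit.
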