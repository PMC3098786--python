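# survinterim

Group-sequential interim analyses of high-dimensional survival studies.

`survinterim` simulates two-phase survival-microarray trials (a recruitment
phase with sample-size-triggered looks, then a follow-up phase with
calendar-triggered looks), screens every gene at each look with a univariate
Cox proportional-hazards regression, controls the FDR with the
Benjamini–Hochberg step-up at the full nominal level (no interim-specific
alpha spending), estimates the achieved **average power rate** (APR — the
detected fraction of truly survival-related genes) with a π0-based plug-in
estimator, and applies an APR-threshold early-stopping rule.  A Monte-Carlo
layer aggregates per-look FDR/APR behavior and first-stop fractions across
replicate studies.

## Library overview

| module | contents |
| --- | --- |
| `survinterim.study_design` | `StudyDesign`, analysis scheduling, administratively censored `SurvivalSnapshot`s, patient-table IO |
| `survinterim.synthetic_cohort` | cohort simulation (exponential / log-normal survival), discretized-normal or table-driven effect vectors, AR(1)-correlated expression matrices |
| `survinterim.cox_screen` | vectorized gene-wise Cox fits (Breslow ties, safeguarded Newton, Wald test, score-test fallback) |
| `survinterim.error_control` | BH/BY adjustment, the equivalent raw-p threshold `bh_alpha`, confusion metrics vs the known truth |
| `survinterim.apr_estimation` | π0 estimation (fixed-ϑ and spline smoother), plug-in APR estimate, stop decision |
| `survinterim.trial_engine` | single-study runs, Monte-Carlo aggregation, analysis of user data, config files and named profiles |

```python
from survinterim import trial_engine

config = trial_engine.profile_config("m4-tau50")          # full-scale profile
config = trial_engine.scaled(config, d=2000, n_runs=200)  # desk scale
summary = trial_engine.run_monte_carlo(config)
print(summary.to_frame())                                 # per-look means/SDs
```

## Command line

```bash
# Monte-Carlo simulation from a named profile or a YAML config
survinterim simulate --profile m4-tau50 --out out/ --runs 200 --genes 2000 --seed 1
survinterim simulate --config my_config.yaml --out out/

# Per-look analysis of your own expression matrix + patient table
survinterim analyze --expr expr.csv --patients patients.csv \
    --config my_config.yaml --out out/
```

Profiles: `m4-tau50` (2+2 looks, τ=50%), `m10-tau50` / `m10-tau50-small`
(5+5 looks, large/small effects), `m10-tau5` (τ=5%), and `breast`
(log-normal survival, packaged value/count effect table, reduced variance).
Config files are flat YAML key/value documents; unknown keys are rejected
(see `survinterim.trial_engine._CONFIG_KEYS`).

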