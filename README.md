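# resistfam

Per-mouse analysis of tumor-volume time courses under weekly drug dosing,
built around a family of sensitive/resistant/drug ODE models:

* **cohort** — tidy-CSV I/O for per-mouse (time, volume) series, caliper
  volume computation (`l·w²·π/6`), censoring of implausible transient
  spikes, endpoint trajectory classification, and a cohort-level Fisher
  exact response test.
* **growth_models** — exponential / logistic / Allee / surface /
  von Bertalanffy growth laws with adaptive RK integration and a
  closed-form (log-linear OLS) exponential fit.
* **resistance_models** — six treatment models crossing resistance timing
  (pre-existing or not) with mechanism (none / random / drug-induced
  transitions), simulated under impulsive weekly dosing with exact
  piecewise-analytic evaluation (an adaptive RK route is kept as a
  cross-check).
* **fitting** — two-step fitter: Sobol quasi-Monte Carlo global search
  over biologically bounded parameter boxes, then downhill-only random
  perturbation descent, wrapped in a seeded multistart with a per-start
  audit trail.
* **model_selection** — SSE-based AIC/BIC, per-mouse best/worst ranking
  with low/medium/high confidence tiers, cohort-level tallies.
* **identifiability** — profile-likelihood scan of the initial resistance
  fraction R(0)/(S(0)+R(0)) with re-optimization of all remaining
  parameters and an identifiability verdict.
* **dose_escalation** — in-silico fold reduction after two weeks of weekly
  dosing across an escalated dose range, with cohort medians and the
  average rate of change.
* **synthetic_data** — cohort generator with known ground truth (lognormal
  inter-mouse variation, multiplicative noise, injected outlier spikes)
  plus parameter/selection recovery experiments.
* **pipeline / cli** — `resistfam` command orchestrating
  preprocess → fit → select → profile → escalate with deterministic
  per-mouse/model sub-seeds and a checksummed run manifest.

## CLI

```sh
# synthetic cohort with ground truth
resistfam synth --model 1.2 --n-mice 10 --seed 1 --out cohort.csv --truth truth.json

# censor outliers, classify trajectories, Fisher test (if both groups present)
resistfam preprocess cohort.csv --out censored.csv --summary response.json

# fit all six resistance models per treatment mouse
resistfam fit censored.csv --model all --n-qmc 4096 --n-iter 2000 --n-starts 3 \
    --seed 1 --out-dir fits/

# AIC/BIC ranking and cohort tallies
resistfam select fits/ --out-prefix selection

# profile the initial resistance fraction
resistfam profile censored.csv --model 1.2 --grid-step 0.05 --seed 1

# dose escalation from saved fits
resistfam escalate fits/ --model 2.1 --dose-min 16 --dose-max 20

# everything from one config / shorthand
resistfam run --model 1.1 --out-dir results/run --seed 42
```

Paper-scale budgets (1.5e6 Sobol points, 5e5 descent iterations, 15
starts) are the library defaults; every entry point exposes reduced
budgets for desk-scale work.

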