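# refcorrect

Estimation of a binary index test's sensitivity and specificity when the
reference standard is imperfect but has known sensitivity and specificity.

The package provides:

- **Correction estimators** (`refcorrect.estimators`): the classical
  (gold-standard) estimates, the Staquet estimators (with corrected
  prevalence), the Gart–Buck estimators (algebraically equivalent to
  Staquet, kept as an independent code path for cross-checking), and the
  Brenner estimators — all assuming conditional independence of the two
  tests given disease status — plus Wilson score confidence intervals.
  Estimates outside [0, 1] are never clamped: they are flagged as
  *illogical* and carry no confidence interval.
- **A scenario simulator** (`refcorrect.simulator`): joint 2×2 cell
  probabilities from prevalence, the two tests' accuracies and fixed
  within-class covariance terms (zero under conditional independence),
  with feasibility-bound validation and reproducible multinomial
  replicate sampling.
- **Monte-Carlo evaluation** (`refcorrect.evaluation`): mean, empirical
  SE, bias and MSE of each estimator across replicates, over sample-size
  grids and prevalence sweeps, with illogical/dropped replicate
  accounting and CSV export.
- **Clinical case studies** (`refcorrect.casestudies`): five packaged
  published 2×2 datasets (HRA cytology vs punch biopsy; two
  fluorescence-based caries devices vs visual inspection at two
  diagnostic thresholds) with their reference accuracies, and a runner
  that reproduces the published unadjusted/corrected tables.

## CLI

```sh
# correct one 2x2 table (a=IT+/RS+, b=IT+/RS-, c=IT-/RS+, d=IT-/RS-)
refcorrect correct --a 40 --b 22 --c 22 --d 177 --sn-rs 0.74 --sp-rs 0.91

# dump replicate tables for a predefined scenario
refcorrect simulate --scenario scenario_one --seed 1 --n 1000 --reps 200 --out tables.csv

# sample-size or prevalence sweep from a JSON/YAML config
refcorrect sweep --config examples/scenario_one.json --axis n --out-dir out/

# re-analyse the packaged clinical datasets
refcorrect clinical --case all --format csv
```

Predefined scenarios: `scenario_one` (reference standard better than the
index test), `scenario_two` (index test better), `scenario_three` (both
equal), `dependence` (positively correlated tests, covariance 0.05).

A sweep config is a JSON/YAML mapping with keys `scenario` (optional
base) and/or `prevalence, sn_it, sp_it, sn_rs, sp_rs, cov_d, cov_nd, n,
reps, seed, name`, plus optional `n_grid` / `prevalence_grid` /
`exclude_illogical`. Each sweep writes a summary CSV and a JSON manifest
(config echo, seed, version) sufficient to reproduce the run bit-for-bit.

## Python API

```python
from refcorrect import (
    ContingencyTable, ReferenceAccuracy,
    staquet_correct, brenner_correct, attach_wilson_ci,
)

table = ContingencyTable(40, 22, 22, 177)
ref = ReferenceAccuracy(sn=0.74, sp=0.91)
result = attach_wilson_ci(staquet_correct(table, ref), table)
result.sensitivity.value   # 0.8938
result.sensitivity.ci      # (0.794, 0.949)
```

## Notes on conventions

- Confidence intervals for sensitivity use n = e (reference-positive
  margin) and for specificity n = f; the case-study runner computes the
  corrected methods' intervals from the 2-dp rounded point estimate,
  which is the convention the published clinical tables follow
  (classical intervals use the exact proportion).
- Empirical SE is the standard deviation of replicate estimates; MSE is
  the mean squared deviation from the generating truth, so
  MSE = population variance + bias² holds exactly per stratum.
- Illogical estimates are included in Monte-Carlo means by default (and
  counted per stratum); pass `exclude_illogical=True` to drop them.
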