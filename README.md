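# hwdi

State-level income-by-BMI disparity indices under two frames of reference,
with a full analysis pipeline and a synthetic survey-data generator.

The package computes, per US state, the **Healthy Weight Disparity Index**
(HWDI) — signed deviations of low/middle/high-income mean BMI from the
fixed 24.9 healthy-weight standard — and its **state-referenced revision**
(RHWDI), which replaces the national standard with the state's own
adjusted mean BMI and replaces the fixed income cut points with a
poverty-guideline-ratio classification (low ≤ 185% of the federal poverty
guideline; high above the state-specific 75th percentile of the
poverty-ratio distribution). States are ranked by index magnitude and the
two rankings are compared with Spearman's rho (optional Bonferroni
factor), tercile Cohen's kappa, and per-state rank-difference summaries.

## Layout

| module | what it does |
| --- | --- |
| `hwdi.synthetic_data` | BRFSS-like microdata generator with known income–BMI gradients, demographic margins, survey weights, and MCAR / MAR-on-weight missingness injection |
| `hwdi.cohort` | respondent exclusions (pregnant, out of 18–64 range, BMI < 18.5) and state eligibility screening (excess missingness, empty income×race crosstab cells) |
| `hwdi.income` | dollar assignment for the 8 ordinal income categories, poverty-guideline ratios, and both low/middle/high classification schemes |
| `hwdi.imputation` | chained-equations multiple imputation per state (linear regression, predictive mean matching, logistic regression; survey weight as predictor) |
| `hwdi.adjusted_means` | survey-weighted WLS of BMI on age/race/sex/education + income group, marginal-standardization group means, Rubin point pooling |
| `hwdi.indices` | HWDI/RHWDI formulas, negativity flags, magnitude rankings |
| `hwdi.concordance` | Spearman (t-approximation or exact permutation), terciles, Cohen's kappa, rank-difference summaries |
| `hwdi.interface` | microdata I/O, YAML config, pipeline orchestration, CLI, packaged data |

Packaged data (`src/hwdi/data/`): the 49-state printed index/ranking table
used as the concordance regression baseline, and the January-2016 DHHS
poverty guidelines (contiguous+DC / Alaska / Hawaii).

## CLI

```sh
# generate synthetic microdata
hwdi simulate --out micro.csv --states "Texas,Ohio,Utah" --n-per-state 2000 \
    --missing-rate 0.1 --seed 7

# run the full pipeline (microdata -> indices + concordance report)
hwdi run-pipeline --input micro.csv --out-dir results/ --seed 7

# concordance between two rankings (defaults to the packaged 49-state table)
hwdi compare-indices
```

`run-pipeline` also accepts `--config cfg.yaml` mirroring
`hwdi.interface.PipelineConfig` field names (generator parameters,
imputation spec, percentile weighting, adjusted-vs-crude means, output
directory, master seed).

Note: the state-eligibility screen drops any state whose observed
income-by-race crosstab has an empty cell. Small synthetic states with
rare race levels (the default survey-like margins include 1.6% levels)
can legitimately fail this screen — use larger `n_per_state` or less
skewed margins when simulating.

## Scope notes

- Survey weights are honored for all point estimates; design-based
  variance estimation (replicate weights, linearization) is out of scope.
- The 75th percentile of the poverty-ratio distribution is unweighted by
  default (averaged-inverted-CDF definition); a survey-weighted variant is
  available via `weighted_percentile=True`.
- Adjusted means default to marginal standardization (g-computation); a
  predict-at-covariate-means variant and crude weighted means are exposed
  as config flags.
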