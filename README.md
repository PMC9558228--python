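# nirsentropy

Sample-entropy analysis of intraoperative cerebral oximetry (rSO₂) traces,
with the full diagnostic-accuracy statistics layer needed to relate signal
irregularity to postoperative cognitive improvement (POCI), and a synthetic
cohort generator so the whole pipeline runs without any patient data.

## What it does

- **`nirsentropy.oximetry`** — read/write/validate 2-s sampled rSO₂ series
  (CSV + JSON sidecar), pre-induction baseline, intraoperative summary, and
  desaturation burden (duration and area strictly below 100/90/80% of
  baseline, rectangular 2-s integration).
- **`nirsentropy.entropy`** — SampEn(m, r, N) with Chebyshev template
  matching over the extension-restricted template range; tolerance given in
  signal units or as a multiple of the series SD (grid 0.10/0.15/0.20/0.25);
  `d ≤ r` matching by default with a strict `<` switch.
- **`nirsentropy.surrogate`** — phase-randomized and AAFT surrogates, the
  lag-1 time-reversal asymmetry statistic, and an exact two-sided rank test
  (default 99 surrogates at α = 0.05) for nonlinear dynamics.
- **`nirsentropy.cognition`** — MoCA education adjustment (+1 for ≤ 12 years,
  capped at 30) and the ≥ 3-point-gain POCI label.
- **`nirsentropy.inference`** — 2×2 tests with an expected-count policy
  (Fisher < 1 ≤ Yates < 5 ≤ Pearson), pooled/Welch t and Mann–Whitney z,
  univariate and backward-LR multivariate logistic regression with Wald CIs,
  ROC/AUC with DeLong or Hanley–McNeil CIs, and AUC z-test power.
- **`nirsentropy.simulate`** — synthetic cohorts: covariates and MoCA scores
  drawn from configurable group distributions, plus rSO₂ traces from a
  trend + periodic + AR(1) signal model whose single irregularity weight is
  calibrated against group-level SampEn targets.
- **`nirsentropy.pipeline` / CLI** — simulate → feature extraction →
  outcome labelling → statistics → CSV report bundle with a JSON run log.

## CLI

```sh
# full run: simulate a 57-subject cohort, extract features, write the report
nirsentropy run-all --out-dir study_out --seed 1

# individual stages
nirsentropy simulate --out-dir data --seed 1          # cohort.csv + series/
nirsentropy entropy data/series/S001.csv --r-coef 0.1 --r-coef 0.2
nirsentropy surrogate data/series/S001.csv --n-surrogates 99
nirsentropy report --data-dir data --out-dir report   # features + statistics
nirsentropy analyze --cohort data/cohort.csv --features report/features.csv \
    --out-dir tables
```

`run-all` accepts `--config config.yaml` overriding any `RunConfig` field
(group sizes, entropy grid, surrogate count, CI method, selection
thresholds). Output tables: baseline characteristics (`table1.csv`),
oximetry/entropy comparison (`table2.csv`), logistic models (`table3.csv`),
ROC summary (`roc.csv`, the headline entropy predictor alone and combined
with preoperative MoCA + blood-pressure-lowering), ROC curve points, the
backward-elimination trace, and `run_log.json` with every tunable setting.
Identical seeds give byte-identical outputs.

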