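# arsmr

Two-sample Mendelian randomization of arsenic-metabolism efficiency (%iAs,
%MMA, %DMA in urine) against asthma and spirometry-based pulmonary traits,
exercised end-to-end on synthetic cohorts.

The package bundles a three-SNV literature instrument (per-allele shifts in
the urinary metabolite percentages, with standard errors), and provides:

- **`arsmr.instrument_catalog`** — loading/validation of the instrument
  weight table, allele harmonization against a cohort's dosage coding, and
  LD (signed correlation) estimation from dosages.
- **`arsmr.synthetic_cohort`** — a cohort generator with configurable
  two-locus LD (D′/r² targets), metabolite percentages closing to 100,
  household/sibship/block-group clustering, smoking and rice-consumption
  strata, reference-model spirometry, and binary pulmonary outcomes whose
  log-odds depend on %iAs only in the high-rice stratum (the low-rice
  stratum is a built-in negative control).
- **`arsmr.phenotyping`** — smoking strata (never = fewer than 100 lifetime
  cigarettes), asthma categories (none/past/current/missing), the 0.88
  anti-asthmatic medication correction, spirometry effort/quality inclusion,
  lower-limit-of-normal thresholds (5th percentile of a stratified normal
  reference model), percent-predicted transforms, and the 80th-percentile
  rice-exposure classifier.
- **`arsmr.association`** — per-SNV Wald tests against each trait with
  fixed effects for principal components, ancestry group and log sampling
  weight, and optional random effects over kinship/household/block-group
  kernels (REML for gaussian traits, penalized quasi-likelihood on the logit
  scale for binary traits; both collapse to OLS / logistic regression
  without kernels).
- **`arsmr.mr_estimator`** — the principal-components IVW estimator for
  correlated instruments (eigen-decomposition of the weighted summary matrix
  Psi, generalized IVW in the reduced space), plus a full-rank GLS oracle
  used to validate it.
- **`arsmr.pipeline`** — orchestration across the four strata
  ({never, ever} smoking × {high, low} rice), the sensitivity-toggle suite
  (broadened asthma, continuous and percent-predicted outcomes, medication
  handling variants, strict quality), an exclusion ledger, and deterministic
  TSV/JSON reports.

## CLI

```bash
# generate a synthetic cohort (cohort.tsv, clusters.tsv, truth.json, variants.vcf)
arsmr simulate --out sim/ --seed 1

# full analysis from a YAML run config
arsmr run --config config.yaml

# baseline plus the sensitivity suite
arsmr sensitivity --config config.yaml
```

A minimal `config.yaml`:

```yaml
out_dir: results/run1
seed: 1
simulation:
  n_participants: 5000
rice_percentile: 80
medication_mode: scale      # scale | covariate | exclude
pc_variance_threshold: 0.99
use_cluster_random_effects: false
```

Each run writes `phenotyped_cohort.tsv`, `associations.tsv`,
`mr_estimates.tsv` (stratum × trait × metabolite: OR, 95% CI, p,
components retained) and `report.json` (exclusion ledger, realized rice
cutoff and LLN thresholds, config echo, output fingerprint). Reruns with the
same config and seed are byte-identical. Exit codes: 0 clean, 1 partial
(error-coded cells), 2 fatal.

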