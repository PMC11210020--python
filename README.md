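# summr

Two-sample Mendelian randomization (MR) from GWAS summary statistics, built
for two-step mediation analyses: harmonization of per-variant association
tables, univariable MR estimators with sensitivity analyses, MR-PRESSO
outlier detection, multivariable MR (MVMR) mediation decomposition,
random-effects meta-analysis over outcome cohorts, instrument-strength and
power calculations, and a synthetic summary-statistics generator with known
ground truth for end-to-end validation.

## Modules

| module | contents |
|---|---|
| `summr.sumstats` | `read_sumstats`, `reconstruct_se`, `select_instruments` (greedy LD clumping), `exclude_blocklist`, `harmonize` (allele alignment, strand complements, palindromic EAF rules) |
| `summr.estimators` | `wald_ratio`, `ivw_mre` (multiplicative random effects), `cochran_q`, `egger` (+ intercept test, I²_GX), `weighted_median` (parametric bootstrap SE), `subset_estimates` |
| `summr.presso` | MR-PRESSO global RSS test, per-SNP outlier test (Bonferroni), distortion test, outlier-corrected re-estimation |
| `summr.mediation` | `mvmr`, `mediate` (product of coefficients, delta-method SE, proportion mediated), `per_doubling` (ln 2 rescaling of liability-scale effects) |
| `summr.meta` | DerSimonian–Laird `meta_random`, `instrument_strength` (R², F), `mr_power` / `detectable_effect` |
| `summr.simulate` | `SimulationConfig` / `simulate` / `inject_outliers`: exposure → mediator → outcome structural model with configurable pleiotropy, palindromic alleles, flipped representations, multiple cohorts |
| `summr.pipeline` | `run_pipeline` from a YAML config: selection → harmonization → estimators → meta-analysis → mediation; `leave_one_out` |

## CLI

All stages are exposed through the `mr` entry point:

```sh
# synthetic data with known truth
mr simulate --config sim.yaml --out-dir sim/

# instrument selection + allele alignment
mr harmonize --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
    --p-threshold 5e-8 --eaf-window 0.42,0.58 --blocklist default --out set.tsv

# estimators, outlier tests, influence scan
mr run --set set.tsv --methods ivw,egger,wm --seed 7 --out estimates.tsv
mr presso --set set.tsv --nsim 1000 --seed 11 --out presso.json
mr loo --set set.tsv --out loo.tsv

# meta-analysis and power
mr meta-analyze --in cohort_estimates.tsv --out meta.tsv
mr power --n 885701 --cases 9491 --r2 0.013 --alpha 0.05 --target-power 0.8

# full two-step analysis from one config
mr run-all --config analysis.yaml
```

`analysis.yaml` names exposure/mediator/outcome tables (outcomes as labeled
cohort files), thresholds, methods, seeds, mediation triples, and an output
directory; the pipeline writes `estimates.tsv`, `instruments.tsv`,
`mediation.json`, `presso.json`, and `failures.json`.

Input tables are tab- or comma-delimited with flexible headers
(SNP/rsid, A1/EA, BETA/b, SE, P/pval, EAF/FRQ, N...). Effects for binary
traits are log-odds; exposures with unit `log-odds` are reported per
doubling of prevalence (× ln 2).

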