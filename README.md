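# tsmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection and harmonization, six causal-effect estimators, a full
diagnostic suite, a reporting policy with explicit gates, and a synthetic
summary-statistics generator so the whole pipeline is testable end to end
without any external data.

## What it does

* **`tsmr.sumstats`** — read/write delimited GWAS summary-statistics tables
  (tab/comma/whitespace dialects, `NA`/`.`/empty missing values, odds-ratio →
  log-odds conversion, per-row validation with reason codes) and square LD
  correlation matrices.
* **`tsmr.instruments`** — genome-wide-significant instrument selection
  (p < 5e-8, optional greedy LD pruning at r² ≥ 0.001) and allele
  harmonization of exposure and outcome effects, including palindromic-SNP
  resolution by allele frequency, with per-SNP Wald ratios.
* **`tsmr.estimators`** — fixed-effect IVW, weighted median, weighted mode
  (with parametric-bootstrap SEs), and Egger regression with its
  directional-pleiotropy intercept.
* **`tsmr.diagnostics`** — Cochran's Q, the I²_GX gauge of the NOME
  assumption, SIMEX-corrected Egger, per-SNP F statistics and variance
  explained, Steiger directionality filtering, leave-one-out analysis.
* **`tsmr.gsmr`** — HEIDI outlier filtering followed by the LD-aware
  generalized least-squares estimate.
* **`tsmr.pipeline`** — the full bidirectional battery under a
  `DecisionPolicy`: IVW/median/mode always (≥ 3 SNPs); Egger and GSMR only
  with ≥ 10 SNPs; Egger reported in full when I²_GX > 0.9, as SIMEX when
  0.6 ≤ I²_GX ≤ 0.9, suppressed below 0.6; Steiger-filtered refits of every
  reported estimator; evidence grading by cross-estimator sign consistency;
  deterministic tab-delimited reports.
* **`tsmr.simulate`** — generative scenarios with configurable causal effect,
  instrument strength, pleiotropy (balanced / directional / InSIDE-violating),
  reverse causation, binary traits, and harmonization stressors
  (palindromic/swapped alleles), plus a Monte-Carlo `recovery_suite`.

## CLI

```sh
# generate a synthetic dataset
tsmr simulate --config scenario.json --out-prefix sim --seed 1

# instrument selection + harmonization only
tsmr harmonize sim.exposure.tsv sim.outcome.tsv --out-prefix sim

# the full battery, both directions, with reports
tsmr mr sim.exposure.tsv sim.outcome.tsv --direction both --seed 1 \
    --out-dir results/
# optional: --policy policy.json --ld ld.tsv --reverse-outcome other.tsv

# condense a saved results.json
tsmr report results/results.json --out-dir results/
```

`scenario.json` holds `SimulationScenario` fields (e.g. `{"L": 50, "theta":
0.1, "sigma_gamma": 0.2}`); `policy.json` holds `DecisionPolicy` fields. The
policy in force is echoed into the output directory for provenance, and every
dropped SNP, suppressed method and gate decision is logged with a reason code
(`-v` for verbose).

## Python API

```python
from tsmr import (SimulationScenario, simulate_sumstats, select_instruments,
                  harmonize, ivw, run_bidirectional, DecisionPolicy)

exposure, outcome = simulate_sumstats(SimulationScenario(L=50, theta=0.1,
                                                         sigma_gamma=0.2))
hset = harmonize(select_instruments(exposure), outcome)
print(ivw(hset))
forward, reverse = run_bidirectional(exposure, outcome, DecisionPolicy(seed=1))
```

## Notes on conventions

* The Wald-ratio SE is first-order (`se_out/|beta_exp|`); a second-order
  option exists on `harmonize`.
* IVW is fixed-effect; a multiplicative random-effects variant exists as an
  option but is never used by the default policy.
* Egger regression orients all instruments to positive exposure effects, uses
  residual-scaled WLS standard errors and t(n−2) p-values.
* Binary traits use the effective sample size `4/(1/n_case + 1/n_control)` in
  variance-explained formulas; betas are natural-log odds throughout, so one
  log-odds unit of a binary exposure corresponds to a 2.72-fold change in
  prevalence odds.
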