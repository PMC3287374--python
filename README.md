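# phyloplast

Phylogenetic comparative analysis of anuran larval development under pond
desiccation risk: derived developmental traits and plasticity statistics,
generalized least squares under star versus tree (Grafen) covariance
structures compared by AIC and Akaike weights, a conservative
soft-polytomy degrees-of-freedom correction, and a synthetic-data
generator with recorded ground truth.

## What it does

* **`phyloplast.tree`** — Newick parsing (via dendropy), Grafen
  ultrametric branch lengths (node height = (tips below − 1)/(n − 1)),
  Brownian-motion covariance matrices, soft-polytomy counting, and
  attachment of replicate observations as near-zero-length tip clusters.
* **`phyloplast.traits`** — developmental rate (1/period), mean growth
  rate (mass/period), volume→mass at density 1 g/mL, percent plasticity
  `100·(trait_d − trait_c)/trait_c`, and Hedges' d with sampling variance.
* **`phyloplast.pgls`** — GLS fits with ML likelihood, AIC
  (k = coefficients + variance scale), Akaike weights, and coefficient
  t-tests at residual df minus one per unresolved node.
* **`phyloplast.analysis`** — the pipeline stages: venue screening,
  High/Low-risk group comparisons of log10 traits, ANCOVA controlling for
  developmental time, plasticity comparisons, the time-plasticity × risk
  interaction, and plasticity-versus-mean-trait regressions; each stage
  emits a star-vs-tree model comparison.
* **`phyloplast.simulate`** — pure-birth trees, Brownian trait evolution
  with habitat-group shifts, and full paired constant/drying datasets
  with controllable group-dependent plasticity structure.

## CLI

```sh
# generate a synthetic dataset (tree.nwk, cases.tsv, truth.json)
phyloplast simulate --n-species 30 --seed 1 --n-polytomy-species 5 --out sim/

# derived-trait and plasticity tables
phyloplast derive --data sim/cases.tsv --out derived/

# full analysis: report.json, derived_traits.tsv, plasticity.tsv, model_tables.tsv
phyloplast analyze --tree sim/tree.nwk --data sim/cases.tsv --out analysis/

# summarize an existing report
phyloplast report --report analysis/report.json
```

Input data are TSVs with one row per case × treatment (columns:
`case_id species population risk_group venue treatment period_mean
period_sd period_n mass_mean mass_sd mass_n mass_is_volume`).
An optional YAML config (`--config`) overrides `AnalysisConfig` fields
(stage selection, replicate-branch epsilon, minimum paired cases, seed).

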