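# gutpredict

Discovery of sparse gut-microbiome taxon sets that predict long-term
weight-loss outcomes from baseline relative abundances in a small cohort
(n ≈ 15 patients, p ≈ 100 dominant taxa).

The pipeline reduces a taxa-by-sample abundance table to its dominant taxa,
locates outcome-associated taxa by three complementary routes, fuses the
evidence into a final candidate score, and evaluates sparse k-term linear
predictors:

1. **Screening** — per-taxon correlations with both responses (relative
   weight loss in % and change in BMI), plus a banded "correlation class"
   (0, ±0.5, ±1, ±1.5, ±2) from the smaller of the two absolute correlations.
2. **Elastic-net stability selection** — repeated cross-validated elastic-net
   fits (fresh fold assignment per repeat, penalty chosen by minimum CV error,
   refit on all samples); a taxon's *occurrence* is the percentage of repeats
   in which its coefficient is nonzero.
3. **Monte-Carlo model search** — a large pool of small OLS models scored by
   small-sample AICc; per-taxon importance is a weighted index of pool
   statistics (top-model frequency, Akaike weight, sign consistency),
   iteratively reducing the term list (e.g. 102 → 44 → 23 → 15 → 7) under two
   weightings.
4. **Final scoring** — score = (7 − full-list rank) + (7 − final-list rank) +
   3·(elastic-net selected) + |correlation class|, missing ranks contributing 0.
5. **Prediction** — exhaustive best k-term models (k = 1..5) by AICc, with
   adjusted R², cross-validated R² (3/5/8/15 folds, out-of-fold predictions
   averaged over repeats), and per-patient classification against a 10%
   weight-loss threshold.
6. **Ordination** — clr transform, PCA, Euclidean PERMANOVA (own
   implementation, seeded permutations), Mann-Whitney group tests with
   Benjamini-Hochberg FDR.

A synthetic cohort generator (log-normal compositional model with planted,
correlation-calibrated outcome-associated taxa) makes every stage testable
with no external data.

## Tests

```sh
python -m pytest -q tests/
```

The statistical acceptance tests (`tests/test_acceptance.py`) include
multi-minute simulations; the unit suite alone finishes in well under a
minute.

## CLI

Each stage is a subcommand; `all` runs the pipeline from a YAML config:

```sh
gutpredict generate --n-taxa 1020 --n-planted 3 --seed 1 --out cohort/
gutpredict prep --abundance cohort/abundance_genus.tsv --n-keep 102 --out pm.csv
gutpredict screen --matrix pm.csv --outcomes cohort/outcomes.csv --out screen.csv
gutpredict enet --matrix pm.csv --outcomes cohort/outcomes.csv --alpha 1 --folds 5 \
    --repeats 1000 --seed 42 --out enet.csv
gutpredict mc --matrix pm.csv --outcomes cohort/outcomes.csv \
    --weights 0.6,0.2,0.2 --schedule 102,44,23,15,7 --models 100000 --seed 7 \
    --out-prefix mc
gutpredict all --config run.yaml
```

Example `run.yaml`:

```yaml
output_dir: out
seed: 7
synthetic:
  n_planted: 3
  target_abs_corr: [0.6, 0.6, 0.6]
  outcome_mode: from_planted
en_repeats: 1000
mc_models: 20000
```

Use `abundance_path`/`outcomes_path` instead of `synthetic:` to analyze your
own TSV/CSV tables (samples in rows, taxa in columns; outcomes CSV with
`patient_id, group, rwl_percent, delta_bmi`).

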