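# boostfill

Missing-value imputation for mixed-type tabular data — continuous
measurements, categorical labels and Boolean flags in one table, with
missing cells spelled however a spreadsheet spells them (`NA`, `#DIV/0!`,
blanks, ...). The intended users are analysts working with clinical,
epidemiological or omics tables who need a single complete dataset, not a
Rubin-style multiply-imputed ensemble.

## Method

For a table **X** with missing mask **Ω**, boostfill runs four stages:

1. **Preprocessing.** Missing-token normalization; optional zero-to-missing
   conversion; per-column typing by a strict majority rule (a column is
   continuous or categorical only if that kind exceeds 60% of its
   non-missing cells, minority cells are coerced to missing, and columns
   failing both tests are excluded from imputation); label encoding of
   categoricals. Output: clean, encoded, and pre-imputed encoded tables.
   The pre-imputation fill is column-mean/mode, kNN, or a mix.
2. **Adaptive matrix completion.** On the pre-imputed matrix, an outer
   fit–reconstruct–refill loop around a rank-r factorization: NMF
   (X ≈ W·H, W,H ≥ 0) when every observed value is non-negative, truncated
   SVD (X ≈ U_r Σ_r V_rᵀ, column-centered) otherwise. Only the originally
   missing cells are overwritten each round (`nan_only` mode); `full` mode
   returns the denoised low-rank reconstruction instead.
3. **Per-column boosted ensembles.** Each column *j* with missing cells is
   regressed/classified on the completed matrix minus column *j*. A
   dataset-size gate (more than 50 samples, sample/feature ratio ≥ 4, at
   most 100 missing columns) decides between hyperparameter search and
   fixed defaults; either way each of the 3–9 ensemble members trains on an
   independent 70% row subsample, and predictions are aggregated by the
   mean (regression) or the mean class-probability argmax (classification).
4. **Iterative refinement.** 1–9 chained passes; within a pass columns are
   updated in place so later columns see earlier columns' fresh
   imputations, and parameters tuned in pass 1 are cached for later passes.

## Worked example

```python
from boostfill import (ImputationConfig, SyntheticSpec, generate_synthetic,
                       mask_mcar, run, score)

spec = SyntheticSpec(n_rows=150, n_cont=8, n_cat=2, n_bool=1,
                     latent_rank=3, noise_sd=0.02, seed=1)
table, truth = generate_synthetic(spec)
masked, mask = mask_mcar(table, fraction=0.2, seed=2)
result = run(masked, ImputationConfig(n_iterations=2, master_seed=3))
print(score(result.imputed_clean, truth, mask, result.profiles))
```

prints (see `examples/03_impute_end_to_end.py`):

```
masked continuous cells: 235, RMSE = 0.0620
masked categorical cells: 95, accuracy = 0.768
per-iteration mean absolute change on imputed cells: ['0.2879', '0.0397']
```

The RMSE is in the units of the continuous block (range ≈ 0–2 here, so the
typical masked-cell error is ~3% of the range); the accuracy is the fraction
of masked category cells restored to their true label; the shrinking
per-pass change shows the chained refinement stabilizing. For comparison, a
column-mean fill on the same mask scores RMSE ≈ 0.28 and accuracy ≈ 0.26
(`examples/04_benchmark_against_baselines.py`).

The `examples/` directory holds one short script per capability:
preprocessing, matrix completion, the end-to-end run, and the benchmark.
A thin CLI wraps the same pipeline:

```bash
boostfill impute --input data.csv --output-dir out --seed 1
boostfill benchmark --rows 200 --fractions 0.1,0.3 --seed 1
```

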