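# Methods

## Problem setting

boostfill produces a single completed dataset from a mixed-type table under
a missing-completely-at-random (MCAR) working assumption: the pattern of
missingness is taken to be independent of both observed and unobserved
values. It does not attempt multiple imputation or uncertainty statements
about the imputed cells.

## Preprocessing rules

Cells are read as text and typed by rules rather than declared schemas.

* **Missing tokens.** The alias set is closed: `NaN`, `NAN`, `Nan`, `nan`,
  `NA`, `#NA`, `N/A`, `NA#`, `#VALUE!`, `#DIV/0!`, plus empty and
  whitespace-only strings (matched after stripping). A closed set is
  deterministic and testable; it can be extended via the `aliases` argument
  of `normalize_missing_tokens`. Normalization is idempotent.
* **Zero conversion.** Optional, off by default: numeric zeros become
  missing. Useful where 0 encodes "not measured" (e.g. expression counts),
  harmful where 0 is a real value — hence a user decision.
* **Column typing.** A column is continuous if more than 60% of its
  *non-missing* cells parse as finite numbers, categorical if more than 60%
  are non-numeric tokens (Boolean spellings `true`/`false` in any listed
  casing count as categorical), otherwise excluded. The inequality is
  strict: a column at exactly 60/40 is excluded. Fractions are computed
  over non-missing cells so that masking more cells cannot flip a column's
  type. Minority-kind cells are coerced to missing and counted in
  `n_coerced`. Excluded columns pass through every output untouched and
  are never imputed or used as features.
* **Encoding.** Label codes 0..K−1 in lexicographic order of the category
  text — deterministic across runs and platforms. Decoding is the exact
  inverse and fails loudly on unseen codes.
* **Pre-imputation.** `column_mean` fills continuous cells with the column
  mean and categorical cells with the modal code (ties to the smallest
  code). `knn` (default k = 5) computes Euclidean distances on the
  mean/mode-filled, per-column min-max-scaled matrix over all typed
  columns, then fills from the k nearest donor rows (mean for continuous,
  majority code for categorical). `mix_type` uses the mean for continuous
  and kNN for categorical. Scaling the distance space stops wide-range
  columns from dominating the metric.

## Matrix completion

The pre-imputed matrix of typed columns is refined by an outer loop:
factorize the current matrix at rank r, reconstruct, overwrite only the
originally missing cells, and stop when the relative L2 change of those
cells drops below `tol` (default 1e-4) or after `max_outer_iters` (default
10) rounds. The inner factorization is NMF (coordinate descent, objective
tolerance 1e-4, at most 500 inner iterations, `nndsvda` initialization
under the run seed) when every observed value is non-negative, otherwise a
column-mean-centered truncated SVD.

Numerical choices:

* **Rank.** Default `min(8, n_rows − 1, n_cols − 1)`. Small ranks
  regularize: the goal is plausible fills, not exact reconstruction.
* **Column scaling (NMF path).** Columns are divided by their maximum
  before factorization and rescaled after. A pure rescaling — rather than
  min-max — is deliberate: a per-column min-max *shift* gives every column
  a different affine map, which inflates the rank of exactly low-rank
  matrices and puts values below the observed column minimum out of reach
  of the zero-clipped refill. Divide-by-max preserves rank exactly while
  still placing label codes and continuous columns on a shared [0, 1]
  scale. After inverse scaling, observed cells are restored bit-exactly so
  `nan_only` mode is cell-identical on the observed mask.
* **Clipping.** NMF refills are clipped at 0 (the method's range
  contract); SVD reconstructions are not clipped.
* **Sub-grouping.** Optional contiguous column blocks of width
  `subgroup_size`, each completed independently — a memory bound for very
  wide tables, off by default.
* `full` mode returns the final low-rank reconstruction everywhere
  (denoising observed cells); the pipeline still writes only originally
  missing cells into its outputs, so observed values are never altered
  downstream regardless of mode.

## Boosted per-column imputation

For each target column: features are the completed matrix minus that
column; training rows are those observed in the target; missing rows are
predicted. Continuous targets use an XGBoost regressor (squared error),
categorical targets a classifier (multiclass log-loss; observed codes are
remapped to a contiguous 0..K−1 range and back).

* **Gate.** Hyperparameter search runs only when the dataset has more than
  50 samples, a sample-to-feature ratio of at least 4, and at most 100
  columns with missing values — search on small or wide data overfits the
  validation split and wastes time. `n_features` counts the feature
  columns, i.e. typed columns excluding the target. The gate is monotone
  in each argument.
* **Fixed defaults** (used when the gate denies or tuning is disabled,
  which is the default): 300 trees, depth 6, learning rate 0.1, subsample
  0.8, colsample 0.8, min child weight 1, L2 1.0 — stable mid-range
  settings stated explicitly so runs are reproducible.
* **Tuning.** A seeded sequential random search (default 20 trials) over:
  learning rate log-uniform [0.01, 0.3], depth {3..9}, trees {100..600},
  subsample [0.6, 0.9], colsample [0.5, 1.0], min child weight [1, 10],
  L2 log-uniform [1e-3, 10]. Candidates are scored on a seeded 80/20
  train/validation split with early stopping (20 rounds), by validation
  RMSE or log-loss. The fixed defaults are always trial 0, so the returned
  parameters can never score worse than the defaults on that split. Few
  trials explore the space poorly, so raise `n_trials` when tuning
  matters.
* **Ensemble.** Each of `n_models` (3–9, default 3) members trains on an
  independent 70% subsample of the training rows, drawn without
  replacement with seed `base + model_index`; a classifier subsample is
  topped up with one row of any class it lost. Regression aggregates by
  the arithmetic mean; classification averages class-probability vectors
  and takes the argmax, ties resolving to the smallest code — a literal
  mean of nominal codes would be meaningless.
* **Degenerate columns.** Fewer than 10 observed rows, or a single
  observed class, falls back to the pre-imputed fill with the reason
  logged and recorded in the run manifest.

## Iterative refinement

1–9 passes (default 3). Columns with missing cells are visited in
ascending order of missing count (ties by original column order): columns
with the most information are re-estimated first, stabilizing the feedback
loop. Updates are in place within a pass (Gauss–Seidel), so later columns
see earlier columns' fresh imputations. Parameters from pass 1 are cached
per column and reused. The mean absolute change of imputed cells is
recorded per pass as a diagnostic; the pass count is fixed — there is no
early convergence stop, so run time is predictable.

Determinism: every stochastic choice (NMF initialization, tuning draws,
subsampling, tree seeds) derives from `master_seed`, and repeated runs are
bit-identical.

## Synthetic data generator

`generate_synthetic` emulates the structure the imputer exploits: a
non-negative rank-r continuous block W·H (entries of W, H uniform on
[0.1, 1]) with optional additive Gaussian noise clipped at 0, plus
categorical columns from quantile-binned latent row factors and Boolean
columns from median-thresholded factors — so every column carries mutual
signal and supervised imputation has something to learn. It does **not**
emulate heavy tails, outliers, nonlinear column dependencies, MAR/MNAR
missingness, or the scale of real cohort tables; passing benchmarks on it
demonstrates the machinery recovers planted low-rank structure under MCAR,
not performance on any particular real dataset.

Benchmark sizes used in tests and in `scripts/acceptance.py` — 500×20
tables (15 continuous, 4 categorical, 1 Boolean), rank 3, noise at 5% of
the continuous range, 10–40% MCAR, 10 seeded replicates with a single
refinement pass — are the package's chosen desk-scale study conditions:
large enough for the gate and ensembles to behave as on real tables, small
enough to re-run routinely.

## Known limitations

* Single imputation only; no variance estimates for imputed cells.
* MCAR masking only in the benchmark; informative missingness will make
  the reported metrics optimistic.
* The 60% typing rule misclassifies numerically-coded categoricals as
  continuous; pre-encode such columns as text if that matters.
* kNN pre-imputation is O(n²) in rows; use `column_mean` on very tall
  tables.
* Excluded (mixed) columns are never imputed and never inform other
  columns' imputations.
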