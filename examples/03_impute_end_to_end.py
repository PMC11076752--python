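"""Full imputation run on a synthetic mixed-type table.

Generates a table with low-rank continuous structure plus categorical and
Boolean columns, masks 20% of cells completely at random, imputes them with
the full pipeline, and scores the imputations against the retained truth.
"""

from boostfill import (
    ImputationConfig,
    SyntheticSpec,
    generate_synthetic,
    mask_mcar,
    run,
    score,
)

spec = SyntheticSpec(n_rows=150, n_cont=8, n_cat=2, n_bool=1,
                     latent_rank=3, noise_sd=0.02, seed=1)
table, truth = generate_synthetic(spec)
masked, mask = mask_mcar(table, fraction=0.2, seed=2)

result = run(masked, ImputationConfig(n_iterations=2, master_seed=3))

metrics = score(result.imputed_clean, truth, mask, result.profiles)
print(f"masked continuous cells: {metrics['n_masked_continuous']}, "
      f"RMSE = {metrics['rmse_continuous']:.4f}")
print(f"masked categorical cells: {metrics['n_masked_categorical']}, "
      f"accuracy = {metrics['accuracy_categorical']:.3f}")
print("per-iteration mean absolute change on imputed cells:",
      [f"{c:.4f}" for c in result.per_iteration_change])
# RMSE is in the units of the continuous block (range ~0-2 here); accuracy is
# the fraction of masked category cells restored to their true label. The
# change diagnostic shrinking across passes shows the refinement stabilizing.
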