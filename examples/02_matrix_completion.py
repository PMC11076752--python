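"""Low-rank matrix completion of masked cells.

Builds a noiseless rank-3 non-negative matrix, masks a few cells (pre-filled
with column means), and runs the NMF completion loop. The masked-cell RMSE
shows how much low-rank structure improves on the mean fill.
"""

import numpy as np

from boostfill import FactorizationConfig, transform

rng = np.random.default_rng(0)
M = rng.uniform(0.1, 1.0, (60, 3)) @ rng.uniform(0.1, 1.0, (3, 12))

mask = rng.uniform(size=M.shape) < 0.1
filled = M.copy()
filled[mask] = np.take(M.mean(axis=0), np.nonzero(mask)[1])  # column-mean start

result = transform(filled, mask, FactorizationConfig(rank=3, max_outer_iters=30, tol=1e-8))

rmse_before = np.sqrt(np.mean((filled[mask] - M[mask]) ** 2))
rmse_after = np.sqrt(np.mean((result.transformed[mask] - M[mask]) ** 2))
print(f"method: {result.method_used}, rank {result.rank_used}, "
      f"{result.n_outer_iters} outer iterations")
print(f"masked-cell RMSE: mean fill {rmse_before:.4f} -> completed {rmse_after:.6f}")
print("observed cells untouched:", np.array_equal(result.transformed[~mask], M[~mask]))
# The completion drives the masked-cell error to ~0 on exactly low-rank data,
# while nan_only mode leaves every observed cell bit-identical.
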