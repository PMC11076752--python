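import numpy as np
import pandas as pd
import pytest

import boostfill as bf


@pytest.fixture
def toy_raw() -> pd.DataFrame:
    """Small mixed-type table with missing-token spellings and a mixed column."""
    return pd.DataFrame(
        {
            "height": ["1.5", "2.0", "NA", "2.5", "3.0", "1.0"],
            "group": ["b", "a", "b", "#DIV/0!", "a", "b"],
            "flag": ["True", "False", "True", "True", "False", "  "],
            "mixed": ["1", "x", "2", "y", "3", "z"],  # 50/50 -> excluded
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample"),
    )


@pytest.fixture
def rank2_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fully observed rank-2 synthetic mixed table with its ground truth."""
    spec = bf.SyntheticSpec(
        n_rows=120, n_cont=8, n_cat=2, n_bool=1, latent_rank=2, noise_sd=0.0, seed=42
    )
    return bf.generate_synthetic(spec)


def rank1_completion_case(shape=(8, 6), masked=(3, 2), negative=False, seed=0):
    """Positive (or shifted-negative) rank-1 matrix with one masked cell,
    pre-filled with the column mean of the remaining entries."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(1.0, 3.0, shape[0]) + (-2.0 if negative else 0.0)
    v = rng.uniform(1.0, 3.0, shape[1])
    M = np.outer(u, v)
    mask = np.zeros(shape, dtype=bool)
    mask[masked] = True
    filled = M.copy()
    i, j = masked
    filled[i, j] = np.delete(M[:, j], i).mean()
    return M, filled, mask
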