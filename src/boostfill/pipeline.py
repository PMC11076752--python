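"""End-to-end imputation driver.

``run`` chains the stages: preprocessing, adaptive matrix-factorization
completion, then 1–9 passes of per-column boosted imputation.  Within a
pass, columns are visited in ascending order of missing count and updated
in place (Gauss–Seidel style), so later columns in the same pass already
see the fresh imputations of earlier ones.  Hyperparameters tuned in the
first pass are cached and reused in later passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factorization import FactorizationConfig, transform
from .imputer import ColumnImputationRecord, impute_column, MIN_MODELS, MAX_MODELS
from .preprocessing import preprocess

logger = logging.getLogger(__name__)

MIN_ITERATIONS, MAX_ITERATIONS = 1, 9


@dataclass
class ImputationConfig:
    """All user-facing knobs of the pipeline.

    impute_zeros: treat numeric zeros as missing.
    pre_impute_strategy: column_mean / knn / mix_type initial fill.
    knn_k: neighbours for knn-based pre-imputation.
    factorization: configuration of the matrix-completion stage.
    n_models: ensemble size per column, 3–9.
    n_iterations: refinement passes, 1–9 (default 3; gains beyond a few
        passes are typically marginal).
    use_tuning: allow hyperparameter search where the dataset-size gate
        permits it; n_trials search trials per column.
    master_seed: single seed governing every stochastic choice.
    """

    impute_zeros: bool = False
    pre_impute_strategy: str = "column_mean"
    knn_k: int = 5
    factorization: FactorizationConfig = field(default_factory=FactorizationConfig)
    n_models: int = 3
    n_iterations: int = 3
    use_tuning: bool = False
    n_trials: int = 20
    master_seed: int = 0


@dataclass
class ImputationResult:
    imputed_clean: pd.DataFrame
    imputed_encoded: pd.DataFrame
    records: dict[str, ColumnImputationRecord]
    per_iteration_change: list[float]
    excluded_columns: list[str]
    profiles: dict = field(default_factory=dict)
    config: ImputationConfig | None = None


def validate_config(config: ImputationConfig) -> ImputationConfig:
    """Reject out-of-range settings with messages naming the field."""
    if not MIN_MODELS <= config.n_models <= MAX_MODELS:
        raise ValueError(
            f"n_models must be in [{MIN_MODELS}, {MAX_MODELS}], got {config.n_models}"
        )
    if not MIN_ITERATIONS <= config.n_iterations <= MAX_ITERATIONS:
        raise ValueError(
            f"n_iterations must be in [{MIN_ITERATIONS}, {MAX_ITERATIONS}], "
            f"got {config.n_iterations}"
        )
    if config.pre_impute_strategy not in ("column_mean", "knn", "mix_type"):
        raise ValueError(
            "pre_impute_strategy must be one of column_mean/knn/mix_type, "
            f"got {config.pre_impute_strategy!r}"
        )
    if config.knn_k < 1:
        raise ValueError(f"knn_k must be >= 1, got {config.knn_k}")
    if config.n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {config.n_trials}")
    config.factorization.__post_init__()  # re-check nested ranges
    return config


def run(raw: pd.DataFrame, config: ImputationConfig | None = None) -> ImputationResult:
    """Impute every missing typed cell of ``raw`` and return the result tables."""
    if config is None:
        config = ImputationConfig()
    validate_config(config)
    config.factorization.seed = config.master_seed

    prep = preprocess(raw, config)
    typed = prep.typed_columns
    clean = prep.clean.copy()
    encoded = prep.encoded.copy()

    missing_columns = [c for c in typed if prep.profiles[c].missing_mask.any()]
    if not typed or not missing_columns:
        if not typed:
            logger.warning("no typed columns; returning input unchanged")
        return ImputationResult(
            imputed_clean=clean,
            imputed_encoded=encoded,
            records={},
            per_iteration_change=[0.0] * config.n_iterations,
            excluded_columns=prep.excluded_columns,
            profiles=prep.profiles,
            config=config,
        )

    pre_matrix = prep.pre_imputed[typed].to_numpy(dtype=float)
    mask = np.column_stack([prep.profiles[c].missing_mask for c in typed])
    fact = transform(pre_matrix, mask, config.factorization)
    working = fact.transformed.copy()
    if config.factorization.mode == "full":
        # prediction features may be denoised, but observed target values
        # (and the final outputs) always stay verbatim
        working[~mask] = pre_matrix[~mask]

    # easiest columns first: ascending missing count, ties by column order
    order = sorted(
        missing_columns, key=lambda c: (int(prep.profiles[c].missing_mask.sum()),)
    )

    records: dict[str, ColumnImputationRecord] = {}
    params_cache: dict = {}
    per_iteration_change: list[float] = []
    prev_filled = {
        c: working[:, typed.index(c)][prep.profiles[c].missing_mask].copy()
        for c in missing_columns
    }
    for _iteration in range(config.n_iterations):
        for col in order:
            record = impute_column(
                col, clean, encoded, working, typed, prep.profiles, config, params_cache
            )
            if record is not None:
                records[col] = record
            else:  # pragma: no cover - order only holds columns with missing cells
                continue
            if record.fallback_reason is not None:
                pos = typed.index(col)
                miss = prep.profiles[col].missing_mask
                fills = prep.pre_imputed[col].to_numpy(dtype=float)[miss]
                vals = encoded[col].to_numpy(dtype=float)
                vals[miss] = fills
                encoded[col] = vals
                working[miss, pos] = fills
                if prep.profiles[col].inferred_type == "categorical":
                    from .preprocessing import decode_categorical

                    clean[col] = decode_categorical(vals, prep.profiles[col])
                else:
                    clean[col] = vals
        changes = []
        for col in missing_columns:
            miss = prep.profiles[col].missing_mask
            now = working[:, typed.index(col)][miss]
            changes.append(np.abs(now - prev_filled[col]))
            prev_filled[col] = now.copy()
        all_changes = np.concatenate(changes) if changes else np.array([0.0])
        per_iteration_change.append(float(np.mean(all_changes)))

    return ImputationResult(
        imputed_clean=clean,
        imputed_encoded=encoded,
        records=records,
        per_iteration_change=per_iteration_change,
        excluded_columns=prep.excluded_columns,
        profiles=prep.profiles,
        config=config,
    )
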