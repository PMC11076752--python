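"""Rule-based preprocessing of mixed-type tables.

Raw cells arrive as arbitrary text/number soup. This module normalizes the
common spreadsheet missing-value spellings to NaN, optionally treats zeros
as missing, infers a per-column type by a strict 60% majority vote over the
non-missing cells, label-encodes categoricals, and produces the three
canonical tables the rest of the pipeline consumes: a *clean* table (original
value space), an *encoded* table (categories as integer codes, NaN retained),
and a *pre-imputed* encoded table (every typed cell filled by a cheap
strategy so downstream matrix methods have a complete matrix to start from).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed set of tokens treated as missing after whitespace stripping.
#: Empty and whitespace-only cells are also missing.
MISSING_TOKEN_ALIASES = frozenset(
    {"NaN", "NAN", "Nan", "nan", "NA", "#NA", "N/A", "NA#", "#VALUE!", "#DIV/0!"}
)

#: Boolean spellings handled as a two-class categorical.
BOOLEAN_TOKENS = frozenset({"true", "false"})

#: Strict majority threshold for column typing.
TYPE_MAJORITY_FRACTION = 0.60


class ColumnTypingError(ValueError):
    """A typed column cannot be processed (e.g. no observed values)."""


@dataclass
class ColumnProfile:
    """Inferred per-column metadata.

    Attributes
    ----------
    name : column label.
    inferred_type : ``"continuous"``, ``"categorical"`` or ``"excluded"``.
    missing_mask : boolean array, True where the cell is missing after
        normalization and type coercion.
    category_map : category text -> integer code (categorical columns only);
        codes are assigned 0..K-1 in lexicographic order of the category text.
    n_coerced : number of minority-type cells converted to missing.
    """

    name: str
    inferred_type: str
    missing_mask: np.ndarray
    category_map: dict[str, int] | None = None
    n_coerced: int = 0

    @property
    def inverse_map(self) -> dict[int, str]:
        if self.category_map is None:
            raise ValueError(f"column {self.name!r} is not categorical")
        return {v: k for k, v in self.category_map.items()}


@dataclass
class PreprocessResult:
    """The three aligned output tables plus per-column profiles."""

    clean: pd.DataFrame
    encoded: pd.DataFrame
    pre_imputed: pd.DataFrame
    profiles: dict[str, ColumnProfile] = field(default_factory=dict)

    @property
    def typed_columns(self) -> list[str]:
        return [
            c
            for c, p in self.profiles.items()
            if p.inferred_type in ("continuous", "categorical")
        ]

    @property
    def excluded_columns(self) -> list[str]:
        return [c for c, p in self.profiles.items() if p.inferred_type == "excluded"]


def _is_missing_scalar(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _parse_number(value):
    """Return the cell as a finite float, or None if it is not numeric."""
    if isinstance(value, bool):
        return None  # Boolean tokens are categorical, never numbers
    if isinstance(value, (int, float, np.integer, np.floating)):
        v = float(value)
        return v if math.isfinite(v) else None
    if isinstance(value, str):
        try:
            v = float(value.strip())
        except ValueError:
            return None
        return v if math.isfinite(v) else None
    return None


def normalize_missing_tokens(
    table: pd.DataFrame, aliases: frozenset[str] = MISSING_TOKEN_ALIASES
) -> pd.DataFrame:
    """Replace missing-value spellings (``NA``, ``#DIV/0!``, blanks, ...) with NaN.

    Total and idempotent: non-alias cells pass through unchanged.
    """
    out = table.copy()
    for col in out.columns:
        values = out[col].to_numpy(dtype=object, copy=True)
        for i, v in enumerate(values):
            if _is_missing_scalar(v):
                values[i] = np.nan
            elif isinstance(v, str):
                stripped = v.strip()
                if stripped == "" or stripped in aliases:
                    values[i] = np.nan
        out[col] = values
    return out


def zeros_to_missing(table: pd.DataFrame, enabled: bool) -> pd.DataFrame:
    """Optionally convert numeric zeros to NaN (for data where 0 codes 'absent')."""
    if not enabled:
        return table.copy()
    out = table.copy()
    for col in out.columns:
        values = out[col].to_numpy(dtype=object, copy=True)
        for i, v in enumerate(values):
            num = _parse_number(v)
            if num is not None and num == 0.0:
                values[i] = np.nan
        out[col] = values
    return out


def classify_column(name: str, values: np.ndarray) -> tuple[ColumnProfile, np.ndarray]:
    """Type a column by strict >60% majority over its non-missing cells.

    Returns the profile and the cleaned cell array (minority cells coerced to
    NaN; continuous cells parsed to float, categorical cells to str).
    Boolean tokens count toward the categorical fraction. A column where
    neither kind exceeds 60% — or with no observed cell at all — is excluded
    and passed through untouched.
    """
    values = np.asarray(values, dtype=object)
    observed_idx = [i for i, v in enumerate(values) if not _is_missing_scalar(v)]
    missing_mask = np.ones(len(values), dtype=bool)
    missing_mask[observed_idx] = False

    if not observed_idx:
        logger.warning("column %r has no observed values; excluded", name)
        return ColumnProfile(name, "excluded", missing_mask), values.copy()

    numeric = {i: _parse_number(values[i]) for i in observed_idx}
    n_obs = len(observed_idx)
    n_num = sum(1 for i in observed_idx if numeric[i] is not None)
    p_num = n_num / n_obs
    p_cat = (n_obs - n_num) / n_obs

    cleaned = values.copy()
    if p_num > TYPE_MAJORITY_FRACTION:
        n_coerced = 0
        for i in observed_idx:
            if numeric[i] is None:
                cleaned[i] = np.nan
                missing_mask[i] = True
                n_coerced += 1
            else:
                cleaned[i] = numeric[i]
        return ColumnProfile(name, "continuous", missing_mask, n_coerced=n_coerced), cleaned
    if p_cat > TYPE_MAJORITY_FRACTION:
        n_coerced = 0
        for i in observed_idx:
            if numeric[i] is not None:
                cleaned[i] = np.nan
                missing_mask[i] = True
                n_coerced += 1
            else:
                cleaned[i] = str(values[i]).strip()
        return ColumnProfile(name, "categorical", missing_mask, n_coerced=n_coerced), cleaned
    logger.info(
        "column %r is %.0f%% numeric / %.0f%% categorical; excluded from imputation",
        name,
        100 * p_num,
        100 * p_cat,
    )
    return ColumnProfile(name, "excluded", missing_mask), values.copy()


def encode_categorical(column: np.ndarray, profile: ColumnProfile) -> np.ndarray:
    """Label-encode a categorical column; codes follow lexicographic text order."""
    if profile.inferred_type != "categorical":
        raise ValueError(f"column {profile.name!r} is not categorical")
    observed = sorted({str(v) for v in column if not _is_missing_scalar(v)})
    profile.category_map = {cat: code for code, cat in enumerate(observed)}
    out = np.empty(len(column), dtype=object)
    for i, v in enumerate(column):
        out[i] = np.nan if _is_missing_scalar(v) else float(profile.category_map[str(v)])
    return out


def decode_categorical(codes: np.ndarray, profile: ColumnProfile) -> np.ndarray:
    """Exact inverse of :func:`encode_categorical` on observed cells."""
    inverse = profile.inverse_map
    out = np.empty(len(codes), dtype=object)
    for i, v in enumerate(codes):
        if _is_missing_scalar(v):
            out[i] = np.nan
            continue
        code = int(round(float(v)))
        if code not in inverse:
            raise KeyError(
                f"column {profile.name!r}: code {v!r} has no known category"
            )
        out[i] = inverse[code]
    return out


def _mode_code(values: np.ndarray) -> float:
    """Most frequent code; ties broken toward the smallest code."""
    codes, counts = np.unique(values, return_counts=True)
    return float(codes[np.argmax(counts)])  # np.unique sorts, argmax takes first max


def pre_impute(
    encoded: pd.DataFrame,
    profiles: dict[str, ColumnProfile],
    strategy: str = "column_mean",
    k: int = 5,
) -> pd.DataFrame:
    """Fill every missing typed cell with a cheap baseline value.

    ``column_mean``: continuous -> column mean, categorical -> modal code.
    ``knn``: both kinds filled from the k nearest rows, with distances taken
    over all typed columns of the mean/mode-filled, per-column min-max-scaled
    matrix (continuous fill = neighbour mean, categorical = neighbour
    majority code).  ``mix_type``: continuous via column mean, categorical via
    knn.  Excluded columns are untouched.
    """
    if strategy not in ("column_mean", "knn", "mix_type"):
        raise ValueError(f"unknown pre-imputation strategy {strategy!r}")
    if strategy in ("knn", "mix_type") and k < 1:
        raise ValueError("k must be >= 1 for knn-based pre-imputation")

    typed = [c for c in encoded.columns if profiles[c].inferred_type != "excluded"]
    out = encoded.copy()

    # mean/mode fill is both the column_mean answer and the knn distance space
    filled = {}
    for col in typed:
        vals = out[col].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size == 0:
            raise ColumnTypingError(f"column {col!r} has no observed values to fill from")
        fill = obs.mean() if profiles[col].inferred_type == "continuous" else _mode_code(obs)
        filled[col] = np.where(np.isnan(vals), fill, vals)

    if strategy == "column_mean":
        for col in typed:
            out[col] = filled[col]
        return out

    # scaled distance matrix over typed columns
    X = np.column_stack([filled[c] for c in typed])
    mins, maxs = X.min(axis=0), X.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    Xs = (X - mins) / span
    d2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)

    for j, col in enumerate(typed):
        kind = profiles[col].inferred_type
        if strategy == "mix_type" and kind == "continuous":
            out[col] = filled[col]
            continue
        vals = out[col].to_numpy(dtype=float)
        miss_rows = np.flatnonzero(np.isnan(vals))
        if miss_rows.size == 0:
            out[col] = vals
            continue
        donor_rows = np.flatnonzero(~np.isnan(vals))
        new_vals = vals.copy()
        for i in miss_rows:
            order = donor_rows[np.argsort(d2[i, donor_rows], kind="stable")]
            neighbours = order[: min(k, order.size)]
            nvals = vals[neighbours]
            if kind == "continuous":
                new_vals[i] = nvals.mean()
            else:
                new_vals[i] = _mode_code(nvals)
        out[col] = new_vals
    return out


def preprocess(raw: pd.DataFrame, config=None) -> PreprocessResult:
    """Run the full preprocessing chain and return the three aligned tables.

    Composition: missing-token normalization -> optional zero conversion ->
    per-column typing and coercion -> label encoding -> pre-imputation.
    Usable standalone, independent of the imputation pipeline.
    """
    if raw.empty:
        raise ValueError("input table is empty")
    if config is None:
        from .pipeline import ImputationConfig

        config = ImputationConfig()

    table = normalize_missing_tokens(raw)
    table = zeros_to_missing(table, config.impute_zeros)

    clean = table.copy()
    encoded = table.copy()
    profiles: dict[str, ColumnProfile] = {}
    for col in table.columns:
        profile, cleaned = classify_column(col, table[col].to_numpy(dtype=object))
        profiles[col] = profile
        clean[col] = cleaned
        if profile.inferred_type == "categorical":
            encoded[col] = encode_categorical(cleaned, profile)
        else:
            encoded[col] = cleaned

    pre_imputed = pre_impute(
        encoded, profiles, strategy=config.pre_impute_strategy, k=config.knn_k
    )
    return PreprocessResult(clean=clean, encoded=encoded, pre_imputed=pre_imputed, profiles=profiles)
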