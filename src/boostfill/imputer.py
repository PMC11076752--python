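"""Per-column supervised imputation with gradient-boosted ensembles.

Each column with missing cells is treated as a prediction target: the
(factorization-completed) matrix minus that column supplies the features,
rows observed in the target supply training data, and the missing rows are
predicted by a small ensemble of XGBoost models, each fitted on an
independent 70% row subsample.  A dataset-size gate decides whether
hyperparameters are searched or fixed defaults are used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from xgboost import XGBClassifier, XGBRegressor

logger = logging.getLogger(__name__)

#: Gate thresholds: hyperparameter search runs only on datasets with more
#: than this many samples, at least this sample-to-feature ratio, and at
#: most this many columns containing missing values.
GATE_MIN_SAMPLES = 50
GATE_MIN_RATIO = 4.0
GATE_MAX_MISSING_COLUMNS = 100

#: Fraction of the observed rows each ensemble member trains on.
ENSEMBLE_SUBSAMPLE = 0.70
MIN_MODELS, MAX_MODELS = 3, 9

#: Degenerate-column guards: below these the ensemble is skipped and the
#: pre-imputed fill is kept.
FALLBACK_MIN_ROWS = 10

_SEED_MOD = 2**31 - 1


class FallbackNeeded(RuntimeError):
    """Signal that a column cannot support supervised imputation."""


@dataclass
class GateDecision:
    n_samples: int
    n_features: int
    n_missing_columns: int
    allowed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ModelParams:
    """Hyperparameters of one boosted learner."""

    learning_rate: float = 0.1
    max_depth: int = 6
    n_estimators: int = 300
    internal_subsample: float = 0.8
    colsample: float = 0.8
    min_child_weight: float = 1.0
    l2_regularization: float = 1.0
    objective: str = "squared_error"

    def __post_init__(self):
        for name in ("internal_subsample", "colsample"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class ColumnImputationRecord:
    column: str
    learner: str
    params: ModelParams
    tuned: bool
    n_models: int
    predictions_per_model: np.ndarray | None = None
    fallback_reason: str | None = None


def gate_hyperparameter_search(
    n_samples: int, n_features: int, n_missing_columns: int
) -> GateDecision:
    """Decide whether hyperparameter search may run on this dataset.

    All three conditions must hold: strictly more than 50 samples, a
    sample-to-feature ratio of at least 4, and no more than 100 columns
    containing missing values.
    """
    reasons = []
    if n_samples <= GATE_MIN_SAMPLES:
        reasons.append(f"samples: need > {GATE_MIN_SAMPLES}, got {n_samples}")
    if n_samples / n_features < GATE_MIN_RATIO:
        reasons.append(
            f"ratio: need sample/feature >= {GATE_MIN_RATIO:g}, "
            f"got {n_samples / n_features:.2f}"
        )
    if n_missing_columns > GATE_MAX_MISSING_COLUMNS:
        reasons.append(
            f"missing columns: need <= {GATE_MAX_MISSING_COLUMNS}, got {n_missing_columns}"
        )
    return GateDecision(n_samples, n_features, n_missing_columns, not reasons, reasons)


def select_learner(profile) -> str:
    """Continuous columns get a regressor, categorical (incl. Boolean) a classifier."""
    if profile.inferred_type == "continuous":
        return "regressor"
    if profile.inferred_type == "categorical":
        return "classifier"
    raise ValueError(f"column {profile.name!r} is excluded and never imputed")


def predefined_params(learner: str) -> ModelParams:
    """Fixed defaults used when the gate denies (or the user disables) tuning."""
    objective = "squared_error" if learner == "regressor" else "multiclass_logloss"
    return ModelParams(objective=objective)


def _make_model(learner: str, params: ModelParams, seed: int, n_classes: int = 0):
    common = dict(
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        n_estimators=params.n_estimators,
        subsample=params.internal_subsample,
        colsample_bytree=params.colsample,
        min_child_weight=params.min_child_weight,
        reg_lambda=params.l2_regularization,
        random_state=seed % _SEED_MOD,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    if learner == "regressor":
        return XGBRegressor(objective="reg:squarederror", **common)
    if n_classes > 2:
        return XGBClassifier(objective="multi:softprob", num_class=n_classes, **common)
    return XGBClassifier(objective="binary:logistic", **common)


def _sample_candidate(rng: np.random.Generator, objective: str) -> ModelParams:
    """Draw one point from the tuning search space."""
    return ModelParams(
        learning_rate=float(np.exp(rng.uniform(math.log(0.01), math.log(0.3)))),
        max_depth=int(rng.integers(3, 10)),
        n_estimators=int(rng.integers(100, 601)),
        internal_subsample=float(rng.uniform(0.6, 0.9)),
        colsample=float(rng.uniform(0.5, 1.0)),
        min_child_weight=float(rng.uniform(1.0, 10.0)),
        l2_regularization=float(np.exp(rng.uniform(math.log(1e-3), math.log(10.0)))),
        objective=objective,
    )


def _validation_loss(params, learner, X_tr, y_tr, X_va, y_va, seed, n_classes):
    model = _make_model(learner, params, seed, n_classes)
    model.set_params(early_stopping_rounds=20)
    model.fit(X_tr, y_tr, eval_set=[(X_va, y_va)], verbose=False)
    if learner == "regressor":
        pred = model.predict(X_va)
        return float(np.sqrt(np.mean((pred - y_va) ** 2)))
    proba = model.predict_proba(X_va)
    p = np.clip(proba[np.arange(len(y_va)), y_va.astype(int)], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def tune_params(
    train_features: np.ndarray,
    train_target: np.ndarray,
    learner: str,
    n_trials: int = 20,
    seed: int = 0,
) -> ModelParams:
    """Sequential seeded random search over the boosting hyperparameter space.

    The observed rows are split 80/20 into train/validation (seeded), each
    candidate is fitted with early stopping and scored by validation RMSE
    (regressor) or log-loss (classifier), and the best candidate wins.  The
    predefined defaults are always evaluated as the first trial, so tuning
    can never return a candidate that scores worse than the defaults on the
    validation split.  Deterministic given ``seed``.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_target, dtype=float)
    if len(y) < 20:
        raise ValueError("tuning needs at least 20 training rows")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    n_classes = 0
    if learner == "classifier":
        classes = np.unique(y)
        if classes.size < 2:
            raise FallbackNeeded("single-class target; cannot tune a classifier")
        remap = {c: i for i, c in enumerate(classes)}
        y = np.array([remap[v] for v in y], dtype=float)
        n_classes = classes.size

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    n_va = max(1, int(round(0.2 * len(y))))
    va_idx, tr_idx = perm[:n_va], perm[n_va:]
    if learner == "classifier" and np.unique(y[tr_idx]).size < n_classes:
        # keep every class in the training split; fall back to a stratified-ish fix
        for c in range(n_classes):
            if not np.any(y[tr_idx] == c):
                move = va_idx[y[va_idx] == c][:1]
                tr_idx = np.concatenate([tr_idx, move])
                va_idx = np.setdiff1d(va_idx, move)

    objective = "squared_error" if learner == "regressor" else "multiclass_logloss"
    best_params, best_loss = None, np.inf
    for trial in range(n_trials):
        cand = predefined_params(learner) if trial == 0 else _sample_candidate(rng, objective)
        loss = _validation_loss(
            cand, learner, X[tr_idx], y[tr_idx], X[va_idx], y[va_idx], seed, n_classes
        )
        if loss < best_loss:
            best_params, best_loss = cand, loss
    return best_params


def fit_ensemble_predict(
    features: np.ndarray,
    target_observed: np.ndarray,
    rows_to_predict: np.ndarray,
    params: ModelParams,
    n_models: int,
    seed: int,
    learner: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit ``n_models`` boosted models on independent 70% row subsamples.

    ``features`` is the feature matrix of the observed rows and
    ``rows_to_predict`` the feature matrix of the rows to fill.
    Subsamples are drawn without replacement with seed
    ``seed + model_index``.  Regressors aggregate by the arithmetic mean of
    model predictions; classifiers average class-probability vectors and take
    the argmax, ties resolved toward the smallest class code.

    Returns ``(per_model_predictions, aggregate)`` with per-model predictions
    shaped (n_missing_rows, n_models).
    """
    if not MIN_MODELS <= n_models <= MAX_MODELS:
        raise ValueError(f"n_models must be in [{MIN_MODELS}, {MAX_MODELS}], got {n_models}")
    X_obs = np.asarray(features, dtype=float)
    y_obs = np.asarray(target_observed, dtype=float)
    X_mis = np.asarray(rows_to_predict, dtype=float)
    n_obs = len(y_obs)
    if n_obs < FALLBACK_MIN_ROWS:
        raise FallbackNeeded(f"only {n_obs} observed rows (< {FALLBACK_MIN_ROWS})")

    n_classes = 0
    classes = None
    if learner == "classifier":
        classes = np.unique(y_obs)
        if classes.size < 2:
            raise FallbackNeeded("single observed class")
        remap = {c: i for i, c in enumerate(classes)}
        y_obs = np.array([remap[v] for v in y_obs], dtype=int)
        n_classes = classes.size

    n_sub = max(1, int(round(ENSEMBLE_SUBSAMPLE * n_obs)))
    per_model = np.empty((len(X_mis), n_models), dtype=float)
    proba_sum = np.zeros((len(X_mis), n_classes)) if n_classes else None

    for m in range(n_models):
        rng = np.random.default_rng((seed + m) % _SEED_MOD)
        idx = rng.choice(n_obs, size=n_sub, replace=False)
        if learner == "classifier" and np.unique(y_obs[idx]).size < n_classes:
            # a subsample must still see every class; top up with one row of each absent class
            for c in range(n_classes):
                if not np.any(y_obs[idx] == c):
                    extra = np.flatnonzero(y_obs == c)[:1]
                    idx = np.concatenate([idx, extra])
        model = _make_model(learner, params, (seed + m) % _SEED_MOD, n_classes)
        model.fit(X_obs[idx], y_obs[idx])
        if learner == "regressor":
            per_model[:, m] = model.predict(X_mis)
        else:
            proba = model.predict_proba(X_mis)
            proba_sum += proba
            per_model[:, m] = classes[np.argmax(proba, axis=1)]

    if learner == "regressor":
        aggregate = per_model.mean(axis=1)
    else:
        # argmax on the mean probability vector; np.argmax takes the first
        # (smallest-code) class on exact ties
        aggregate = classes[np.argmax(proba_sum / n_models, axis=1)]
    return per_model, aggregate


def impute_column(
    column_name: str,
    clean,
    encoded,
    transformed: np.ndarray,
    feature_columns: list[str],
    profiles: dict,
    config,
    params_cache: dict,
) -> ColumnImputationRecord | None:
    """Impute one column in place and return its record.

    The target column is dropped from the completed matrix to form the
    feature set; rows observed in the target train the ensemble and missing
    rows are predicted.  Parameters are tuned (when the gate and config
    allow) on first encounter and reused from ``params_cache`` on later
    passes.  Updates ``clean`` (decoded values), ``encoded`` (codes/values)
    and the corresponding column of ``transformed``.
    """
    from .preprocessing import decode_categorical

    profile = profiles[column_name]
    miss = profile.missing_mask
    if not miss.any():
        return None
    learner = select_learner(profile)

    col_pos = feature_columns.index(column_name)
    feat_idx = [i for i in range(len(feature_columns)) if i != col_pos]
    X = transformed[:, feat_idx]
    target = encoded[column_name].to_numpy(dtype=float)
    obs_rows = np.flatnonzero(~miss)
    mis_rows = np.flatnonzero(miss)
    col_seed = (config.master_seed * 1009 + 13 * col_pos) % _SEED_MOD

    def _fallback(reason: str) -> ColumnImputationRecord:
        logger.info("column %r: fallback to pre-imputed values (%s)", column_name, reason)
        return ColumnImputationRecord(
            column=column_name,
            learner=learner,
            params=predefined_params(learner),
            tuned=False,
            n_models=0,
            fallback_reason=reason,
        )

    try:
        if column_name in params_cache:
            params, tuned = params_cache[column_name]
        else:
            n_missing_columns = sum(
                1 for c in feature_columns if profiles[c].missing_mask.any()
            )
            gate = gate_hyperparameter_search(
                transformed.shape[0], len(feat_idx), n_missing_columns
            )
            tuned = bool(config.use_tuning and gate.allowed and len(obs_rows) >= 20)
            if tuned:
                params = tune_params(
                    X[obs_rows],
                    target[obs_rows],
                    learner,
                    n_trials=config.n_trials,
                    seed=col_seed,
                )
                params = replace(
                    params,
                    objective="squared_error" if learner == "regressor" else "multiclass_logloss",
                )
            else:
                params = predefined_params(learner)
            params_cache[column_name] = (params, tuned)

        per_model, aggregate = fit_ensemble_predict(
            X[obs_rows], target[obs_rows], X[mis_rows],
            params, config.n_models, col_seed, learner,
        )
    except FallbackNeeded as exc:
        return _fallback(str(exc))

    new_encoded = target.copy()
    new_encoded[mis_rows] = aggregate
    encoded[column_name] = new_encoded
    transformed[mis_rows, col_pos] = aggregate
    if profile.inferred_type == "categorical":
        clean[column_name] = decode_categorical(new_encoded, profile)
    else:
        clean[column_name] = new_encoded

    return ColumnImputationRecord(
        column=column_name,
        learner=learner,
        params=params,
        tuned=tuned,
        n_models=config.n_models,
        predictions_per_model=per_model,
    )
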