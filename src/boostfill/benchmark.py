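"""Synthetic mixed-type data, MCAR masking, and masked-cell evaluation.

The generator builds tables with the structure the imputer exploits: a
non-negative low-rank continuous block (W·H plus Gaussian noise) and
categorical/Boolean columns derived by quantile-thresholding the latent row
factors, so every column carries mutual signal.  Masking is MCAR — uniform
over eligible (observed) cells — either globally or per column, including
the 1%–25% schedule used for stress-testing imputers.  Scoring computes
RMSE on masked continuous cells and proportion-correct on masked
categorical cells, against the retained ground truth, with column-mean and
knn fills as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import pre_impute, preprocess

_SEED_MOD = 2**31 - 1


@dataclass
class SyntheticSpec:
    """Shape and signal parameters of a synthetic mixed-type table.

    noise_sd is the SD of additive Gaussian noise on the continuous block,
    in the units of that block (its values are O(latent_rank) products of
    uniforms; use ``noise_fraction_of_range`` to set it relative to range).
    """

    n_rows: int = 200
    n_cont: int = 10
    n_cat: int = 3
    n_bool: int = 1
    latent_rank: int = 3
    noise_sd: float = 0.0
    n_classes: int = 3
    seed: int = 0


@dataclass
class MaskingSpec:
    fractions: list[float] = field(default_factory=lambda: [0.1, 0.2, 0.3, 0.4])
    scope: str = "global"
    seed: int = 0


@dataclass
class BenchmarkResult:
    """Per-missingness-level metrics for the pipeline and baselines."""

    entries: pd.DataFrame  # tidy: fraction, method, metric, value

    def to_csv(self, path):
        self.entries.to_csv(path, index=False)


def generate_synthetic(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return ``(table, ground_truth)`` — identical here; truth is kept for scoring.

    Continuous columns ``x0..`` are a non-negative rank-``latent_rank``
    product W·H plus noise (clipped at 0 so the NMF route applies);
    categorical columns ``cat0..`` take class labels ``c0..c{K-1}`` from
    quantile bins of a latent factor; Boolean columns ``flag0..`` threshold
    a latent factor at its median.
    """
    if spec.latent_rank > min(spec.n_rows, spec.n_cont):
        raise ValueError(
            f"latent_rank {spec.latent_rank} exceeds min(n_rows, n_cont)"
        )
    rng = np.random.default_rng(spec.seed)
    W = rng.uniform(0.1, 1.0, size=(spec.n_rows, spec.latent_rank))
    H = rng.uniform(0.1, 1.0, size=(spec.latent_rank, spec.n_cont))
    cont = W @ H
    if spec.noise_sd > 0:
        cont = np.clip(cont + rng.normal(0.0, spec.noise_sd, size=cont.shape), 0.0, None)

    data: dict[str, np.ndarray] = {}
    for j in range(spec.n_cont):
        data[f"x{j}"] = cont[:, j]
    for j in range(spec.n_cat):
        factor = W[:, j % spec.latent_rank]
        qs = np.quantile(factor, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
        codes = np.searchsorted(qs, factor, side="right")
        data[f"cat{j}"] = np.array([f"c{c}" for c in codes], dtype=object)
    for j in range(spec.n_bool):
        factor = W[:, (spec.n_cat + j) % spec.latent_rank]
        data[f"flag{j}"] = np.where(factor > np.median(factor), "True", "False").astype(object)

    index = pd.Index([f"s{i}" for i in range(spec.n_rows)], name="sample")
    table = pd.DataFrame(data, index=index)
    return table, table.copy()


def noise_fraction_of_range(spec: SyntheticSpec, fraction: float) -> float:
    """Noise SD equal to ``fraction`` of the noiseless continuous-block range."""
    noiseless = SyntheticSpec(**{**spec.__dict__, "noise_sd": 0.0})
    rng = np.random.default_rng(noiseless.seed)
    W = rng.uniform(0.1, 1.0, size=(spec.n_rows, spec.latent_rank))
    H = rng.uniform(0.1, 1.0, size=(spec.latent_rank, spec.n_cont))
    cont = W @ H
    return float(fraction * (cont.max() - cont.min()))


def mask_mcar(
    table: pd.DataFrame, fraction: float, scope: str = "global", seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask a fraction of observed cells uniformly at random.

    Returns ``(masked_table, mask)`` where ``mask`` is a Boolean frame, True
    at newly masked positions.  The realized count is round(fraction x
    eligible cells), at least 1 when fraction > 0; already-missing cells are
    never targeted.  ``scope="per_column"`` draws the fraction independently
    within each column.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if scope not in ("global", "per_column"):
        raise ValueError(f"scope must be global or per_column, got {scope!r}")
    rng = np.random.default_rng(seed % _SEED_MOD)
    values = table.to_numpy(dtype=object)
    observed = np.ones(values.shape, dtype=bool)
    for (i, j), v in np.ndenumerate(values):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            observed[i, j] = False
    mask = np.zeros(values.shape, dtype=bool)

    def _pick(eligible_flat_idx, frac):
        n = int(round(frac * eligible_flat_idx.size))
        if frac > 0:
            n = max(1, n)
        return rng.choice(eligible_flat_idx, size=min(n, eligible_flat_idx.size), replace=False)

    if fraction > 0:
        if scope == "global":
            eligible = np.flatnonzero(observed.ravel())
            chosen = _pick(eligible, fraction)
            mask.ravel()[chosen] = True
        else:
            for j in range(values.shape[1]):
                eligible = np.flatnonzero(observed[:, j])
                if eligible.size == 0:
                    continue
                chosen = _pick(eligible, fraction)
                mask[chosen, j] = True

    for j in range(values.shape[1]):
        if observed[:, j].any() and not (observed[:, j] & ~mask[:, j]).any():
            raise ValueError(
                f"masking fraction {fraction} leaves column {table.columns[j]!r} "
                "with no observed values"
            )

    masked = table.copy()
    masked_values = masked.to_numpy(dtype=object, copy=True)
    masked_values[mask] = np.nan
    out = pd.DataFrame(masked_values, index=table.index, columns=table.columns)
    mask_df = pd.DataFrame(mask, index=table.index, columns=table.columns)
    return out, mask_df


def mask_schedule(
    table: pd.DataFrame, levels_percent: list[int] | None = None, seed: int = 0
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Apply a schedule of MCAR levels (default 1%..25%, one dataset per level).

    Each level gets an independent seed derived from the master seed.
    """
    if levels_percent is None:
        levels_percent = list(range(1, 26))
    out = []
    for i, level in enumerate(levels_percent):
        level_seed = (seed * 10007 + 101 * i + level) % _SEED_MOD
        out.append(mask_mcar(table, level / 100.0, scope="global", seed=level_seed))
    return out


def score(
    imputed: pd.DataFrame,
    truth: pd.DataFrame,
    mask: pd.DataFrame,
    profiles: dict,
    density_export: str | None = None,
) -> dict[str, float]:
    """Masked-cell metrics: continuous RMSE and categorical accuracy.

    Optionally writes a tidy CSV of (column, kind, truth, imputed) pairs at
    masked positions for density plotting.
    """
    if imputed.shape != truth.shape:
        raise ValueError("imputed and truth shapes differ")
    if not mask.to_numpy().any():
        raise ValueError("mask is empty; nothing to score")

    sq_errors: list[float] = []
    cat_hits: list[bool] = []
    rows = []
    for col in truth.columns:
        kind = profiles[col].inferred_type if col in profiles else "excluded"
        if kind == "excluded":
            continue
        m = mask[col].to_numpy(dtype=bool)
        if not m.any():
            continue
        t = truth[col].to_numpy(dtype=object)[m]
        v = imputed[col].to_numpy(dtype=object)[m]
        if kind == "continuous":
            t_f = np.array([float(x) for x in t])
            v_f = np.array([float(x) for x in v])
            sq_errors.extend(((t_f - v_f) ** 2).tolist())
            rows.extend(
                {"column": col, "kind": kind, "truth": a, "imputed": b}
                for a, b in zip(t_f, v_f)
            )
        else:
            hits = [str(a) == str(b) for a, b in zip(t, v)]
            cat_hits.extend(hits)
            rows.extend(
                {"column": col, "kind": kind, "truth": str(a), "imputed": str(b)}
                for a, b in zip(t, v)
            )
    if density_export is not None:
        pd.DataFrame(rows).to_csv(density_export, index=False)

    return {
        "rmse_continuous": float(np.sqrt(np.mean(sq_errors))) if sq_errors else float("nan"),
        "accuracy_categorical": float(np.mean(cat_hits)) if cat_hits else float("nan"),
        "n_masked_continuous": len(sq_errors),
        "n_masked_categorical": len(cat_hits),
    }


def _baseline_impute(masked: pd.DataFrame, strategy: str, knn_k: int = 5) -> pd.DataFrame:
    """Decode-aware baseline: preprocess, pre-impute, decode back to text."""
    from .preprocessing import decode_categorical

    prep = preprocess(masked)
    filled = pre_impute(prep.encoded, prep.profiles, strategy=strategy, k=knn_k)
    out = prep.clean.copy()
    for col in out.columns:
        p = prep.profiles[col]
        if p.inferred_type == "continuous":
            out[col] = filled[col].to_numpy(dtype=float)
        elif p.inferred_type == "categorical":
            out[col] = decode_categorical(filled[col].to_numpy(dtype=float), p)
    return out


def run_benchmark(
    spec: SyntheticSpec,
    masking: MaskingSpec,
    config=None,
    baselines: tuple[str, ...] = ("column_mean", "knn"),
) -> BenchmarkResult:
    """Mask a synthetic table at each level, impute, and score against truth."""
    from .pipeline import ImputationConfig, run

    table, truth = generate_synthetic(spec)
    records = []
    for i, frac in enumerate(masking.fractions):
        level_seed = (masking.seed * 7919 + i) % _SEED_MOD
        masked, mask = mask_mcar(table, frac, scope=masking.scope, seed=level_seed)
        if config is None:
            config = ImputationConfig()
        config.master_seed = (masking.seed + i) % _SEED_MOD
        result = run(masked, config)
        metrics = score(result.imputed_clean, truth, mask, result.profiles)
        for metric in ("rmse_continuous", "accuracy_categorical"):
            records.append(
                {"fraction": frac, "method": "boostfill", "metric": metric, "value": metrics[metric]}
            )
        for strategy in baselines:
            base = _baseline_impute(masked, strategy, knn_k=config.knn_k)
            bm = score(base, truth, mask, result.profiles)
            for metric in ("rmse_continuous", "accuracy_categorical"):
                records.append(
                    {"fraction": frac, "method": strategy, "metric": metric, "value": bm[metric]}
                )
    return BenchmarkResult(entries=pd.DataFrame.from_records(records))
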