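"""Adaptive low-rank completion of the pre-imputed matrix.

The pre-imputed matrix is complete but its filled cells carry only
column-marginal information.  This module sharpens those fills by an outer
fit–reconstruct–refill loop around a low-rank factorization: fit a rank-r
model to the current matrix, reconstruct, overwrite *only* the originally
missing cells with the reconstruction, and repeat until the refilled cells
stop moving.  NMF is used when every observed value is non-negative (label
codes and most biological measurements are), truncated SVD otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

_EPS = 1e-12


@dataclass
class FactorizationConfig:
    """Knobs of the completion stage.

    method: "auto" picks NMF for non-negative matrices and SVD otherwise;
        "off" disables the stage.
    rank: number of latent components, or "auto" for min(8, n-1, m-1).
    mode: "nan_only" keeps observed cells verbatim and replaces only the
        originally missing ones; "full" returns the low-rank reconstruction
        everywhere (a denoised matrix).
    max_outer_iters / tol: outer-loop budget and relative-change stop on the
        refilled cells.
    subgroup_size: optional width of contiguous column blocks completed
        independently (bounds memory on very wide tables); None = no blocks.
    """

    method: str = "auto"
    rank: int | str = "auto"
    mode: str = "nan_only"
    max_outer_iters: int = 10
    tol: float = 1e-4
    subgroup_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("auto", "nmf", "svd", "off"):
            raise ValueError(f"method must be auto/nmf/svd/off, got {self.method!r}")
        if self.mode not in ("nan_only", "full"):
            raise ValueError(f"mode must be nan_only/full, got {self.mode!r}")
        if self.max_outer_iters < 1:
            raise ValueError("max_outer_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def resolve_rank(self, n_rows: int, n_cols: int) -> int:
        if self.rank == "auto":
            return max(1, min(8, n_rows - 1, n_cols - 1))
        rank = int(self.rank)
        if rank < 1 or rank > min(n_rows, n_cols):
            raise ValueError(
                f"rank {rank} out of range for a {n_rows}x{n_cols} matrix"
            )
        return rank


@dataclass
class FactorizationResult:
    transformed: np.ndarray
    method_used: str
    rank_used: int
    n_outer_iters: int
    final_rel_change: float


def choose_method(matrix: np.ndarray) -> str:
    """NMF iff every observed (non-NaN) value is non-negative, else SVD."""
    observed = matrix[~np.isnan(matrix)]
    if observed.size == 0:
        raise ValueError("matrix has no observed values")
    return "nmf" if np.all(observed >= 0) else "svd"


def _outer_loop(X: np.ndarray, mask: np.ndarray, reconstruct, config) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Shared fit–reconstruct–refill loop; returns (completed, last_recon, iters, rel_change)."""
    X = X.copy()
    recon = X
    rel_change = 0.0
    n_iters = 0
    if not mask.any():
        return X, reconstruct(X), 0, 0.0
    for n_iters in range(1, config.max_outer_iters + 1):
        recon = reconstruct(X)
        old = X[mask]
        new = recon[mask]
        denom = np.linalg.norm(old)
        rel_change = float(np.linalg.norm(new - old) / (denom + _EPS))
        X[mask] = new
        if rel_change < config.tol:
            break
    return X, recon, n_iters, rel_change


def _column_max_scale(X: np.ndarray) -> np.ndarray:
    """Per-column divisors mapping a non-negative matrix into [0, 1].

    Pure rescaling (no shift): a shift gives every column a different affine
    map, which inflates the rank of low-rank inputs and puts values below
    the observed column minimum out of reach of the clipped refill.
    """
    maxs = X.max(axis=0)
    return np.where(maxs > 0, maxs, 1.0)


def iterative_nmf_complete(
    pre_imputed: np.ndarray, missing_mask: np.ndarray, config: FactorizationConfig
) -> FactorizationResult:
    """Complete a non-negative matrix by the NMF outer loop.

    Columns are scaled into [0, 1] by their maximum before factorization (so
    label codes and wide-range continuous columns share scale) and
    inverse-scaled after; refills are clipped at zero.  With
    ``subgroup_size`` set, contiguous column blocks are completed
    independently.
    """
    X = np.asarray(pre_imputed, dtype=float)
    if np.isnan(X).any():
        raise ValueError("pre-imputed matrix must be complete (no NaN)")
    if (X < 0).any():
        raise ValueError("matrix has negative entries; use svd_complete")
    mask = np.asarray(missing_mask, dtype=bool)
    rank = config.resolve_rank(*X.shape)

    block = config.subgroup_size or X.shape[1]
    if block < 1:
        raise ValueError("subgroup_size must be >= 1")
    out = np.empty_like(X)
    total_iters = 0
    last_change = 0.0
    recon_full = np.empty_like(X)
    for start in range(0, X.shape[1], block):
        cols = slice(start, min(start + block, X.shape[1]))
        Xb, Mb = X[:, cols], mask[:, cols]
        r = min(rank, min(Xb.shape))
        span = _column_max_scale(Xb)
        Xs = Xb / span

        model = NMF(
            n_components=r,
            init="nndsvda",
            solver="cd",
            tol=1e-4,
            max_iter=500,
            random_state=config.seed,
        )

        def reconstruct(M):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence warnings at the cap
                W = model.fit_transform(np.clip(M, 0.0, None))
            R = W @ model.components_
            return np.clip(R, 0.0, None)

        comp_s, recon_s, iters, change = _outer_loop(Xs, Mb, reconstruct, config)
        completed = np.clip(comp_s * span, 0.0, None)
        completed[~Mb] = Xb[~Mb]  # observed cells stay bit-exact despite scaling
        out[:, cols] = completed
        recon_full[:, cols] = np.clip(recon_s * span, 0.0, None)
        total_iters = max(total_iters, iters)
        last_change = max(last_change, change)

    transformed = recon_full if config.mode == "full" else out
    return FactorizationResult(transformed, "nmf", rank, total_iters, last_change)


def svd_complete(
    pre_imputed: np.ndarray, missing_mask: np.ndarray, config: FactorizationConfig
) -> FactorizationResult:
    """Complete a real matrix by the truncated-SVD outer loop.

    Columns are mean-centered before each decomposition and un-centered
    after; reconstructions are not clipped.
    """
    X = np.asarray(pre_imputed, dtype=float)
    if np.isnan(X).any():
        raise ValueError("pre-imputed matrix must be complete (no NaN)")
    mask = np.asarray(missing_mask, dtype=bool)
    rank = config.resolve_rank(*X.shape)

    def reconstruct(M):
        mu = M.mean(axis=0)
        U, s, Vt = np.linalg.svd(M - mu, full_matrices=False)
        return (U[:, :rank] * s[:rank]) @ Vt[:rank] + mu

    completed, recon, iters, change = _outer_loop(X, mask, reconstruct, config)
    transformed = recon if config.mode == "full" else completed
    return FactorizationResult(transformed, "svd", rank, iters, change)


def transform(
    pre_imputed: np.ndarray, missing_mask: np.ndarray, config: FactorizationConfig
) -> FactorizationResult:
    """Dispatch on the configured/auto-chosen method and run the completion."""
    X = np.asarray(pre_imputed, dtype=float)
    if config.method == "off":
        return FactorizationResult(X.copy(), "off", 0, 0, 0.0)
    method = config.method
    if method == "auto":
        method = choose_method(X)
    if method == "nmf":
        return iterative_nmf_complete(X, missing_mask, config)
    return svd_complete(X, missing_mask, config)
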