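"""Feedforward ridge-regression response models.

Three variants, differing only in how the design matrix accounts for the
hemodynamic delay between a stimulus feature and the BOLD response:

* ``R-C``   — features convolved with the canonical HRF (T x p design);
* ``R-CTD`` — canonical HRF plus its temporal and dispersion derivatives,
  column-concatenated (T x 3p);
* ``R-F``   — a finite-impulse-response model using the features lagged by
  3, 4, 5 and 6 s, column-concatenated (T x 4p, no lag-0 term).

Coefficients are estimated per voxel by analytically minimising the
L2-penalised least-squares loss; the per-voxel regularisation strength is
chosen on a held-out validation set by Pearson correlation. A single
eigendecomposition of X'X is shared across all grid values and voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hrf import HRFKernel, canonical_hrf, hrf_derivatives, toeplitz_convolve

__all__ = [
    "RidgeDesign",
    "RidgeModel",
    "default_lambda_grid",
    "build_design",
    "ridge_solve",
    "select_lambda",
    "predict_ridge",
    "fit_ridge_model",
]

VARIANTS = ("R-C", "R-CTD", "R-F")
FIR_LAGS = (3, 4, 5, 6)


def default_lambda_grid(n: int = 20) -> np.ndarray:
    """Log-spaced regularisation grid, 1e-3 .. 1e6."""
    return np.logspace(-3, 6, n)


@dataclass(frozen=True)
class RidgeDesign:
    """A design matrix with bookkeeping mapping columns back to features."""

    variant: str
    matrix: np.ndarray
    column_map: tuple[tuple[int, str], ...]  # (feature index, basis-or-lag label)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class RidgeModel:
    """Per-voxel ridge coefficients B (m x d) and regularisation lambda (m)."""

    variant: str
    B: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.B)):
            raise ValueError("non-finite coefficients")
        if np.any(self.lam < 0):
            raise ValueError("lambda must be non-negative")


def _hrf_kernels(sampling_interval: float) -> tuple[HRFKernel, HRFKernel, HRFKernel]:
    canonical = canonical_hrf(sampling_interval)
    temporal, dispersion = hrf_derivatives(canonical)
    return canonical, temporal, dispersion


def build_design(
    feature_blocks: list[np.ndarray],
    variant: str,
    sampling_interval: float = 1.0,
    kernels: tuple[HRFKernel, HRFKernel, HRFKernel] | None = None,
) -> RidgeDesign:
    """Construct the design matrix for one ridge variant.

    ``feature_blocks`` is a list of (T_b x p) matrices; each block is
    convolved / lagged independently (zero history at block starts) and the
    results are stacked over blocks in order.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    blocks = [np.asarray(b, dtype=float) for b in feature_blocks]
    if not blocks or any(b.size == 0 for b in blocks):
        raise ValueError("empty feature blocks")
    p = blocks[0].shape[1]

    if variant in ("R-C", "R-CTD"):
        if kernels is None:
            kernels = _hrf_kernels(sampling_interval)
        use = kernels[:1] if variant == "R-C" else kernels
        labels = ("canonical", "temporal", "dispersion")[: len(use)]
        parts = []
        for b in blocks:
            parts.append(np.concatenate([toeplitz_convolve(k, b) for k in use], axis=1))
        matrix = np.concatenate(parts, axis=0)
        column_map = tuple((j, lab) for lab in labels for j in range(p))
    else:  # R-F
        lag_steps = [int(round(s / sampling_interval)) for s in FIR_LAGS]
        parts = []
        for b in blocks:
            lagged = []
            for L in lag_steps:
                shifted = np.zeros_like(b)
                if L < b.shape[0]:
                    shifted[L:] = b[: b.shape[0] - L]
                lagged.append(shifted)
            parts.append(np.concatenate(lagged, axis=1))
        matrix = np.concatenate(parts, axis=0)
        column_map = tuple((j, f"lag{s}") for s in FIR_LAGS for j in range(p))
    return RidgeDesign(variant=variant, matrix=matrix, column_map=column_map)


class _RidgeFactor:
    """Eigendecomposition of X'X, reusable across lambda values and voxels."""

    def __init__(self, X: np.ndarray):
        d = X.shape[1]
        G = X.T @ X
        self.evals, self.evecs = np.linalg.eigh(G)
        self.evals = np.clip(self.evals, 0.0, None)
        self.d = d

    def solve(self, Xty: np.ndarray, lam: float) -> np.ndarray:
        """Return (X'X + lam I)^-1 X'y for one or more right-hand sides."""
        denom = self.evals + lam
        if lam == 0:
            denom = np.where(denom < 1e-12 * max(self.evals.max(), 1.0), np.inf, denom)
        z = self.evecs.T @ Xty
        return self.evecs @ (z / denom[:, None] if Xty.ndim == 2 else z / denom)


def ridge_solve(
    design: RidgeDesign | np.ndarray, Y: np.ndarray, lam: np.ndarray | float
) -> RidgeModel:
    """Per-voxel penalised least squares: B_v = argmin ||y_v - X b||^2 + lam_v ||b||^2.

    One eigendecomposition of X'X is shared across voxels; voxels with equal
    lambda share the same linear solve.
    """
    X = design.matrix if isinstance(design, RidgeDesign) else np.asarray(design, float)
    variant = design.variant if isinstance(design, RidgeDesign) else "R-C"
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and response row counts differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("NaN or inf in inputs")
    m = Y.shape[1]
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (m,)).copy()
    if np.any(lam < 0):
        raise ValueError("lambda must be non-negative")
    factor = _RidgeFactor(X)
    Xty = X.T @ Y
    B = np.empty((m, X.shape[1]))
    for value in np.unique(lam):
        cols = np.where(lam == value)[0]
        B[cols] = factor.solve(Xty[:, cols], float(value)).T
    return RidgeModel(variant=variant, B=B, lam=lam)


def _pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r between two (T x m) arrays; constant columns -> 0."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", A, B) / denom
    return np.where(denom > 0, r, 0.0)


def select_lambda(
    train_design: RidgeDesign,
    train_Y: np.ndarray,
    val_design: RidgeDesign,
    val_Y: np.ndarray,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Pick, per voxel, the grid lambda maximising validation Pearson r.

    Ties favour the larger (more conservative) lambda. A voxel whose
    validation response is constant cannot be scored; it receives the grid
    maximum with a warning.
    """
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    grid = np.sort(grid)
    train_Y = np.atleast_2d(train_Y)
    val_Y = np.atleast_2d(val_Y)
    m = train_Y.shape[1]
    factor = _RidgeFactor(train_design.matrix)
    Xty = train_design.matrix.T @ train_Y
    best_r = np.full(m, -np.inf)
    best_lam = np.full(m, grid[-1])
    constant = val_Y.std(axis=0) < 1e-12
    for lam in grid:
        B = factor.solve(Xty, float(lam))
        r = _pearson_columns(val_design.matrix @ B, val_Y)
        take = r >= best_r  # ties -> larger lambda (grid ascends)
        best_r = np.where(take, r, best_r)
        best_lam = np.where(take, lam, best_lam)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} voxel(s) with constant validation response; "
            "assigned the largest grid lambda",
            stacklevel=2,
        )
        best_lam[constant] = grid[-1]
    return best_lam


def predict_ridge(model: RidgeModel, design: RidgeDesign) -> np.ndarray:
    """Predicted responses: design . B' -> (T x m)."""
    if isinstance(design, RidgeDesign):
        if design.variant != model.variant:
            raise ValueError(f"design variant {design.variant!r} != model {model.variant!r}")
        X = design.matrix
    else:
        X = np.asarray(design, dtype=float)
    if X.shape[1] != model.B.shape[1]:
        raise ValueError("design/model dimension mismatch")
    return X @ model.B.T


def fit_ridge_from_dataset(
    dataset,
    variant: str = "R-C",
    tail_seconds: float = 45.0,
    grid: np.ndarray | None = None,
):
    """Fit one ridge variant on a preprocessed :class:`EncodingDataset`.

    Designs are built on the *full* training blocks and split row-wise at the
    validation cut, so the validation tail keeps its convolution history (the
    tail physically follows the training samples within the block). Returns
    ``(model, test_predictions, test_Y)``.
    """
    si = dataset.sampling_interval
    tail = int(round(tail_seconds / si))
    kernels = _hrf_kernels(si) if variant in ("R-C", "R-CTD") else None
    train_pairs = list(dataset.blocks("train"))
    if not train_pairs:
        raise ValueError("dataset has no training blocks")
    design_full = build_design([fb.values for fb, _ in train_pairs], variant, si, kernels)
    tr_rows, va_rows, tr_Y, va_Y = [], [], [], []
    offset = 0
    for fb, rb in train_pairs:
        T = fb.n_samples
        cut = T - tail
        if cut <= 0:
            raise ValueError(f"block {fb.block_id!r}: validation tail exceeds block length")
        tr_rows.append(design_full.matrix[offset : offset + cut])
        va_rows.append(design_full.matrix[offset + cut : offset + T])
        tr_Y.append(rb.values[:cut])
        va_Y.append(rb.values[cut:])
        offset += T
    train_design = RidgeDesign(variant, np.concatenate(tr_rows), design_full.column_map)
    val_design = RidgeDesign(variant, np.concatenate(va_rows), design_full.column_map)
    lam = select_lambda(
        train_design, np.concatenate(tr_Y), val_design, np.concatenate(va_Y), grid
    )
    model = ridge_solve(train_design, np.concatenate(tr_Y), lam)
    test_pairs = list(dataset.blocks("test"))
    if test_pairs:
        test_design = build_design([fb.values for fb, _ in test_pairs], variant, si, kernels)
        test_pred = predict_ridge(model, test_design)
        test_Y = np.concatenate([rb.values for _, rb in test_pairs])
    else:
        test_pred, test_Y = None, None
    return model, test_pred, test_Y


def fit_ridge_model(
    train_blocks: list[np.ndarray],
    train_Y: np.ndarray,
    val_blocks: list[np.ndarray],
    val_Y: np.ndarray,
    variant: str = "R-C",
    sampling_interval: float = 1.0,
    grid: np.ndarray | None = None,
) -> RidgeModel:
    """Convenience wrapper: build designs, select lambda, refit on train."""
    kernels = _hrf_kernels(sampling_interval) if variant in ("R-C", "R-CTD") else None
    train_design = build_design(train_blocks, variant, sampling_interval, kernels)
    val_design = build_design(val_blocks, variant, sampling_interval, kernels)
    lam = select_lambda(train_design, train_Y, val_design, val_Y, grid)
    return ridge_solve(train_design, train_Y, lam)
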