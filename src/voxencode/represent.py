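"""Analyses of trained-model internals: RDMs across pipeline stages and optimal lags.

A representational dissimilarity matrix (RDM) summarises a stage of the
pipeline — features, layer-1 or layer-2 hidden states, or predicted
responses — by the pairwise correlation distance (1 - Pearson r) between the
activity patterns at every pair of time points. Correlating the upper
triangles of two stages' RDMs measures how much representational geometry
they share.

The optimal-lag analysis asks which part of the stimulus history each hidden
unit tracks: every unit is cross-correlated with every feature at
non-positive lags, the correlations are averaged over features, and the lag
of the maximum is the unit's optimal lag. Units trained on slowly varying
features tend to acquire more negative optimal lags than units trained on
fast ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RDM",
    "LagProfile",
    "compute_rdm",
    "rdm_correlation",
    "average_rdms",
    "optimal_lags",
    "pooled_optimal_lags",
    "lag_ttest",
]

STAGES = ("features", "layer1", "layer2", "predictions")


@dataclass(frozen=True)
class RDM:
    """Correlation-distance dissimilarities (C x C) over time-point conditions."""

    matrix: np.ndarray
    stage: str

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class LagProfile:
    """Per-unit optimal lag (seconds, <= 0) and peak mean cross-correlation."""

    lags: np.ndarray
    peaks: np.ndarray
    searched_window: tuple[float, float]


def compute_rdm(patterns: np.ndarray, stage: str = "features") -> RDM:
    """RDM of a (T x k) pattern matrix: entry (i, j) = 1 - corr(pattern_i, pattern_j).

    Time points with constant patterns have undefined correlations; their
    entries are flagged NaN with a warning.
    """
    P = np.asarray(patterns, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2 or P.shape[1] < 2:
        raise ValueError("need a (T x k) matrix with T >= 2 and k >= 2")
    C = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1)
    flat = norms <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant pattern row(s); their RDM entries are NaN",
            stacklevel=2,
        )
    safe = np.where(flat, 1.0, norms)
    corr = (C @ C.T) / np.outer(safe, safe)
    matrix = 1.0 - np.clip(corr, -1.0, 1.0)
    matrix[flat, :] = np.nan
    matrix[:, flat] = np.nan
    np.fill_diagonal(matrix, 0.0)
    return RDM(matrix=matrix, stage=stage)


def rdm_correlation(rdm_a: RDM, rdm_b: RDM) -> float:
    """Pearson correlation between the strictly-upper-triangular parts of two RDMs."""
    A, B = rdm_a.matrix, rdm_b.matrix
    if A.shape != B.shape:
        raise ValueError("RDMs must have the same number of conditions")
    C = A.shape[0]
    if C < 3:
        raise ValueError("need at least 3 conditions (2+ upper-triangle entries)")
    iu = np.triu_indices(C, k=1)
    a, b = A[iu], B[iu]
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 finite upper-triangle pairs")
    return float(stats.pearsonr(a[keep], b[keep])[0])


def average_rdms(rdms: list[RDM]) -> RDM:
    """Elementwise (NaN-aware) mean of same-stage RDMs, e.g. over dataset groups."""
    if not rdms:
        raise ValueError("no RDMs to average")
    stage = rdms[0].stage
    stack = np.stack([r.matrix for r in rdms])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return RDM(matrix=np.nanmean(stack, axis=0), stage=stage)


def _mean_corr_profile(H, F, max_lag):
    """Mean (over features) cross-correlation per unit at lags -max_lag..0."""
    T = H.shape[0]
    n_lags = max_lag + 1
    profile = np.empty((n_lags, H.shape[1]))
    for k, L in enumerate(range(-max_lag, 1)):
        h_seg = H[-L:] if L < 0 else H
        f_seg = F[: T + L]
        hc = h_seg - h_seg.mean(axis=0)
        fc = f_seg - f_seg.mean(axis=0)
        denom = np.outer(np.linalg.norm(hc, axis=0), np.linalg.norm(fc, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (hc.T @ fc) / denom
        corr[~np.isfinite(corr)] = 0.0
        profile[k] = corr.mean(axis=1)
    return profile


def pooled_optimal_lags(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    max_lag: int = 20,
    sampling_interval: float = 1.0,
) -> LagProfile:
    """Optimal lags from cross-correlation profiles averaged over blocks.

    ``pairs`` is a list of ``(hidden (T x h), features (T x p))`` blocks for
    the same units. Averaging the mean-correlation profiles across blocks
    before the argmax suppresses the single-block sampling noise that makes
    per-block optimal lags jumpy on short test blocks.
    """
    if not pairs:
        raise ValueError("no blocks supplied")
    profiles = []
    for hidden, features in pairs:
        H = np.asarray(hidden, dtype=float)
        F = np.asarray(features, dtype=float)
        if max_lag >= H.shape[0]:
            raise ValueError("max_lag must be smaller than every block length")
        Hz, _ = _zscore_cols(H)
        Fz, _ = _zscore_cols(F)
        profiles.append(_mean_corr_profile(Hz, Fz, max_lag))
    avg = np.mean(profiles, axis=0)
    lag_values = (np.arange(-max_lag, 1) * sampling_interval).astype(float)
    best = np.argmax(avg, axis=0)
    return LagProfile(
        lags=lag_values[best],
        peaks=avg[best, np.arange(avg.shape[1])],
        searched_window=(float(lag_values[0]), 0.0),
    )


def _zscore_cols(M):
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    flat = sd <= 0
    return np.where(flat, 0.0, M / np.where(flat, 1.0, sd)), flat


def optimal_lags(
    hidden: np.ndarray,
    features: np.ndarray,
    max_lag: int = 30,
    sampling_interval: float = 1.0,
) -> LagProfile:
    """Optimal (most informative) non-positive lag per hidden unit.

    Each unit's z-scored trajectory is correlated with each z-scored feature
    at lags -max_lag..0 (a lag of -L pairs the unit at time t with the
    feature at t - L), the correlations are averaged over features (signed),
    and the unit's optimal lag is the argmax, breaking ties toward the
    earliest (most negative) lag. Constant units are flagged with NaN.
    """
    H = np.asarray(hidden, dtype=float)
    F = np.asarray(features, dtype=float)
    if H.ndim != 2 or F.ndim != 2 or H.shape[0] != F.shape[0]:
        raise ValueError("hidden and features must share the time axis")
    T = H.shape[0]
    if max_lag >= T:
        raise ValueError("max_lag must be smaller than the sequence length")
    Hz, h_flat = _zscore_cols(H)
    Fz, _ = _zscore_cols(F)
    if h_flat.any():
        warnings.warn(f"{int(h_flat.sum())} constant hidden unit(s) flagged", stacklevel=2)
    mean_corr = _mean_corr_profile(Hz, Fz, max_lag)
    best = np.argmax(mean_corr, axis=0)  # first (most negative lag) wins ties
    lag_values = (np.arange(-max_lag, 1) * sampling_interval).astype(float)
    lags = lag_values[best]
    peaks = mean_corr[best, np.arange(H.shape[1])]
    lags = np.where(h_flat, np.nan, lags)
    peaks = np.where(h_flat, np.nan, peaks)
    return LagProfile(lags=lags, peaks=peaks, searched_window=(float(lag_values[0]), 0.0))


def lag_ttest(lags_a: np.ndarray, lags_b: np.ndarray):
    """Unpaired two-sample t-test comparing mean optimal lags of two models."""
    a = np.asarray(lags_a, dtype=float)
    b = np.asarray(lags_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    return stats.ttest_ind(a, b)
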