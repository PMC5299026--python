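"""Statistical evaluation of response models.

Performance is the cross-validated Pearson correlation between observed and
predicted test responses, aggregated over a voxel group by the median. Four
inferential tools accompany it:

* a Monte-Carlo *noise ceiling* per voxel, estimated from repeated test
  measurements: the median correlation between a Gaussian signal (variance =
  data variance minus noise variance) and that signal plus Gaussian noise
  (variance from the repeat standard errors);
* a *permutation test* against chance: responses are permuted over time,
  the model is retrained per permutation, and the p-value is the fraction of
  permutations whose group median meets the observed one;
* a *bootstrap comparison* of two models: voxels are resampled with
  replacement and the difference of group medians gets a percentile CI
  (Bonferroni-corrected across model pairs);
* a *threshold analysis* partitioning voxels by whether two models differ by
  more than a fixed correlation margin.

Medians are used for every group aggregate; means never are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import EncodingDataset, ResponseBlock

__all__ = [
    "voxel_performance",
    "noise_ceiling",
    "ceiling_correct",
    "permutation_test",
    "PermutationResult",
    "bootstrap_compare",
    "BootstrapComparison",
    "threshold_diff_analysis",
    "ThresholdAnalysis",
]


def voxel_performance(predicted: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Pearson r per voxel between predicted and observed (T x m) sequences.

    Constant predictions (or observations) get r = 0 with a warning rather
    than NaN, so downstream medians stay defined.
    """
    P = np.asarray(predicted, dtype=float)
    O = np.asarray(observed, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if O.ndim == 1:
        O = O[:, None]
    if P.shape != O.shape:
        raise ValueError(f"shape mismatch: predicted {P.shape} vs observed {O.shape}")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    Pc = P - P.mean(axis=0)
    Oc = O - O.mean(axis=0)
    denom = np.linalg.norm(Pc, axis=0) * np.linalg.norm(Oc, axis=0)
    flat = denom <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} voxel(s) with constant sequence; r set to 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", Pc, Oc) / denom
    return np.where(flat, 0.0, r)


def noise_ceiling(
    repeats: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    sem_mode: str = "mean_square",
) -> np.ndarray:
    """Monte-Carlo noise ceiling per voxel from a repeat stack (R x T x m).

    For each voxel the noise variance is estimated from the per-time-point
    standard errors of the repeat mean (``sem_mode='mean_square'`` averages
    the squared SEMs over time; ``'variance'`` takes the variance of the
    SEMs, an alternative reading of the same recipe) and the signal variance
    is the variance of the repeat mean minus the noise variance, floored at
    zero. Each simulation draws a Gaussian signal and adds Gaussian noise;
    the ceiling is the median correlation over ``n_sim`` draws. Voxels with
    no signal variance get a ceiling of 0 with a warning.
    """
    repeats = np.asarray(repeats, dtype=float)
    if repeats.ndim == 2:
        repeats = repeats[:, :, None]
    R, T, m = repeats.shape
    if R < 2:
        raise ValueError("need at least 2 repeats")
    if sem_mode not in ("mean_square", "variance"):
        raise ValueError(f"unknown sem_mode {sem_mode!r}")
    mean = repeats.mean(axis=0)
    sem = repeats.std(axis=0, ddof=1) / np.sqrt(R)
    if sem_mode == "mean_square":
        sigma_n2 = (sem**2).mean(axis=0)
    else:
        sigma_n2 = sem.var(axis=0)
    sigma_d2 = mean.var(axis=0)
    sigma_s2 = np.maximum(sigma_d2 - sigma_n2, 0.0)
    dead = sigma_s2 <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} voxel(s) with no signal variance; ceiling set to 0",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    ceilings = np.zeros(m)
    for v in range(m):
        if dead[v]:
            continue
        sig = rng.standard_normal((n_sim, T)) * np.sqrt(sigma_s2[v]) + mean[:, v].mean()
        noise = rng.standard_normal((n_sim, T)) * np.sqrt(sigma_n2[v])
        noisy = sig + noise
        sc = sig - sig.mean(axis=1, keepdims=True)
        nc = noisy - noisy.mean(axis=1, keepdims=True)
        r = np.einsum("ij,ij->i", sc, nc) / (
            np.linalg.norm(sc, axis=1) * np.linalg.norm(nc, axis=1)
        )
        ceilings[v] = np.median(r)
    return ceilings


def ceiling_correct(group_median_r: float, group_median_ceiling: float) -> float:
    """Noise-ceiling-corrected group performance: median r / median ceiling."""
    if group_median_ceiling <= 0:
        warnings.warn("non-positive noise ceiling; corrected value undefined", stacklevel=2)
        return float("nan")
    return group_median_r / group_median_ceiling


def _permute_dataset(dataset: EncodingDataset, rng: np.random.Generator) -> EncodingDataset:
    """Permute response time indices, one shared permutation per role."""
    role_of = {fb.block_id: fb.role for fb in dataset.features}
    by_role: dict[str, list[ResponseBlock]] = {}
    order: dict[str, list[str]] = {}
    for rb in dataset.responses:
        role = role_of[rb.block_id]
        by_role.setdefault(role, []).append(rb)
        order.setdefault(role, []).append(rb.block_id)
    new_blocks: dict[str, ResponseBlock] = {}
    for role, blocks in by_role.items():
        Y = np.concatenate([b.values for b in blocks], axis=0)
        Y = Y[rng.permutation(Y.shape[0])]
        offset = 0
        for b in blocks:
            T = b.values.shape[0]
            new_blocks[b.block_id] = ResponseBlock(
                values=Y[offset : offset + T], block_id=b.block_id
            )
            offset += T
    return EncodingDataset(
        features=dataset.features,
        responses=[new_blocks[b.block_id] for b in dataset.responses],
        voxel_groups=dataset.voxel_groups,
        sampling_interval=dataset.sampling_interval,
    )


@dataclass(frozen=True)
class PermutationResult:
    """Per-group permutation p-values with Bonferroni significance calls."""

    observed_median: dict[str, float]
    p: dict[str, float]
    label: dict[str, str]  # "<1/n" when no permutation reached the observed value
    significant: dict[str, bool]
    n_perm: int
    alpha: float


def permutation_test(
    fit_score,
    dataset: EncodingDataset,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationResult:
    """Compare a retrainable model against chance by permuting responses over time.

    ``fit_score(dataset) -> per-voxel r`` must retrain the model from scratch
    on the (permuted) dataset and score it on the test blocks. One time-index
    permutation is shared across voxels and applied within the train-role and
    test-role blocks separately. The p-value per voxel group is the fraction
    of permutations whose group median meets or exceeds the observed one;
    zero counts are labelled ``"<1/n_perm"``. Significance uses a Bonferroni
    correction over groups. With autocorrelated responses this index-wise
    permutation is anticonservative; it matches the evaluated protocol.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    groups = dataset.group_indices()
    observed = np.asarray(fit_score(dataset), dtype=float)
    obs_median = {g: float(np.median(observed[ix])) for g, ix in groups.items()}
    rng = np.random.default_rng(seed)
    exceed = {g: 0 for g in groups}
    for _ in range(n_perm):
        permuted = _permute_dataset(dataset, rng)
        r = np.asarray(fit_score(permuted), dtype=float)
        for g, ix in groups.items():
            if np.median(r[ix]) >= obs_median[g]:
                exceed[g] += 1
    p = {g: exceed[g] / n_perm for g in groups}
    label = {g: (f"<1/{n_perm}" if exceed[g] == 0 else f"{p[g]:.4g}") for g in groups}
    corrected = alpha / len(groups)
    significant = {g: p[g] < corrected for g in groups}
    return PermutationResult(obs_median, p, label, significant, n_perm, alpha)


@dataclass(frozen=True)
class BootstrapComparison:
    """Difference of group medians with a bootstrap percentile CI."""

    delta_median: float
    ci_low: float
    ci_high: float
    significant: bool
    n_boot: int
    level: float  # the Bonferroni-corrected CI level actually used


def bootstrap_compare(
    perf_a: np.ndarray,
    perf_b: np.ndarray,
    n_boot: int = 10000,
    alpha: float = 0.05,
    n_models: int = 1,
    seed: int = 0,
) -> BootstrapComparison:
    """Bootstrap the difference of medians between two matched performance vectors.

    Voxels are resampled with replacement ``n_boot`` times; the statistic is
    ``median(a) - median(b)`` over the resampled voxels. The percentile CI is
    taken at level ``1 - alpha / n_models`` (Bonferroni over the number of
    model comparisons) and the difference is significant when the CI excludes
    zero.
    """
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("performance vectors must be matched over voxels")
    if a.size < 2:
        raise ValueError("need at least 2 voxels")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    stats_ = np.median(a[idx], axis=1) - np.median(b[idx], axis=1)
    corrected = alpha / n_models
    lo, hi = np.quantile(stats_, [corrected / 2, 1 - corrected / 2])
    delta = float(np.median(a) - np.median(b))
    significant = bool(lo > 0 or hi < 0)
    return BootstrapComparison(delta, float(lo), float(hi), significant, n_boot, 1 - corrected)


@dataclass(frozen=True)
class ThresholdAnalysis:
    """Partition of voxels by whether two models differ by more than a margin."""

    fraction_differing: float
    fraction_favoring_a: float  # among the differing voxels
    delta_median_a: float  # median |difference| where a wins
    delta_median_b: float  # median |difference| where b wins
    n_differing: int


def threshold_diff_analysis(
    perf_a: np.ndarray, perf_b: np.ndarray, threshold: float = 0.1
) -> ThresholdAnalysis:
    """Describe where two models' per-voxel performance differs by more than ``threshold``."""
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("performance vectors must be matched over voxels")
    diff = a - b
    differing = np.abs(diff) > threshold
    n_diff = int(differing.sum())
    if n_diff == 0:
        return ThresholdAnalysis(0.0, 0.0, float("nan"), float("nan"), 0)
    favor_a = differing & (diff > 0)
    favor_b = differing & (diff < 0)
    med = lambda mask: float(np.median(np.abs(diff[mask]))) if mask.any() else float("nan")
    return ThresholdAnalysis(
        fraction_differing=n_diff / a.size,
        fraction_favoring_a=float(favor_a.sum()) / n_diff,
        delta_median_a=med(favor_a),
        delta_median_b=med(favor_b),
        n_differing=n_diff,
    )
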