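"""Ground-truth synthetic datasets emulating a continuous movie-watching experiment.

The generator mirrors the block structure of a public movie-watching study:
twelve 600 s training blocks and nine 60 s test blocks whose stimulus is
repeated (R = 10) to support noise-ceiling estimation, with the first 6 s of
every block discarded and the last 45 s of each training block reserved for
validation. A ``scale`` factor shrinks block lengths for desk-scale runs.

Features are stationary AR(1) sequences whose time constant controls how
persistent they are — slow sequences stand in for semantic-like descriptors,
fast ones for structural ones. Each voxel response is a sparse linear
combination of the features, optionally passed through a saturating
nonlinearity, convolved with a voxel-specific gamma-difference HRF whose
response delay is drawn from a configured range, plus white Gaussian noise
calibrated to a target SNR. Every quantity needed to verify recovery (weights,
kernels, delays, noise levels) is returned as :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import EncodingDataset, FeatureBlock, ResponseBlock, preprocess
from .hrf import HRFKernel, HRFParams, canonical_hrf, toeplitz_convolve

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_features",
    "generate_voxels",
    "generate_responses",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Block structure defaults follow the emulated experiment (12 x 600 s train,
    9 x 60 s test, 10 test repeats, 6 s discard, 45 s validation tails);
    ``scale`` multiplies the training block lengths only. The stimulus
    surrogate is 8-dimensional AR(1) noise with a 1 s time constant (fast,
    structural-like features; voxel HRF differences are only identifiable
    when the stimulus has power at the timescales on which kernels differ);
    voxel response delays are uniform on 4-8 s with undershoots 8-12 s later,
    at SNR 2.
    """

    n_train_blocks: int = 12
    train_block_seconds: float = 600.0
    n_test_blocks: int = 9
    test_block_seconds: float = 60.0
    n_repeats: int = 10
    scale: float = 1.0  # shrinks *training* block length only; test blocks must
    # stay long enough to cover the HRF support, so their length is explicit
    n_features: int = 8
    feature_tau: float = 1.0  # fast, structural-like features; voxel HRF
    # differences are only identifiable when the stimulus has power at the
    # timescales on which the kernels differ
    n_voxels: int = 20
    delay_range: tuple[float, float] = (4.0, 8.0)
    undershoot_offset_range: tuple[float, float] = (8.0, 12.0)
    snr: float = 2.0
    weight_density: float = 0.5
    nonlinearity: str | None = None  # None | "tanh" | "threshold"
    canonical_hrf_only: bool = False  # every voxel uses the canonical kernel
    discard_seconds: float = 6.0
    validation_tail_seconds: float = 45.0
    sampling_interval: float = 1.0
    apply_preprocess: bool = True

    def __post_init__(self):
        train_T = int(round(self.train_block_seconds * self.scale / self.sampling_interval))
        test_T = int(round(self.test_block_seconds / self.sampling_interval))
        if min(self.n_train_blocks, self.n_test_blocks) < 1 or min(train_T, test_T) < 1:
            raise ValueError("inconsistent config: need at least one sample per block")
        if self.apply_preprocess:
            discard = int(round(self.discard_seconds / self.sampling_interval))
            if discard >= test_T or discard >= train_T:
                raise ValueError("inconsistent config: discard exceeds a block length")
            if self.validation_tail_seconds >= (train_T - discard) * self.sampling_interval:
                raise ValueError("inconsistent config: validation tail exceeds a train block")
        if self.n_repeats < 2:
            raise ValueError("inconsistent config: need at least 2 test repeats")
        if self.nonlinearity not in (None, "tanh", "threshold"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    @property
    def train_samples(self) -> int:
        return int(round(self.train_block_seconds * self.scale / self.sampling_interval))

    @property
    def test_samples(self) -> int:
        return int(round(self.test_block_seconds / self.sampling_interval))


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    weights: np.ndarray  # (m x p) sparse linear weights
    hrf_kernels: list[HRFKernel]  # per-voxel sampled kernels (peak-normalised)
    delays_response: np.ndarray  # (m,) seconds, from a dense-grid argmax
    delays_undershoot: np.ndarray  # (m,) seconds
    snr: float
    noise_sd: np.ndarray = field(default=None)  # (m,) filled by generate_responses
    nonlinearity: str | None = None
    seed: int = 0


def generate_features(T: int, p: int, tau: float, seed: int) -> np.ndarray:
    """Stationary AR(1) feature matrix (T x p), z-scored per column.

    The lag-1 autocorrelation is exp(-1/tau) (tau in samples); ``tau = 0``
    yields white noise. Innovations are scaled so the process is unit
    variance before the final per-block z-scoring.
    """
    if T < 1 or p < 1:
        raise ValueError("T and p must be positive")
    if tau < 0 or not np.isfinite(tau):
        raise ValueError(f"invalid time constant {tau!r}")
    rng = np.random.default_rng(seed)
    rho = 0.0 if tau == 0 else float(np.exp(-1.0 / tau))
    eps = rng.standard_normal((T, p))
    out = np.empty((T, p))
    out[0] = eps[0]
    innov = np.sqrt(1.0 - rho**2)
    for t in range(1, T):
        out[t] = rho * out[t - 1] + innov * eps[t]
    out -= out.mean(axis=0)
    sd = out.std(axis=0)
    out /= np.where(sd > 0, sd, 1.0)
    return out


def _dense_delays(params: HRFParams) -> tuple[float, float]:
    """Response/undershoot delays of a kernel from a 1 ms grid evaluation."""
    from .hrf import _double_gamma

    t = np.arange(0.0, params.duration, 1e-3)
    v = _double_gamma(t, params)
    peak = int(np.argmax(v))
    trough = peak + int(np.argmin(v[peak:]))
    return float(t[peak]), float(t[trough])


def generate_voxels(
    m: int,
    p: int,
    delay_range: tuple[float, float] = (4.0, 8.0),
    undershoot_offset_range: tuple[float, float] = (8.0, 12.0),
    snr: float = 2.0,
    weight_density: float = 0.5,
    seed: int = 0,
    sampling_interval: float = 1.0,
    nonlinearity: str | None = None,
) -> GroundTruth:
    """Draw per-voxel weights and gamma-difference HRFs with known delays.

    Response delays are uniform on ``delay_range`` and undershoot delays sit
    ``undershoot_offset_range`` seconds later. The recorded ground-truth
    delays come from a dense (1 ms) evaluation of each kernel, so they are
    exact for the *difference* kernel, not just its positive lobe.
    """
    lo, hi = delay_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi or lo <= 0:
        raise ValueError(f"invalid delay range {delay_range!r}")
    olo, ohi = undershoot_offset_range
    if olo > ohi or olo <= 0:
        raise ValueError(f"invalid undershoot offset range {undershoot_offset_range!r}")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    # nonnegative (half-normal) weights: responses to energy-like features are
    # predominantly positive, and a positive net drive is what makes the
    # all-ones impulse probe read out the kernel with its physiological sign
    weights = np.abs(rng.standard_normal((m, p)))
    mask = rng.random((m, p)) < weight_density
    # guarantee at least one active feature per voxel
    for v in range(m):
        if not mask[v].any():
            mask[v, rng.integers(p)] = True
    weights *= mask
    delays = rng.uniform(lo, hi, m)
    offsets = rng.uniform(olo, ohi, m)
    kernels, d_resp, d_under = [], [], []
    for v in range(m):
        # gamma mode = delay - dispersion, so shift by the (unit) dispersion
        params = HRFParams(
            response_delay=delays[v] + 1.0, undershoot_delay=delays[v] + offsets[v] + 1.0
        )
        kernels.append(canonical_hrf(sampling_interval, params=params))
        dr, du = _dense_delays(params)
        d_resp.append(dr)
        d_under.append(du)
    return GroundTruth(
        weights=weights,
        hrf_kernels=kernels,
        delays_response=np.asarray(d_resp),
        delays_undershoot=np.asarray(d_under),
        snr=snr,
        nonlinearity=nonlinearity,
        seed=seed,
    )


def _drive(F: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Per-voxel neural drive (T x m): linear mix, optional static nonlinearity."""
    u = F @ truth.weights.T
    if truth.nonlinearity == "tanh":
        return np.tanh(u)
    if truth.nonlinearity == "threshold":
        return np.maximum(u, 0.0)
    return u


def generate_responses(
    feature_blocks: dict[str, np.ndarray],
    truth: GroundTruth,
    test_ids: set[str] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, ResponseBlock]:
    """Convolve each voxel's drive with its HRF, add calibrated noise, z-score.

    The noise standard deviation per voxel is the noiseless signal's standard
    deviation (over all blocks) divided by the target SNR, recorded in
    ``truth.noise_sd``. Blocks named in ``test_ids`` get ``n_repeats``
    independent noise realisations around the shared noiseless signal; their
    ``values`` are the repeat mean. All outputs are z-scored per block (the
    same affine map is applied to repeats, preserving the mean structure).
    """
    test_ids = test_ids or set()
    m = truth.weights.shape[0]
    signals = {}
    for bid, F in feature_blocks.items():
        if F.shape[1] != truth.weights.shape[1]:
            raise ValueError(f"block {bid!r}: feature dimension mismatch with ground truth")
        drive = _drive(np.asarray(F, float), truth)
        sig = np.empty_like(drive)
        for v in range(m):
            sig[:, v] = toeplitz_convolve(truth.hrf_kernels[v], drive[:, v])
        signals[bid] = sig
    pooled = np.concatenate(list(signals.values()), axis=0)
    noise_sd = pooled.std(axis=0) / truth.snr
    truth.noise_sd = noise_sd

    rng = np.random.default_rng(seed)
    out = {}
    for bid, sig in signals.items():
        if bid in test_ids:
            reps = sig[None] + rng.standard_normal((n_repeats,) + sig.shape) * noise_sd
            values = reps.mean(axis=0)
            mu, sd = values.mean(axis=0), values.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            out[bid] = ResponseBlock(
                values=(values - mu) / sd, block_id=bid, repeats=(reps - mu) / sd
            )
        else:
            values = sig + rng.standard_normal(sig.shape) * noise_sd
            mu, sd = values.mean(axis=0), values.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            out[bid] = ResponseBlock(values=(values - mu) / sd, block_id=bid)
    return out


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[EncodingDataset, GroundTruth]:
    """Assemble a full synthetic dataset plus its ground truth.

    All randomness flows from ``seed`` through a spawned ``SeedSequence`` per
    component (voxels, one stream per feature block, one for noise), so the
    result is bit-reproducible. When ``config.apply_preprocess`` is set
    (default) the initial-transient discard and per-block z-scoring are
    applied before returning; validation tails are left inside the training
    blocks for the fitting routines to split off.
    """
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    voxel_seed, noise_seed, *block_seeds = ss.generate_state(
        2 + config.n_train_blocks + config.n_test_blocks
    )
    truth = generate_voxels(
        config.n_voxels,
        config.n_features,
        config.delay_range,
        config.undershoot_offset_range,
        config.snr,
        config.weight_density,
        seed=int(voxel_seed),
        sampling_interval=config.sampling_interval,
        nonlinearity=config.nonlinearity,
    )
    if config.canonical_hrf_only:
        canonical = canonical_hrf(config.sampling_interval)
        dr, du = _dense_delays(canonical.params)
        truth.hrf_kernels = [canonical] * config.n_voxels
        truth.delays_response[:] = dr
        truth.delays_undershoot[:] = du
    truth.seed = seed

    feature_blocks: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    k = 0
    for i in range(config.n_train_blocks):
        bid = f"train{i:02d}"
        feature_blocks[bid] = generate_features(
            config.train_samples, config.n_features, config.feature_tau, int(block_seeds[k])
        )
        roles[bid] = "train"
        k += 1
    for i in range(config.n_test_blocks):
        bid = f"test{i:02d}"
        feature_blocks[bid] = generate_features(
            config.test_samples, config.n_features, config.feature_tau, int(block_seeds[k])
        )
        roles[bid] = "test"
        k += 1

    responses = generate_responses(
        feature_blocks,
        truth,
        test_ids={b for b, r in roles.items() if r == "test"},
        n_repeats=config.n_repeats,
        seed=int(noise_seed),
    )
    dataset = EncodingDataset(
        features=[
            FeatureBlock(values=F, block_id=bid, role=roles[bid])
            for bid, F in feature_blocks.items()
        ],
        responses=[responses[bid] for bid in feature_blocks],
        voxel_groups=["all"] * config.n_voxels,
        sampling_interval=config.sampling_interval,
    )
    if config.apply_preprocess:
        dataset = preprocess(dataset, discard_seconds=config.discard_seconds, zscore=True)
    return dataset, truth
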