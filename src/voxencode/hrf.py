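"""Canonical hemodynamic response function, its derivatives, and causal convolution.

The canonical HRF is the standard difference of two gamma densities: a
positive response peaking ~5-6 s after neural activity and a delayed negative
undershoot. Its temporal derivative (sensitivity to onset shifts) and
dispersion derivative (sensitivity to width changes) form the usual
three-function basis for feedforward response models.

Convolution is implemented as multiplication by the causal Toeplitz operator
of the sampled kernel, applied independently within each stimulus block
(zero-padded history at block starts; nothing leaks across block boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["HRFParams", "HRFKernel", "canonical_hrf", "hrf_derivatives", "toeplitz_convolve"]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma parameters (seconds), following the common SPM defaults."""

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    response_undershoot_ratio: float = 6.0
    duration: float = 32.0
    onset: float = 0.0


@dataclass(frozen=True)
class HRFKernel:
    """A causal kernel sampled on the response grid (lags 0..duration)."""

    samples: np.ndarray
    sampling_interval: float
    params: HRFParams | None = None

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("kernel has non-finite samples")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.sampling_interval


def _double_gamma(t: np.ndarray, p: HRFParams) -> np.ndarray:
    """Evaluate the unnormalised double-gamma HRF at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float) - p.onset
    # SPM convention: shape = delay/dispersion, scale = dispersion
    # (the positive lobe then peaks at delay - dispersion, i.e. 5 s by default)
    a1 = p.response_delay / p.response_dispersion
    a2 = p.undershoot_delay / p.undershoot_dispersion
    peak = gamma_dist.pdf(t, a1, scale=p.response_dispersion)
    under = gamma_dist.pdf(t, a2, scale=p.undershoot_dispersion)
    out = peak - under / p.response_undershoot_ratio
    out[t < 0] = 0.0
    return out


def canonical_hrf(
    sampling_interval: float = 1.0,
    duration: float = 32.0,
    params: HRFParams | None = None,
) -> HRFKernel:
    """Sample the canonical double-gamma HRF, peak-normalised to max 1.

    ``params`` defaults to the SPM convention (response delay 6 s, undershoot
    delay 16 s, unit dispersions, response:undershoot ratio 6). Regression
    weights absorb amplitude, so peak normalisation is purely a convention.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = params or HRFParams(duration=duration)
    if p.duration != duration:
        p = replace(p, duration=duration)
    lags = np.arange(0.0, duration + 0.5 * sampling_interval, sampling_interval)
    samples = _double_gamma(lags, p)
    peak = samples.max()
    if peak <= 0:
        raise ValueError("degenerate HRF parameters: non-positive peak")
    return HRFKernel(samples=samples / peak, sampling_interval=sampling_interval, params=p)


def hrf_derivatives(
    kernel: HRFKernel,
    onset_step: float = 1.0,
    dispersion_step: float = 0.01,
) -> tuple[HRFKernel, HRFKernel]:
    """Temporal and dispersion derivatives of a canonical kernel.

    Both are central finite differences of the *unnormalised* double gamma —
    with respect to an onset shift for the temporal derivative and to the
    response dispersion for the dispersion derivative — sampled on the
    kernel's grid and scaled to unit Euclidean norm.
    """
    if kernel.params is None:
        raise ValueError("kernel lacks analytic parameters; cannot differentiate")
    if onset_step <= 0 or dispersion_step <= 0:
        raise ValueError("finite-difference steps must be positive")
    p = kernel.params
    lags = kernel.lags

    plus = _double_gamma(lags, replace(p, onset=p.onset + onset_step / 2))
    minus = _double_gamma(lags, replace(p, onset=p.onset - onset_step / 2))
    temporal = (minus - plus) / onset_step  # d/d(peak time): later peak = positive onset

    dplus = _double_gamma(lags, replace(p, response_dispersion=p.response_dispersion + dispersion_step / 2))
    dminus = _double_gamma(lags, replace(p, response_dispersion=p.response_dispersion - dispersion_step / 2))
    dispersion = (dplus - dminus) / dispersion_step

    def _unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero derivative kernel")
        return v / n

    si = kernel.sampling_interval
    return (
        HRFKernel(samples=_unit(temporal), sampling_interval=si),
        HRFKernel(samples=_unit(dispersion), sampling_interval=si),
    )


def toeplitz_convolve(kernel: HRFKernel, F: np.ndarray) -> np.ndarray:
    """Causal convolution of each column of ``F`` (T x p) with the kernel.

    out[t] = sum_{tau=0..min(t, L)} kernel[tau] * F[t - tau], i.e. the product
    of the lower-triangular Toeplitz matrix of the kernel with the signal.
    History before the first row is treated as zero; callers convolve each
    block separately so nothing crosses block boundaries.
    """
    F = np.asarray(F, dtype=float)
    if F.size == 0:
        raise ValueError("empty feature matrix")
    squeeze = F.ndim == 1
    if squeeze:
        F = F[:, None]
    T = F.shape[0]
    k = kernel.samples
    # full convolution along time, truncated to the causal window
    out = np.apply_along_axis(lambda col: np.convolve(col, k)[:T], 0, F)
    return out[:, 0] if squeeze else out
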