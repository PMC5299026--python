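"""Voxel-specific HRF estimation by impulse stimulation of a trained response model.

Any response model that maps a feature sequence to response sequences can be
probed: the model is driven with a feature stream that is all zeros except
for a single all-ones vector at time 0, preceded by a silent pre-period that
settles the model's state. The per-voxel output around the impulse is then
normalised — the value just before the impulse is subtracted as baseline and
the curve is divided by its maximum — and the post-impulse segment is read
out as that voxel's estimated HRF. For a linear response model this returns
the model's kernel exactly (peak-normalised); for a recurrent model it reads
out whatever hemodynamic-like dynamics training has instilled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ridge import RidgeModel, build_design, predict_ridge

__all__ = [
    "EstimatedHRF",
    "RidgeSimulator",
    "impulse_response",
    "normalize_hrf",
    "extract_delays",
    "estimate_hrfs",
    "select_voxels_for_hrf",
]


@dataclass(frozen=True)
class EstimatedHRF:
    """A normalised impulse response (lags 0..horizon) with extracted delays.

    ``degenerate`` marks voxels whose impulse response had no positive
    deflection (normalisation undefined); ``delay_undershoot`` is None when
    the response never dips below baseline after its peak.
    """

    samples: np.ndarray
    sampling_interval: float
    voxel: int
    delay_response: float | None
    delay_undershoot: float | None
    degenerate: bool = False

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.sampling_interval


class RidgeSimulator:
    """Adapter giving a ridge model the same probing interface as an RNN model."""

    def __init__(self, model: RidgeModel, sampling_interval: float = 1.0, n_features: int | None = None):
        self.model = model
        self.sampling_interval = sampling_interval
        d = model.B.shape[1]
        factor = {"R-C": 1, "R-CTD": 3, "R-F": 4}[model.variant]
        self.n_features = n_features if n_features is not None else d // factor

    def simulate(self, features: np.ndarray) -> np.ndarray:
        design = build_design([features], self.model.variant, self.sampling_interval)
        return predict_ridge(self.model, design)


def _model_n_features(model) -> int:
    if hasattr(model, "n_features"):
        return model.n_features
    if hasattr(model, "layer1"):
        return model.layer1.input_dim
    raise TypeError("model does not expose its feature dimensionality")


def impulse_response(
    model,
    horizon: float = 32.0,
    pre_period: float = 32.0,
    amplitude: float = 1.0,
    sampling_interval: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the model's response to a feature impulse.

    The input stream is zero everywhere except at time 0, where every feature
    equals ``amplitude`` (all ones by default). A silent ``pre_period``
    precedes the impulse to stabilise the baseline. Returns ``(lags, raw)``
    where ``lags`` runs from ``-pre_period`` to ``horizon`` in sampling steps
    and ``raw`` is (len(lags) x m).
    """
    if horizon < 32.0:
        raise ValueError("horizon must cover the HRF support (>= 32 s)")
    pre = int(round(pre_period / sampling_interval))
    post = int(round(horizon / sampling_interval))
    if pre < 1:
        raise ValueError("need a pre-period of at least one sample")
    p = _model_n_features(model)
    X = np.zeros((pre + post + 1, p))
    X[pre] = amplitude
    raw = np.asarray(model.simulate(X), dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("model produced non-finite impulse response")
    lags = (np.arange(pre + post + 1) - pre) * sampling_interval
    return lags, raw


def normalize_hrf(
    lags: np.ndarray, raw: np.ndarray, sampling_interval: float = 1.0, voxel: int = 0
) -> EstimatedHRF:
    """Baseline-subtract, peak-normalise and crop one voxel's raw impulse response.

    The value at lag -1 is subtracted, the curve is divided by its maximum,
    and only lags >= 0 are kept. If the maximum after baseline subtraction is
    not positive the voxel is flagged degenerate (samples kept unscaled).
    """
    raw = np.asarray(raw, dtype=float)
    lags = np.asarray(lags, dtype=float)
    zero = int(np.argmin(np.abs(lags)))
    if zero < 1:
        raise ValueError("raw response must include at least one pre-impulse sample")
    shifted = raw - raw[zero - 1]
    peak = shifted.max()
    if peak <= 0:
        return EstimatedHRF(
            samples=shifted[zero:],
            sampling_interval=sampling_interval,
            voxel=voxel,
            delay_response=None,
            delay_undershoot=None,
            degenerate=True,
        )
    samples = (shifted / peak)[zero:]
    delay_response, delay_undershoot = extract_delays(samples, sampling_interval)
    return EstimatedHRF(
        samples=samples,
        sampling_interval=sampling_interval,
        voxel=voxel,
        delay_response=delay_response,
        delay_undershoot=delay_undershoot,
    )


def extract_delays(
    samples: np.ndarray, sampling_interval: float = 1.0
) -> tuple[float, float | None]:
    """Delay of response (argmax lag) and delay of undershoot (post-peak argmin).

    Ties break toward the earliest lag. The undershoot is undefined (None)
    when the post-peak minimum never dips below baseline — e.g. for a
    monotone or single-delta response.
    """
    samples = np.asarray(samples, dtype=float)
    peak = int(np.argmax(samples))
    delay_response = peak * sampling_interval
    tail = samples[peak + 1 :]
    if tail.size == 0:
        return delay_response, None
    trough = int(np.argmin(tail))
    if tail[trough] >= 0:
        return delay_response, None
    return delay_response, (peak + 1 + trough) * sampling_interval


def estimate_hrfs(
    model,
    voxels: np.ndarray | None = None,
    horizon: float = 32.0,
    pre_period: float = 32.0,
    amplitude: float = 1.0,
    sampling_interval: float = 1.0,
) -> list[EstimatedHRF]:
    """Probe a model once and return per-voxel normalised HRFs with delays."""
    lags, raw = impulse_response(model, horizon, pre_period, amplitude, sampling_interval)
    if voxels is None:
        voxels = np.arange(raw.shape[1])
    return [normalize_hrf(lags, raw[:, v], sampling_interval, voxel=int(v)) for v in voxels]


def select_voxels_for_hrf(
    r: np.ndarray, n_samples: int, alpha: float = 0.05
) -> np.ndarray:
    """Voxels whose correlation beats chance after Bonferroni correction.

    Uses the one-sided t-statistic of a Pearson correlation,
    t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom, at level
    ``alpha`` divided by the number of voxels. Returns the selected indices.
    """
    r = np.asarray(r, dtype=float)
    if n_samples <= 2:
        raise ValueError("need more than 2 samples to test a correlation")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rr = np.clip(r, -0.9999999, 0.9999999)
    t = rr * np.sqrt((n_samples - 2) / (1.0 - rr**2))
    p = stats.t.sf(t, df=n_samples - 2)
    return np.where(p < alpha / r.size)[0]
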