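"""Spatial-envelope (GIST-style) visual features of grayscale video frames.

Each second of video (a stack of frames) is summarised by Gabor energies: the
frames are filtered with a bank of 32 Gabor filters (8 orientations x 4
scales, one octave apart), the squared response is averaged within each cell
of a 4 x 4 spatial grid, and the energies are averaged over the frames of
the second. With the default bank and grid this yields a 512-dimensional
feature vector per second (16 regions x 32 filters).

Filtering happens in the frequency domain with wraparound (the standard
spatial-envelope convention); kernels are forced to zero mean so features are
invariant to the mean luminance. The Gabor parameterisation (centre
frequencies one octave apart starting at 0.25 cycles/px, bandwidth about one
octave) follows the common public implementations of the descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import gabor_kernel

__all__ = ["GaborBank", "build_gabor_bank", "gist_features"]


@dataclass(frozen=True)
class GaborBank:
    """A stack of zero-mean real Gabor kernels and their metadata."""

    kernels: tuple[np.ndarray, ...]
    orientations: int
    scales: int
    frequencies: tuple[float, ...]
    thetas: tuple[float, ...]

    @property
    def n_filters(self) -> int:
        return len(self.kernels)


def build_gabor_bank(
    orientations: int = 8, scales: int = 4, max_frequency: float = 0.25
) -> GaborBank:
    """Build ``orientations x scales`` zero-mean Gabor kernels.

    Orientations are spaced pi/orientations apart; scales are one octave
    apart descending from ``max_frequency`` (cycles/pixel). Each kernel is
    the real (cosine-phase) part of a complex Gabor with its mean subtracted,
    so a constant image produces exactly zero response.
    """
    if orientations < 1 or scales < 1:
        raise ValueError("orientations and scales must be positive")
    kernels, freqs, thetas = [], [], []
    for s in range(scales):
        frequency = max_frequency / (2**s)
        for o in range(orientations):
            theta = o * np.pi / orientations
            k = np.real(gabor_kernel(frequency, theta=theta))
            k = k - k.mean()
            kernels.append(k)
            freqs.append(frequency)
            thetas.append(theta)
    return GaborBank(
        kernels=tuple(kernels),
        orientations=orientations,
        scales=scales,
        frequencies=tuple(freqs),
        thetas=tuple(thetas),
    )


def _filter_fft(frame: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular (wraparound) convolution of a frame with a centred kernel."""
    H, W = frame.shape
    kh, kw = kernel.shape
    if kh > H or kw > W:
        # low-frequency kernels can outgrow small frames: crop centrally and
        # restore the zero-mean property so luminance invariance is kept
        ch, cw = min(kh, H), min(kw, W)
        r0, c0 = (kh - ch) // 2, (kw - cw) // 2
        kernel = kernel[r0 : r0 + ch, c0 : c0 + cw]
        kernel = kernel - kernel.mean()
        kh, kw = kernel.shape
    padded = np.zeros((H, W))
    padded[:kh, :kw] = kernel
    # centre the kernel so the response is not translated
    padded = np.roll(padded, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return np.real(np.fft.ifft2(np.fft.fft2(frame) * np.fft.fft2(padded)))


def gist_features(
    frames: np.ndarray, bank: GaborBank | None = None, grid: int = 4
) -> np.ndarray:
    """Gabor-energy spatial-envelope features of one second of video.

    ``frames`` is (n_frames x H x W) grayscale (an RGB stack (n, H, W, 3) is
    converted by channel mean). For every frame and filter, the mean squared
    filter response is computed in each of the ``grid x grid`` non-overlapping
    regions; energies are averaged over frames and concatenated region-major
    (grid cells x filters). Defaults give 16 x 32 = 512 features.
    """
    bank = bank or build_gabor_bank()
    F = np.asarray(frames, dtype=float)
    if F.ndim == 4:
        F = F.mean(axis=-1)
    if F.ndim == 2:
        F = F[None]
    if F.ndim != 3 or F.shape[0] < 1:
        raise ValueError("expected a (n_frames x H x W) stack")
    n, H, W = F.shape
    if H != W:
        raise ValueError("frames must be square")
    if H % grid != 0:
        raise ValueError(f"frame size {H} not divisible by grid {grid}")
    cell = H // grid
    energies = np.zeros((grid * grid, bank.n_filters))
    for frame in F:
        for j, kernel in enumerate(bank.kernels):
            resp2 = _filter_fft(frame, kernel) ** 2
            blocks = resp2.reshape(grid, cell, grid, cell).mean(axis=(1, 3))
            energies[:, j] += blocks.ravel()
    energies /= n
    return energies.ravel()
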