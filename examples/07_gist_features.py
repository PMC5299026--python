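"""Gabor-energy spatial-envelope (GIST-style) features of video frames.

Each second of video (a stack of grayscale frames) becomes a 512-dimensional
vector: 32 Gabor filters (8 orientations x 4 scales) x 16 spatial regions,
energies averaged over the frames of the second.
"""

import numpy as np

from voxencode import build_gabor_bank, gist_features

bank = build_gabor_bank()
print(f"bank: {bank.n_filters} filters "
      f"({bank.orientations} orientations x {bank.scales} scales), "
      f"frequencies {sorted(set(bank.frequencies), reverse=True)}")

rng = np.random.default_rng(0)
frames = rng.random((15, 128, 128))  # one second of 15 FPS noise video
feats = gist_features(frames, bank)
print(f"feature vector length: {feats.shape[0]}")

# a vertical grating at the bank's highest frequency lights up one orientation
x = np.arange(128)
grating = np.cos(2 * np.pi * bank.frequencies[0] * x)[None, :].repeat(128, axis=0)
energy = gist_features(grating[None], bank).reshape(16, 32).mean(axis=0)
print(f"grating energy by orientation (scale 1): {np.round(energy[:8], 3)}")
print(f"preferred orientation index: {np.argmax(energy[:8])}")
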