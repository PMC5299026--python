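"""Generate a ground-truth synthetic dataset and inspect its structure.

The generator emulates a continuous movie-watching experiment: block-paired
feature/response matrices, repeated test measurements, initial-transient
discard and per-block z-scoring. Everything needed to verify an analysis
(weights, kernels, delays, noise levels) comes back as GroundTruth.
"""

import numpy as np

from voxencode import SyntheticConfig, generate_dataset

config = SyntheticConfig(scale=0.25)  # 150 s training blocks, full 60 s test blocks
dataset, truth = generate_dataset(config, seed=0)

train = [fb for fb in dataset.features if fb.role == "train"]
test = [fb for fb in dataset.features if fb.role == "test"]
print(f"{len(train)} training blocks x {train[0].n_samples} s, "
      f"{len(test)} test blocks x {test[0].n_samples} s")
print(f"{dataset.n_features} features, {dataset.n_voxels} voxels")
rep = dataset.response_for("test00").repeats
print(f"test repeats: R = {rep.shape[0]}")
print(f"true response delays (s): {np.sort(truth.delays_response).round(1)}")
# The delays are the ground truth that HRF probing should recover; the repeat
# stack is what the noise-ceiling estimate feeds on.
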