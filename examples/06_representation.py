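"""Representational analyses of a trained recurrent model's internals.

RDMs (correlation distance between time-point patterns) summarise each
pipeline stage; correlating their upper triangles shows how strongly the
hidden states are coupled to the inputs vs the outputs. Optimal lags show
which part of the stimulus history each hidden unit tracks.
"""

import numpy as np

from voxencode import (
    SyntheticConfig, TrainConfig, compute_rdm, forward, generate_dataset,
    init_model, optimal_lags, rdm_correlation, split_validation, train,
)

dataset, _ = generate_dataset(SyntheticConfig(scale=0.25), seed=0)
train_ds, val_ds = split_validation(dataset, 45)
model = init_model("GRU", 10, dataset.n_features, dataset.n_voxels, seed=7)
model, _ = train(
    model,
    [(fb.values, rb.values) for fb, rb in train_ds.blocks("train")],
    [(fb.values, rb.values) for fb, rb in val_ds.blocks("validation")],
    TrainConfig(max_epochs=200),
    seed=7,
)

fb = next(f for f, _ in dataset.blocks("test"))
pred, h1, h2 = forward(model, fb.values)
rdms = {
    "features": compute_rdm(fb.values, "features"),
    "layer1": compute_rdm(h1, "layer1"),
    "layer2": compute_rdm(h2, "layer2"),
    "predictions": compute_rdm(pred, "predictions"),
}
for a, b in (("features", "layer1"), ("layer1", "layer2"),
             ("layer2", "predictions"), ("features", "predictions")):
    print(f"RDM correlation {a:>9s} ~ {b:<11s}: {rdm_correlation(rdms[a], rdms[b]):.2f}")
# Hidden-state RDMs correlate more with the predictions than with the
# instantaneous features: the states carry stimulus *history*.

prof = optimal_lags(h2, fb.values, max_lag=30)
finite = prof.lags[np.isfinite(prof.lags)]
print(f"layer-2 optimal lags (s): {np.sort(finite)}")
print(f"mean optimal lag: {finite.mean():.1f} s")
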