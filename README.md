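# voxencode

Voxelwise encoding models for continuous-design fMRI: feedforward ridge
models with hemodynamic basis functions, gated recurrent response models
(LSTM/GRU) trained by truncated backpropagation through time, voxel-specific
HRF estimation by impulse probing, and the statistical machinery — noise
ceilings, permutation tests, bootstrap comparisons, representational
analyses — needed to compare them honestly.

## The problem

An encoding model predicts brain activity from a stimulus: a *feature
model* φ turns the stimulus into a feature vector per second, and a
*response model* g turns the feature sequence into voxel responses,

  ŷᵗ = g(φ(x⁰), …, φ(xᵗ)),  φ(xᵗ) ∈ ℝᵖ, ŷᵗ ∈ ℝᵐ.

In continuous designs (movie watching, music listening) there are no
discrete trials: the BOLD signal at time t reflects seconds of stimulus
history filtered through each voxel's hemodynamic response function (HRF).
The classical response model fixes that history handling in advance — it
convolves the features with a canonical HRF (or a small basis around it, or
lagged copies) and fits a regularised linear map per voxel:

  ŷᵗ = (H_c F Bᵀ)ᵗ,  B estimated by per-voxel ridge regression.

The recurrent alternative learns the temporal dependencies instead of
assuming them: two stacked LSTM or GRU layers are shared by the voxels of a
group, and each voxel reads its prediction linearly off the second layer's
hidden state, ŷᵗ = h₂ᵗ Wᵀ. Because the gates control what the state
retains, the network can represent voxel-to-voxel differences in
hemodynamic timing — and, once trained, those learned dynamics can be read
back out: driving the model with a single feature impulse and normalising
the response yields each voxel's estimated HRF, with its delay of response
(peak) and delay of undershoot (post-peak trough).

The package implements both families, the probing procedure, the evaluation
protocol (cross-validated Pearson r per voxel, group medians, Monte-Carlo
noise ceilings from repeated test measurements, permutation tests with
model retraining, bootstrap comparisons over voxels), representational
analyses (RDMs across pipeline stages, per-unit optimal lags), a
Gabor-energy spatial-envelope feature model for video frames, and a
ground-truth synthetic data generator that emulates the block structure of a
public movie-watching experiment so every claim is testable without
downloads. The recurrent cells, their gradients, and the training loop are
implemented in numpy and verified against finite differences.

## Worked example

Generate a desk-scale synthetic dataset (12 training blocks of 150 s, nine
60 s test blocks repeated 10 times; 20 voxels whose true HRF delays are
drawn from 4–8 s; SNR 2), fit the canonical-HRF ridge model and a 10-unit
GRU model, and probe the GRU for the voxels' HRFs:

```python
import numpy as np
from voxencode import (
    SyntheticConfig, TrainConfig, estimate_hrfs, fit_ridge_from_dataset,
    forward, generate_dataset, init_model, split_validation, train,
    voxel_performance,
)

dataset, truth = generate_dataset(SyntheticConfig(scale=0.25), seed=0)

model, pred, obs = fit_ridge_from_dataset(dataset, "R-C")
print(f"R-C median test r: {np.median(voxel_performance(pred, obs)):.3f}")

train_ds, val_ds = split_validation(dataset, 45)
gru = init_model("GRU", 10, dataset.n_features, dataset.n_voxels, seed=7)
gru, history = train(
    gru,
    [(fb.values, rb.values) for fb, rb in train_ds.blocks("train")],
    [(fb.values, rb.values) for fb, rb in val_ds.blocks("validation")],
    TrainConfig(max_epochs=300), seed=7,
)
hrfs = estimate_hrfs(gru)
err = [abs(e.delay_response - d) for e, d in zip(hrfs, truth.delays_response)]
print(f"delays within 1 s of truth: {np.mean(np.array(err) <= 1):.2f}")
```

Output (examples/02, 03 and 04 print the full versions):

```
   R-C: median test r = 0.884
best validation median r: 0.673 (epoch 293)
test median r over 20 voxels: 0.785
voxel  true delay  estimated  curve r
    0       7.47        7.0    0.909
    1       4.60        5.0    0.967
    2       7.71        7.0    0.935
fraction of voxels within 1 s of the true delay: 1.00
```

Reading: on this dataset the HRF delays stay close enough to the canonical
peak that the fixed-kernel ridge model predicts slightly better than the
small recurrent trunk (0.88 vs 0.79 median r) — yet only the recurrent model
carries the voxels' individual hemodynamics, and the impulse probe recovers
every voxel's true delay to within a second with HRF curve correlations
above 0.9. When the generator draws delays far from the canonical peak
(5–11 s), the ordering flips decisively: the GRU's median r exceeds the
ridge model's by ~0.2 with a bootstrap CI well away from zero
(examples/08 and the acceptance script run that comparison).

The `examples/` directory has one short script per capability: dataset
simulation, the ridge family, GRU training, HRF probing, evaluation
statistics, representational analyses, GIST features, and the full pipeline
(also available as a thin CLI: `voxencode simulate|run|report`).

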