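# Methods

## Problem and model families

`voxencode` fits and evaluates *response models* for continuous-design fMRI:
mappings from a stimulus feature sequence φ(x¹), …, φ(xᵗ) ∈ ℝᵖ (one vector
per second) to voxel response sequences y¹, …, yᵗ ∈ ℝᵐ (BOLD amplitude,
TR = 1 s, z-scored). Two families are implemented.

**Feedforward ridge family.** Per voxel v, ŷᵗ = (X Bᵀ)ᵗ with an
L²-penalised analytic solution for each row of B. The variants differ only
in the design matrix X:

* `R-C` — features convolved with the canonical double-gamma HRF
  (lower-triangular Toeplitz operator; T × p columns);
* `R-CTD` — canonical HRF plus its temporal (onset) and dispersion
  derivatives, column-concatenated (T × 3p);
* `R-F` — finite-impulse-response model: the features lagged by 3, 4, 5 and
  6 s, concatenated (T × 4p, deliberately no lag-0 term).

The per-voxel regularisation λ is chosen on a held-out validation set
(maximum Pearson r over a 20-point log grid spanning 10⁻³…10⁶; ties go to
the larger λ). One eigendecomposition of XᵀX is shared across grid values
and voxels. Validation rows are carved out of the *convolved* training
blocks so the tail keeps its convolution history.

**Recurrent family.** Two stacked recurrent layers (LSTM or GRU cells, equal
width h ∈ {10, 50, 100}) shared by all voxels of a group, plus a per-voxel
linear readout of the second layer's hidden state: ŷᵗ = h₂ᵗ Wᵀ. The LSTM
candidate activation is a sigmoid by default (`candidate_tanh=True` restores
the conventional tanh; the sigmoid variant is the form this package treats
as primary). Gates carry their own recurrent weights U, input weights W and
biases b. Training is truncated backpropagation through time (window 60
samples, states carried across windows, gradients not) with Adam on the MSE
loss, inverted dropout on both hidden layers' outputs, and early stopping at
the epoch with the highest validation *median* correlation over the group's
voxels. Gradients are hand-derived and verified against central finite
differences in the test suite. All randomness (initialisation, dropout
masks) flows from one seed, so training histories are bit-reproducible.

### Training hyperparameters

| parameter | default | rationale |
| --- | --- | --- |
| truncation window | 60 s | must exceed the ~32 s HRF support with margin |
| learning rate | 3e-3 | Adam; cells are small, loss well-conditioned |
| dropout | 0.2 | with h = 10 units, stronger dropout (e.g. 0.5) removes half the state and caps the attainable fit far below the representational ceiling; 0.2 regularises without crippling small trunks |
| max epochs | 500 | validation early stopping picks the returned snapshot |
| gradient clip | 5.0 (global norm) | guards the rare exploding-gradient window |
| init | uniform ±1/√fan-in, LSTM forget bias +1 | standard |

Equal-length training blocks are stacked into one batch and advanced in
lockstep, which keeps the per-epoch cost at a handful of matrix products.

## HRF estimation by impulse probing

Any fitted response model exposing `simulate(features)` can be probed: the
input is all zeros except an all-ones feature vector at time 0, preceded by
a 32 s silent pre-period that settles the state. The raw per-voxel output is
baseline-corrected (value at lag −1 subtracted), divided by its maximum, and
cropped to lags ≥ 0. Delay of response = argmax lag (earliest on ties);
delay of undershoot = argmin over lags after the peak, flagged undefined
when the post-peak minimum never dips below baseline. Probing a *linear*
model returns its kernel peak-normalised to machine precision — the module's
central oracle, asserted in the tests. Voxels are selected for HRF reporting
when their test correlation beats chance under a one-sided t-test
(t = r√((n−2)/(1−r²))) with Bonferroni correction over voxels.

The impulse amplitude is 1 on every feature. Trained recurrent models are
nonlinear, so the estimated HRF can depend on this amplitude; a scaling knob
is exposed (`amplitude=`) and left at 1 by default.

## Statistical evaluation

* **Performance**: Pearson r between predicted and observed test responses
  per voxel; group summaries are medians, never means. Constant sequences
  score r = 0 with a warning.
* **Noise ceiling**: Monte-Carlo estimate from the repeated test
  measurements. Noise variance = mean squared SEM of the repeat mean over
  time (an alternative reading — the variance *of* the SEMs — is exposed via
  `sem_mode="variance"`); signal variance = variance of the repeat mean
  minus noise variance, floored at 0. Each of n_sim = 1000 draws correlates
  a Gaussian signal with itself plus Gaussian noise; the ceiling is the
  median. Group performance is ceiling-corrected by dividing the median r by
  the group's median ceiling (the correction is a ratio by construction
  here; flagged undefined when the ceiling is ≤ 0).
* **Permutation test**: responses are permuted over time (one shared
  permutation across voxels, applied within the train-role and test-role
  blocks separately), the model is retrained per permutation, and p is the
  fraction of permutations whose group median meets the observed one
  (zero counts reported as "< 1/n_perm"); Bonferroni over groups.
  Index-wise permutation ignores temporal autocorrelation and is therefore
  anticonservative on strongly autocorrelated nulls; this matches the
  evaluated protocol and is noted wherever p-values are reported.
* **Bootstrap comparison**: voxels resampled with replacement (default
  10 000 draws); statistic = difference of medians; percentile CI at the
  Bonferroni-corrected level; significant when the CI excludes zero.
* **Threshold analysis**: voxels partitioned by |r_a − r_b| > 0.1 and by
  sign, with side-wise median absolute differences.

## Representational analyses

RDMs use correlation distance (1 − Pearson r) between the multivariate
patterns at pairs of test time points, for four pipeline stages: features,
layer-1 states, layer-2 states, predictions. Stage RDMs are compared by the
Pearson correlation of their strictly-upper triangles and averaged across
groups elementwise. Optimal lags cross-correlate each (z-scored) hidden unit
with each feature at lags −30…0 s, average the signed correlations over
features, and take the argmax lag (earliest on ties). Persistent features
produce more negative optimal lags than fast features; the package's lag
contrast checks exactly this sign.

## Synthetic data generator

The generator emulates the block structure of a public movie-watching
experiment: twelve 600 s training blocks, nine 60 s test blocks whose
stimulus repeats R = 10 times, first 6 s of every block discarded, last 45 s
of each training block reserved for validation, per-block z-scoring.
Repeats are mapped through the same per-block affine transform as their
mean, so the stored mean always equals the repeat average.

Generative model per voxel: drive = F·w_v (optionally passed through a
saturating `tanh` or half-wave `threshold` nonlinearity), convolved with a
voxel-specific gamma-difference HRF, plus white Gaussian noise scaled to a
target SNR (noise sd = signal sd / SNR; default SNR 2). Response delays are
uniform on 4–8 s, undershoot delays 8–12 s later; ground-truth delays are
recorded from a 1 ms dense evaluation of each kernel. Weights are sparse
(density 0.5) and **nonnegative** (half-normal): BOLD responses to
energy-like features are predominantly positive, and a positive net drive is
what makes the all-ones impulse probe well-posed — with symmetric weights,
half the voxels would respond to the probe with a sign-flipped kernel that
peak-normalisation necessarily scrambles.

Design choices worth stating explicitly:

* **`scale` shrinks training blocks only.** Test blocks must cover the 32 s
  HRF support to be usable at all; scaling them down with the training data
  would destroy every model's attainable correlation for reasons unrelated
  to the models. Desk-scale runs therefore shorten the (expensive) training
  blocks and keep the nine 60 s test blocks.
* **Fast features by default (AR(1) time constant 1 s).** Voxel-specific
  kernels are identifiable only when the stimulus has power at the
  timescales on which the kernels differ; with slow features the outputs of
  different kernels are nearly collinear and no method could tell them
  apart. Slow, semantic-like statistics (e.g. τ = 8 s) remain available via
  `feature_tau` and are used in the lag contrast.
* **Convolution is block-local** with zero-padded history, matching the
  preprocessing convention that nothing crosses block boundaries. Because
  the first 6 s of each block are discarded after generation, the observed
  responses retain contributions from discarded samples that no model can
  see; this depresses attainable correlations equally for all models,
  exactly as in the emulated experiment.
* **What the generator does not emulate**: drift, motion, physiological
  noise, spatial correlation between voxels, session effects. Passing tests
  on this generator shows the estimators and the training loop are correct
  and calibrated under the stated generative model — not that the models
  reach comparable performance on real recordings.

## Experiment-level conditions used by the acceptance script

* *HRF recovery*: scale 0.25, m = 20 voxels, delays 4–8 s, SNR 2, linear;
  G-10 trained 500 epochs with a fixed seed. Reported: fraction of
  significant voxels whose estimated delay is within ±1 s of truth, and the
  median correlation between estimated and true HRF curves.
* *Direction of effect*: scale 1.0, m = 60 voxels, delays uniform 5–11 s,
  linear. This condition makes HRF variability — the mechanism the recurrent
  family is designed to absorb and the ridge family cannot — the dominant
  generative violation: voxel-to-voxel BOLD latency differences of several
  seconds are well documented, and with delays confined near the canonical
  peak the fixed-kernel model is barely penalised (wide gamma kernels
  overlap heavily) while a 10-unit trunk carries an intrinsic small-capacity
  handicap. Reported: both medians, the difference of medians, and the lower
  edge of its 95% bootstrap CI.
* *Canonical control*: data generated exactly by the canonical-HRF linear
  model (scale 0.25, m = 20); the ridge model should match or beat the
  recurrent model here, and does.
* *Calibration*: permutation p-values on null data (100 replicates,
  n_perm = 50) tested for uniformity; permutation p on a planted signal;
  bootstrap CI coverage of a known median gap (200 replications); Monte-Carlo
  noise ceiling against the closed form σ_s/√(σ_s²+σ_n²).
* *Lag contrast*: G-10 trained on slow (τ = 8 s) vs fast (τ = 1 s) features
  at scale 0.25; mean optimal lag of hidden units, whose difference should
  be (and is) negative.

Problem sizes (block scale, voxel counts, epochs, permutation and bootstrap
counts) are the package's desk-scale defaults, chosen so the full
recomputation completes in minutes on one CPU while leaving every
statistical check adequately powered.

## Numerical conventions and degenerate inputs

* Sample t covers [t, t+1) s; 0-based, block-local indices.
* The canonical HRF uses the common SPM parameterisation (shape =
  delay/dispersion, scale = dispersion; response delay 6, undershoot delay
  16, dispersions 1, ratio 6, 32 s support), peak-normalised. Derivative
  kernels are unit-norm central finite differences (onset step 1 s,
  dispersion step 0.01).
* Planted kernels place their *mode* at the drawn delay (shape = delay + 1
  with unit dispersion), and ground-truth delays are read off a dense grid
  of the full difference kernel.
* Ties in argmax/argmin: earliest lag, everywhere.
* Constant channels: z-scoring zeroes them (warning); correlations against
  constants are 0 (warning); constant RDM patterns give NaN entries
  (warning); degenerate impulse responses are flagged per voxel, never
  raised.
* Detrending is assumed done upstream; the generator produces drift-free
  data.
* Whether the emulated experiment z-scored per block or per session is not
  determinable from its description; z-scoring here is per block (flag
  `zscore` on `preprocess`).

## Known limitations

* The permutation test retrains the model per permutation; in the pipeline
  it is run for the ridge family only — retraining a recurrent model 200
  times is out of scale for a desk run (the machinery accepts any
  retrainable scorer).
* Recurrent trunks of width 10 are representation-limited: ~20 state
  dimensions cannot realise 20+ independent voxel kernels exactly, which is
  visible as a few-percent gap to the ridge model on canonical-linear data.
* GIST features follow the standard spatial-envelope construction (4×4
  grid of 32×32 px regions on 128×128 frames, 8 orientations × 4 scales one
  octave apart, frequency-domain filtering with wraparound); the exact Gabor
  bandwidths of historical implementations vary, and ours are recorded in
  `build_gabor_bank`'s signature.
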