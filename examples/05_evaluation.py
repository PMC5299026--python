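"""Statistical evaluation: noise ceilings, bootstrap comparison, thresholds.

The noise ceiling bounds what any model could score given measurement noise
(estimated from the repeated test presentations); the bootstrap compares two
models' median performance over voxels; the threshold analysis describes
where they differ by more than r = 0.1.
"""

import numpy as np

from voxencode import (
    SyntheticConfig, bootstrap_compare, ceiling_correct, fit_ridge_from_dataset,
    generate_dataset, noise_ceiling, threshold_diff_analysis, voxel_performance,
)

dataset, truth = generate_dataset(SyntheticConfig(scale=0.25), seed=0)

stacks = [rb.repeats for _, rb in dataset.blocks("test") if rb.repeats is not None]
ceil = noise_ceiling(np.concatenate(stacks, axis=1), n_sim=500, seed=0)
print(f"median noise ceiling: {np.median(ceil):.3f} "
      f"(test responses average R = 10 repeats, so the ceiling is high)")

r = {}
for variant in ("R-C", "R-F"):
    _, pred, obs = fit_ridge_from_dataset(dataset, variant)
    r[variant] = voxel_performance(pred, obs)
    med = float(np.median(r[variant]))
    print(f"{variant}: median r = {med:.3f}, ceiling-corrected = "
          f"{ceiling_correct(med, float(np.median(ceil))):.3f}")

boot = bootstrap_compare(r["R-C"], r["R-F"], n_boot=5000, seed=0)
print(f"R-C minus R-F: delta median = {boot.delta_median:+.3f}, "
      f"95% CI [{boot.ci_low:+.3f}, {boot.ci_high:+.3f}], "
      f"significant: {boot.significant}")
thr = threshold_diff_analysis(r["R-C"], r["R-F"], threshold=0.1)
print(f"voxels differing by more than 0.1: {thr.fraction_differing:.0%}")
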