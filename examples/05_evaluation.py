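"""Screening-classifier evaluation utilities.

AUROC with DeLong interval, exact Clopper-Pearson intervals for sensitivity,
operating-point selection (max harmonic mean, or a target-sensitivity floor
for rare diseases), and the cosine-distance analysis that suggests where a
shared encoder should branch into per-finding paths.
"""

import numpy as np

import carfundus as cf
from carfundus.evaluation import cosine_branch_analysis

rng = np.random.default_rng(0)
n = 400
labels = (rng.random(n) < 0.3).astype(int)
scores = np.clip(0.55 * labels + 0.25 * rng.random(n) + 0.1, 0, 1)

auc, lo, hi = cf.delong_ci(scores, labels)
print(f"AUROC {auc:.3f} (95% DeLong CI {lo:.3f}-{hi:.3f})")

op = cf.choose_operating_point(scores, labels, policy="max_harmonic_mean")
print(f"max-harmonic-mean point: threshold {op.threshold:.3f}, "
      f"sens {op.sensitivity:.3f}, spec {op.specificity:.3f}")

k = int(np.sum((scores >= op.threshold) & (labels == 1)))
npos = int(labels.sum())
cp = cf.clopper_pearson(k, npos)
print(f"sensitivity {k}/{npos} with exact 95% CI ({cp[0]:.3f}, {cp[1]:.3f})")

op90 = cf.choose_operating_point(scores, labels, policy="target_sensitivity",
                                 target=0.9)
print(f"90%-sensitivity point: threshold {op90.threshold:.3f}, "
      f"sens {op90.sensitivity:.3f}, spec {op90.specificity:.3f}")

# branch-point analysis: per-finding features at successive encoder depths.
# Shallow layers share structure; deeper layers separate findings.
layer_sets = {}
shared = {depth: rng.normal(size=(20, 16)) for depth in range(4)}
for depth, spread in enumerate([0.0, 0.0, 0.6, 1.2]):
    groups = {}
    for f in range(3):
        # same shared features per layer; deeper layers add per-finding offsets
        groups[f"finding{f}"] = shared[depth] + spread * np.eye(16)[f] * 5.0
    layer_sets[f"stage{depth}"] = groups
result = cosine_branch_analysis(layer_sets)
for layer, dist in result["mean_distance"].items():
    print(f"{layer}: mean pairwise cosine distance {dist:.3f}")
print(f"suggested branch layer: {result['suggested_branch_layer']}")
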