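"""Fuse noisy multi-reader annotations into probabilistic training targets.

Simulates a 3-reader panel with known sensitivities/specificities, recovers
the reader profiles by EM, and compares posterior-thresholded labels with
plain majority vote against the simulated truth.
"""

import numpy as np
import pandas as pd

import carfundus as cf
from carfundus.fusion import panel_matrix

n, prevalence = 3000, 0.3
sens, spec = (0.9, 0.8, 0.7), (0.95, 0.9, 0.85)

rng = np.random.default_rng(0)
truth = (rng.random(n) < prevalence).astype(int)
truths = pd.DataFrame({"image_id": [f"i{k}" for k in range(n)], "lab": truth})
panel = cf.simulate_reader_panel(truths, ["lab"], sens, spec, seed=1)

res = cf.em_estimate(panel, "lab")
print(f"estimated prevalence: {res.prior.prevalence:.3f} (true {prevalence})")
for prof, s, c in zip(res.profiles, sens, spec):
    print(f"  {prof.reader}: sens {prof.sensitivity:.3f} (true {s}), "
          f"spec {prof.specificity:.3f} (true {c})")

# align pivot order (lexicographic image ids) back to the truth order
marks, image_ids, _ = panel_matrix(panel, "lab")
majority = pd.Series(marks.mean(axis=1) > 0.5, index=image_ids)
order = truths["image_id"]
posterior_labels = (res.posteriors.loc[order].to_numpy() > 0.5).astype(int)
majority_labels = majority.loc[order].to_numpy().astype(int)
print(f"posterior accuracy vs truth: {np.mean(posterior_labels == truth):.3f}")
print(f"majority-vote accuracy     : {np.mean(majority_labels == truth):.3f}")

# the conservative reference standard for evaluation splits
for pattern in [(1, 1, 0), (0, 0, 0), (1, 0, 0)]:
    print(f"reference standard {pattern} -> {cf.reference_standard(pattern)}")

# ordinal severity calls expand into per-label binary marks
recoded = cf.severity_recode(["any_dr", "referable_dr"],
                             ["any_dr", "referable_dr", "none"])
print("severity recode (readers: any DR, referable DR, none):", recoded)
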