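"""Compare the model's CAR grid with the pooled expert odds-ratio grid.

Experts' readings for each finding-disease pair are pooled into a 2x2 table;
its odds ratio measures how strongly experts associate the pair.  A model
whose CAR grid ranks pairs like the expert OR grid draws diagnostic
conclusions the way clinicians do.
"""

import numpy as np

import carfundus as cf
from carfundus.expert import car_or_grid, expert_or_grid

spec = cf.GeneratorSpec(n_images=800, seed=2)
co = cf.simulate_cohort(spec)
truths = None

# reader panel over both findings and diseases
import pandas as pd
frame = {"image_id": [f"i{k}" for k in range(spec.n_images)]}
for f, name in enumerate(spec.finding_names):
    frame[name] = co.finding_truth[:, f]
for d, name in enumerate(spec.disease_names):
    frame[name] = co.disease_truth[:, d]
truths = pd.DataFrame(frame)
panel = cf.simulate_reader_panel(truths, spec.finding_names + spec.disease_names,
                                 spec.reader_sens, spec.reader_spec, seed=3)

# worked single table: hemorrhage vs retinopathy
table = cf.pooled_contingency(panel, "hemorrhage", "retinopathy")
print("pooled 2x2 (f=1&d=1, f=1&d=0; f=0&d=1, f=0&d=0):")
print(table.counts)
print(f"expert OR: {cf.odds_ratio(table, correction='haldane'):.2f}")

# model trained on the cohort features
fheads, _ = cf.train_finding_heads(co.features, co.finding_truth.astype(float),
                                   spec.finding_names)
dheads, _ = cf.train_disease_heads(co.features, co.disease_truth.astype(float),
                                   spec.disease_names)
model = cf.ModelBundle(fheads, dheads)

grids = car_or_grid(cf.car_matrix(model, eps=0.005), panel)
print("expert log-OR grid:")
print(grids["log_or"].round(2))
print("model log-CAR grid:")
print(grids["log_car"].round(2))
print("per-disease Spearman rank agreement:")
print(grids["rank_agreement"].round(3))
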