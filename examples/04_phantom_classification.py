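"""End-to-end: phantom cohort -> descriptors -> repeated-split evaluation.

Generates a two-class cohort of textured 3D lesion phantoms with air
pockets, air-cleanses and quantizes each volume-of-interest, extracts the
13-direction retained-28 descriptor at stride 2, and evaluates it with
Gini ranking + forward selection + random forests over repeated
stratified splits.  Settings are reduced (60 trees, 8 iterations) so the
script finishes in about half a minute.
"""

import numpy as np

from msglcm import (
    EnsembleParams,
    PhantomSpec,
    SplitPlan,
    evaluate_scheme,
    extract_features,
    generate_cohort,
)

spec = PhantomSpec(
    n_benign=16, n_malignant=16, shape=(20, 20, 20),
    separation=0.8, air_fraction=0.05, seed=5,
)
lesions = generate_cohort(spec)
print(f"cohort: {len(lesions)} lesions, "
      f"{sum(l.label for l in lesions)} malignant, VOI {spec.shape}")

table = extract_features(
    lesions, displacement=1, stride=2, cleanse_threshold=-855.0
)
n_feat = table.shape[1] - 2
print(f"descriptor: 13 directions x 28 measures = {n_feat} variables/lesion")

labels = table["label"].to_numpy()
feats = table.drop(columns=["lesion_id", "label"]).to_numpy()
plan = SplitPlan.generate(labels, n_iterations=8, n_train_benign=8,
                          n_train_malignant=8, seed=6)
params = EnsembleParams(n_trees=60, max_subset_size=8)
result = evaluate_scheme(feats, labels, plan, params)

s = result.summary()
print(f"\nmean AUC         = {s['mean_auc']:.3f} +/- {s['sd_auc']:.3f}")
print(f"mean accuracy    = {s['mean_accuracy']:.3f}")
print(f"mean sensitivity = {s['mean_sensitivity']:.3f}")
print(f"mean specificity = {s['mean_specificity']:.3f}")
sizes = [len(f) for f in result.selected_features]
print(f"selected subset sizes per split: {sizes}")
# With separation 0.8 the two classes differ in correlation length and
# contrast, so a handful of selected texture variables suffices for
# near-perfect discrimination; separation 0 would hover near AUC 0.5.
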