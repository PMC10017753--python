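"""Which brain features drive the classification?

Computes permutation importance (mean squared change in classification
cross-entropy over column shuffles) on each fold's validation subjects with
that fold's model, averages across folds, and applies the mean + 2 SD rule.
The features flagged important should belong to the planted nodes.
"""

import numpy as np

from connsae import AEConfig, CohortConfig, generate_cohort
from connsae.importance import cv_permutation_importance, identify_important_features
from connsae.pipeline import compute_feature_table
from connsae.ssae import cross_validate_ssae

planted = [("struct", 3), ("struct", 11), ("func", 2), ("func", 17)]
cfg = CohortConfig(n_per_group=25, effect_nodes=planted, effect_size=2.0, seed=5)
cohort = generate_cohort(cfg)
table, _ = compute_feature_table(cohort, seed=0)
cols = [c for c in table.columns if c != "group"]
X = table[cols].to_numpy()
y = (table["group"] == "tbi").to_numpy().astype(float)

cv = cross_validate_ssae(X, y, AEConfig(seed=0), k=5, seed=0)
print(f"CV accuracy {100 * cv.accuracy_mean:.1f}%")

fi, _ = cv_permutation_importance(cv, X, y, n_source_features=X.shape[1],
                                  m=300, seed=0)
candidates = np.flatnonzero(~np.isnan(fi))
important = [candidates[i] for i in identify_important_features(fi[candidates])]
print(f"{len(candidates)} features were ever selected across folds; "
      f"{len(important)} pass the mean+2SD importance rule:")
planted_nodes = {f"{k}_{n}" for k, n in planted}
for i in sorted(important, key=lambda i: -fi[i]):
    name = cols[i]
    kind, node = name.split("_")[0], name.split("_")[-1]
    tag = "PLANTED NODE" if f"{kind}_{node}" in planted_nodes else ""
    print(f"  {name:30s} FI = {fi[i]:.4g}  {tag}")
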