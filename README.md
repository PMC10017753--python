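# connsae

Graph-topological connectome features + a semi-supervised autoencoder for
discriminating children with traumatic brain injury (TBI) from matched
controls, and for relating the discriminative brain features to
attention-symptom severity.

## The problem

Paediatric TBI frequently leaves attention deficits whose neural substrate is
distributed across brain systems rather than localised to single regions.
A systems-level approach represents each subject as two brain networks:

* a **structural network** — 78 anatomical regions, edges weighted by
  probabilistic-tractography streamline counts between them,
  `w_ij = ln(1 + s_ij) / max_kl ln(1 + s_kl)`;
* a **functional network** — 59 task-fMRI regions, edges from Pearson
  correlations of BOLD time series, binarised over the network-cost range in
  which the graph is small-world (sigma = (C/C_rand)/(L/L_rand) > 1.1).

For every node, five topological properties are computed (strength/degree,
nodal global efficiency, nodal local efficiency, clustering coefficient,
betweenness centrality), giving 390 structural + 295 functional = **685
features per subject**.

A **semi-supervised autoencoder** (encoder 60-40-20, decoder 20-40-60,
classifier 20-20-1, sigmoid units throughout) is trained on the top 60
features (selected per CV fold by t-test + mutual information + Lasso,
mean-rank combined) with the composite loss

```
L = 0.7 * MSE(reconstruction) + 0.3 * BCE(classification)
```

so the 20-dimensional latent code ("AE-features") is shaped by
reconstruction and constrained by the diagnosis label.  Feature relevance is
quantified by permutation importance, `FI = (1/m) Σ_k (H − H'_k)²`, the mean
squared change in classification cross-entropy over m column shuffles, with
features above mean + 2 SD flagged important.  Post-hoc analyses relate
important features to Conners 3-PS inattention / hyperactivity T-scores via
cross-validated support vector regression and a bootstrap path model
(features → latents → T-score, adjusted for age, sex, SES, IQ).

The study's MRI data are not publicly deposited, so the package ships a
first-class **synthetic cohort generator**: group-matched demographics,
negative-binomial streamline counts over a shared topology, correlation
matrices from factor-model time series (positive semidefinite by
construction), planted nodal group effects calibrated in Cohen's d, and
planted feature-to-symptom couplings.  All analysis code is agnostic to
whether matrices come from the generator or from files.

## Worked example

```python
from connsae import AEConfig, CohortConfig, generate_cohort
from connsae.pipeline import compute_feature_table
from connsae.ssae import cross_validate_ssae, pca_svm_baseline

cfg = CohortConfig(n_per_group=25, effect_size=1.5,
                   effect_nodes=[("struct", 3), ("struct", 11),
                                 ("struct", 25), ("func", 2), ("func", 17)],
                   seed=4)
cohort = generate_cohort(cfg)
table, meta = compute_feature_table(cohort, seed=0)
X = table.drop(columns="group").to_numpy()
y = (table["group"] == "tbi").to_numpy().astype(float)

cv = cross_validate_ssae(X, y, AEConfig(seed=0), k=5, seed=0)
bl = pca_svm_baseline(X, y, k=5, seed=0)
print(f"SSAE    accuracy {100*cv.accuracy_mean:.2f}% ± {100*cv.accuracy_sd:.2f}%")
print(f"PCA+SVM accuracy {100*bl.accuracy_mean:.2f}% ± {100*bl.accuracy_sd:.2f}%")
```

prints (seed 4 cohort, seed 0 folds):

```
SSAE    accuracy 86.00% ± 11.40%
PCA+SVM accuracy 84.00% ± 5.48%
```

i.e. on this 50-subject cohort with five planted nodal effects of d = 1.5 the
autoencoder separates the groups well above chance and edges out the
conventional PCA+SVM baseline evaluated on identical folds.  The
`examples/` directory has one narrative script per capability (cohort
simulation, network construction, training, importance, brain-behaviour,
full pipeline), each printing the numbers it computes and what they mean.

A thin CLI wraps the pipeline: `connsae run-all -c config.yaml --seed 7`
writes `report.json` (versioned schema) and a human-readable `summary.txt`.

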