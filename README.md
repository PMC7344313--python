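# ginfc — GIN classification and saliency mapping of functional connectomes

`ginfc` classifies subjects from the graph structure of their resting-state
functional connectome and maps which brain regions drive the decision.  It is
aimed at network-neuroscience researchers who have per-subject ROI time-series
(or precomputed connectivity matrices), a parcellation table, and a binary
phenotype label, and who want both a cross-validated classifier and a
region-level, neuroscientifically interpretable saliency map.

## The model

**Graph construction.** For each subject, functional connectivity between
regions *i* and *j* is the Pearson correlation of their mean BOLD time-series,
R_ij = Cov(y_i, y_j) / (σ_{y_i} σ_{y_j}).  The connectivity matrix is
thresholded by sparsity — the top *M*-percentile of upper-triangle values
become unweighted, undirected edges — and each node carries a one-hot encoding
of its region identity, so the graph topology alone distinguishes subjects.
Subjects with framewise displacement above 0.3 mm at any frame are excluded.

**Classifier.** A Graph Isomorphism Network (GIN).  Layer *k* updates node
features by

    p_v = MLP( (1 + ε) · p_v + Σ_{u ∈ N(v)} p_u ),

equivalently in matrix form X ← σ((c·I + A) X W) with c = 1 + ε, each MLP
stage followed by batch normalization and ReLU.  Node features are sum-pooled
per layer and concatenated across layers into a graph feature, mapped by a
dropout-regularized linear head to class logits.  Training minimizes
cross-entropy plus λ times an Infomax regularizer: a bilinear discriminator
learns to tell matched (node, graph) embedding pairs from pairs corrupted
across the minibatch, encouraging the readout to preserve mutual information
with node features.

**The shift-operator duality.** With c·I + A in place of the cyclic shift
matrix S, the GIN layer is exactly a two-tab convolutional layer
X ← σ((c·X + S X) W); the adjacency matrix acts as a generalized shift
operator.  `ginfc.gin.verify_cnn_duality` checks this identity numerically.
The duality justifies CNN-style saliency mapping on the trained network.

**Saliency.** Grad-CAM at layer *k* weights feature channels by node-summed
gradients of the target-class logit, α_j = Σ_i ∂y/∂X_ij, and maps nodes by
S = Σ_j α_j x_j.  With one-hot inputs the input-layer map reduces to column
sums of the input gradient — a direct per-region importance score.  Group maps
average subject maps per class, are min–max normalized to [0, 1], and the top
5-percentile regions are extracted; robustness is the percentage of top
regions from subject subsets that match the full-group set.  A CAM baseline
(mean-pooling head) is provided for comparison.

Because suitable benchmark cohorts are access-restricted, the package ships a
synthetic-cohort generator: two groups of multivariate-normal ROI time-series
whose correlation structure differs only on a planted subset of regions, so
classification accuracy and saliency recovery have a known ground truth.

## Worked example

```python
import numpy as np
from ginfc import CohortSpec, generate_cohort, GinConfig, TrainConfig, ConnectomeGIN

spec = CohortSpec(
    n_subjects_per_class=30, n_regions=20, n_timepoints=120,
    planted_regions=frozenset(range(4)), effect_size=0.6, seed=5,
    fd_spike_prob=0.0,
)
cohort = generate_cohort(spec)

model = ConnectomeGIN.from_timeseries(
    cohort.time_series, cohort.labels, sparsity_percent=30.0,
    gin_config=GinConfig(n_layers=2, hidden_units=16),
    train_config=TrainConfig(epochs=60, batch_size=16, n_folds=4, seed=2),
)
results = model.cross_validate()
print(results.summary())
print(f"silhouette: {results.silhouette():.3f}")

analysis = results.saliency_analysis(class_filter=1, percentile=20.0)
print("top salient regions:", sorted(int(i) for i in analysis["top_regions"].region_indices))
print(f"one-fold robustness: {analysis['robustness_one_fold'].mean:.1f}%")
```

Output:

```
Connectome GIN cross-validation
=============================================
subjects: 60   folds: 4
layers: 2   hidden units: 16   lambda_infomax: 0.05
---------------------------------------------
accuracy :  88.33 ± 8.66 %
precision:  89.48 ± 6.38 %
recall   :  86.61 ± 13.45 %
  fold 0: acc  80.00%  prec  83.33%  rec  71.43%
  fold 1: acc 100.00%  prec 100.00%  rec 100.00%
  fold 2: acc  80.00%  prec  85.71%  rec  75.00%
  fold 3: acc  93.33%  prec  88.89%  rec 100.00%
silhouette: 0.069
top salient regions: [0, 1, 2, 3]
one-fold robustness: 87.5%
```

The classifier separates the two groups (88% mean held-out accuracy on a
60-subject cohort), the silhouette score quantifies how well the learned graph
embeddings cluster by class, and the four planted regions (indices 0–3) are
exactly the four most salient regions in the group map — the saliency pipeline
recovers the ground-truth discriminative subnetwork.

## Command-line pipeline

The same analysis runs from the shell, one stage per subcommand:

```sh
ginfc simulate      --out cohort/ --n-per-class 50 --n-regions 50 --seed 7
ginfc build-graphs  --cohort cohort/ --out graphs/ --sparsity 30
ginfc train         --graphs graphs/ --out train/ --n-folds 5
ginfc saliency      --graphs graphs/ --train-out train/ \
                    --parcellation cohort/parcellation.tsv --out saliency/
ginfc report        --train-out train/
```

Every output embeds the config hash and seed; a YAML config file can supply
any option, and flags override it.

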