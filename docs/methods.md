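# Methods

## Scope and model

`ginfc` implements a complete analysis chain for binary classification of
subjects from functional-connectome graphs, with region-level attribution:

1. **Connectivity.** Pearson correlation between regional mean BOLD
   time-series (sample moments, T ≥ 3, zero-variance regions rejected with the
   offending region named).  The correlation matrix is symmetric with unit
   diagonal by construction.
2. **Graph.** The top *M*-percentile of the N(N−1)/2 upper-triangle
   connectivity values become unweighted undirected edges.  Ranking is by
   **signed** value (most-positive first); magnitude ranking is available via
   `use_absolute=True`, since either reading of "top percentile" is defensible.
   Ties break deterministically by (row, column) index; the edge budget is
   round-half-away-from-zero of M/100 · N(N−1)/2, which makes the edge count
   exactly reproducible across platforms.  No self-loops are added: the GIN
   update's (1+ε)·I term supplies the self-contribution.
3. **Node features.** One-hot region identity (the N×N identity) by default,
   so the classifier sees topology only.  Alternatives: per-region mean BOLD
   (N×1), centroid coordinates (N×3), and dimension-matched coordinates (N×3
   plus a linear map to width N learned with the model) — included because
   they are the natural ablations of the one-hot choice.
4. **Classifier.** GIN with K layers (default 5) of width C (default 64);
   each layer is a depth-2 MLP whose stages are followed by batch
   normalization and ReLU; ε is learnable per layer, initialized at 0.
   Readout sums node features per layer and concatenates layers 1..K (the
   layer-0 encoding is identical across subjects and is excluded; the literal
   0..K concatenation is available via `include_layer0_readout`).  A linear
   head with dropout 0.5 (training only) produces two logits.
5. **Training.** Adam, 150 epochs, learning rate 0.005 decayed ×0.8 every 5
   epochs, minibatch 32, loss = cross-entropy + λ·Infomax with λ = 0.05.  The
   Infomax term is the binary log-loss of a bilinear discriminator
   D(p_v, p_G) = σ(p_vᵀ B p_G) on matched versus corrupted (node, graph)
   embedding pairs; node embeddings come from the final GIN layer, corruption
   swaps node embeddings across the minibatch by a seeded cyclic shift (a
   derangement for any batch ≥ 2), and the loss is normalized by the total
   term count so an indifferent discriminator scores log 2.  The published
   formulation states a log-likelihood to maximize inside a minimized
   objective; we minimize its negative, which is the consistent reading.
   Evaluation is deterministic (dropout off, batch-norm running statistics).
6. **Cross-validation.** Stratified k-fold (default 10), per-fold training
   with fold-specific seeds, metrics reported as mean ± sd over folds.
   Precision/recall are computed against a configurable positive class
   (default 1); a fold predicting no positives reports precision 0 with an
   explicit flag.  Embedding quality is summarized by the silhouette score of
   held-out graph features.
7. **Saliency.** Grad-CAM with channel weights α_j = Σ_i ∂y/∂X_ij (y the
   pre-softmax target logit — numerically stabler than post-softmax and
   standard practice) and map S = Σ_j α_j x_j.  No rectification is applied to
   gradients or maps; negative saliency survives until the group-map min–max
   normalization.  At the input layer with one-hot features the map is exactly
   the column sums of the input gradient, and the implementation realizes the
   identity bit-for-bit (same code path).  Group maps are averaged per class
   using true-class logits (configurable to predicted), because per-class
   reporting is the only reading consistent with separate per-class saliency
   tables; a constant group map normalizes to zeros with a warning rather than
   erroring.  Top-percentile selection takes floor(p/100·N) regions, ties by
   index (400 regions at the 5th percentile give exactly 20).  Robustness is
   the percentage of a subset's top regions matching the full-group set,
   reported for single folds and for two half-cohort aggregates.

## Differentiation core

No automatic-differentiation library is part of the package's dependency set,
so `ginfc.autodiff` provides a small reverse-mode engine on float64 numpy
arrays (broadcasting arithmetic, batched matmul, reductions, ReLU/sigmoid/
softplus/log-softmax, batch gathering, concatenation).  It exists because both
training and Grad-CAM need exact gradients of the same forward pass; every op
is finite-difference tested, and Grad-CAM correctness is additionally checked
end-to-end against central differences (step 1e-4, relative tolerance 1e-4).

## Synthetic cohorts

The generator emulates multi-subject ROI time-series with a known group
difference.  Class 0 draws T×N samples from a compound-symmetric correlation
matrix Σ0 = (1−ρ)I + ρJ (baseline inter-regional correlation ρ = 0.1);
class 1 adds `effect_size` to every off-diagonal entry within a planted region
subset, then projects to the nearest valid correlation matrix (eigenvalue clip
at 1e-6, rescale to unit diagonal).  Sampling is by Cholesky factor with a
seeded generator, so cohorts are bitwise reproducible.  A scalar framewise-
displacement series is generated independently (baseline uniform 0.02–0.25 mm,
spikes > 0.3 mm with per-frame probability 0.001, ≈18% subject exclusion at
T = 200, the same order as real cohort exclusion rates); it exists only to
exercise the exclusion rule.  The synthetic parcellation assigns unique
labels, an L/R split at the halfway index, the seven canonical functional
networks cycled, and uniform centroids in a cortical bounding box.

What the generator does **not** emulate: hemodynamic autocorrelation, scanner
noise spectra, spatially structured motion artifacts, site effects, or
realistic network topology beyond the planted block.  Passing tests therefore
demonstrate that the pipeline recovers a known correlational group difference
under idealized noise — not performance on real fMRI.

## Validation experiment

The recovery experiment (`ginfc.experiments`) fixes desk-scale study
conditions: 100 subjects per class, 50 regions, 200 timepoints, a 6-region
planted subnetwork with effect 0.4, sparsity 30%, a 3-layer/32-unit GIN with
λ = 0.05, 5-fold CV, 150 training epochs.  Measured outcomes are the CV
accuracy (expected well above 90%), the overlap of the top-6 salient regions
with the planted set and its exact hypergeometric tail probability (chance
would give mean overlap 0.72 of 6), robustness ratios, and a null cohort
(effect 0) whose accuracy should sit within binomial noise of 50%.

## Numerical choices and edge cases

- Everything runs in float64; the node-wise/matrix layer identity holds to
  ~1e-14 and is asserted at 1e-10.
- Batch normalization acts over the (graph, node) axes per channel — the
  natural reading when graphs are batched; running statistics use momentum
  0.1 with the unbiased-variance correction.
- Isolated nodes: normalized-Laplacian rows follow the identity-row
  convention (the D^{−1/2} term is taken as 0), avoiding division by zero;
  the combinatorial Laplacian and the GIN itself need no convention.
- A trailing minibatch of size 1 is merged into the previous batch when the
  Infomax term is active, since corruption needs a partner graph.
- Non-finite training loss raises immediately with the epoch index.
- Checkpoints are self-describing `.npz` archives (config JSON + parameter and
  batch-norm state arrays) with an exact save/load round trip.

## Known limitations

- Graphs in one model must share the node count and parcellation; there is no
  cross-parcellation alignment.
- The saliency cutoff (top 5-percentile) is a heuristic, not a statistical
  threshold; no significance testing of individual regions is performed.
- Training is CPU-only and single-threaded beyond BLAS; cohorts of a few
  hundred subjects at ≤ 400 regions are the intended scale.
- The Infomax discriminator sees final-layer node embeddings only; feeding all
  layers is a possible extension, not implemented.
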