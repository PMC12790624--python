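# Methods

## Model

`driverfusion` scores genes for driver likelihood by transductive node
classification on a fixed multi-view gene graph. The architecture has four
stages:

1. **Multi-view encoding.** One two-layer GCN per network view (PPI, GO
   semantic similarity, KEGG pathway co-occurrence) over the shared
   z-scored feature matrix, followed by softmax attention fusion across
   the three view embeddings. The fusion weights α_i are exposed per gene
   as the interpretability signal.
2. **Functional embedding.** A gene-set attention block
   A = row-softmax(M W^attn), E^gene = A E^set over the binary gene × set
   membership matrix M. W^attn and E^set are trained with the model.
3. **Structural encoding.** Frozen inputs from the PPI view only: PCA
   scores of the row-stochastic random-walk matrix T = D⁻¹A
   (the positional block e^rw) and PageRank centrality (e^pr).
4. **Biased transformer.** The concatenated input
   [x | z^fusion | E^gene | e^rw | e^pr] is linearly projected to width d
   and passed through L transformer layers attending over all N genes.
   Each head's pre-softmax logits receive an additive edge-attention bias
   b_ij = Σ_m σ(W^edge [score_ij^(m), 1] + b^edge) over the views in which
   the pair (i, j) is connected. A sigmoid head yields ŷ_i ∈ [0, 1].

Assumptions: the three views share one gene universe (defined by the PPI
node set); unlabeled genes participate in message passing and attention but
not the loss; networks are static and undirected; edge scores live in
[0, 1] and are comparable within a view.

## Parameters that matter

| Parameter | Default | Meaning / rationale |
|---|---|---|
| d | 128 (32 for synthetic benchmarks) | shared embedding width of all learned blocks |
| L, H, dropout | 3/4/0.1 (`pan_cancer`), 2/2/0.2 (`cancer_specific`) | transformer depth/heads; the smaller preset suits few-positive label sets |
| lr, epochs | 1e-3/30 (`pan_cancer`), 1e-4/50 (`cancer_specific`) | AdamW, one full-batch step per epoch |
| weight decay | 1e-4 | decoupled (AdamW); not applied to biases/layer-norm |
| focal α, γ | 1.0, 1.5 | class-imbalance reweighting of cross-entropy |
| edge thresholds | PPI 0.85, GO 0.8, pathway 0.6 | minimum confidence for an edge to exist |
| PageRank damping | 0.85 | standard teleport rate |
| d_rw | d, capped at N−1 | width of the random-walk positional block |
| threshold | 0.5 | classification cutoff for F1 |

## Design choices where the design was open

* **Degree normalization.** The GCN uses symmetric normalization with
  added self-loops, c_ij = √((deg_i+1)(deg_j+1)) — the standard GCN
  convention; row normalization is available via `ModelConfig.gcn_norm`.
  Self-loops are added inside the convolution so genes isolated in a view
  still receive an embedding (the GO/pathway views do not cover all
  genes). No activation follows the second GCN layer, and message passing
  is unweighted by default (edge scores gate existence and feed the edge
  bias); score-weighted aggregation sits behind `gcn_weighted`.
* **Layer-1 width.** The first GCN layer maps F → d: the raw feature width
  F is the only well-typed input dimension for W₁ acting on x_j ∈ ℝ^F.
* **Edge descriptor.** The pairwise descriptor is fixed at k = 2:
  [edge score, existence indicator]. It is isolated behind
  `build_edge_bias` so alternatives are drop-in. Pairs with no edge in any
  view contribute exactly zero bias — "no evidence, no modulation" — which
  makes the EAA-ablated model exactly a vanilla transformer encoder. One
  bias tensor is shared across all layers.
* **Transformer internals.** Post-norm residual blocks, feed-forward width
  4d, GELU activation — unexceptional conventions, stated here because
  nothing in the model definition forces them. Full-graph attention in one
  pass with a memory guard at `n_max` = 20 000 genes.
* **Initialization.** Fan-in-scaled uniform for all weights, zeros for
  biases, seeded. The scoring head (w, b) is zero-initialized: the
  untrained model then outputs a calibrated 0.5 for every gene, and early
  focal-loss training is not dominated by the random projection of an
  arbitrary head — at the small step budgets of the presets (30–50
  full-batch AdamW steps) a random head would otherwise contribute most of
  the final ranking direction.
* **Epochs.** An "epoch" is one full-batch gradient step, the standard
  convention for transductive GCN-family models.
* **PCA details.** The transition matrix is column-centered before the
  SVD (standard PCA); scores are scaled by the component singular values
  ("variance-scaled"; scaling by explained-variance ratio is the noted
  alternative). Each component's sign is fixed so its largest-magnitude
  loading is positive, making the encoding reproducible. Rank-deficient
  columns are zero-padded. Isolated nodes get a self-transition of 1 so T
  stays row-stochastic.
* **Loss masking.** The focal loss is averaged over labeled training genes
  only, with probabilities clamped to [1e-7, 1 − 1e-7]. Alternatives such
  as per-epoch negative subsampling were not adopted.
* **Final model for ranking.** After cross-validation the model is refit
  on all labeled genes to score unlabeled genes; fold models are not
  ensembled.
* **Z-scoring.** Population standard deviation, computed once over the
  whole feature matrix before any train/test split. This matches the
  pipeline convention the package follows; it does share column statistics
  across folds, which is documented rather than "fixed". Constant columns
  and genes missing from the feature table become all-zero rows.
* **Fold assignment.** Stratified k-fold (seeded); stratification is
  required for label sets with very few positives.
* **Ablation semantics.** PE/CE/GSA/EAA/NFE/IF zero the corresponding
  block and remove its parameters. Disabling IF zeroes the shared feature
  matrix, so the GCN encoders also lose their input — the reading of
  "removing the initial features" as removing them from the whole model,
  not only from the concatenation.

## The synthetic generator

`driverfusion.simulate` emulates the statistical shape of the real corpus
so the pipeline is testable without downloads:

* three partially overlapping views from a Chung–Lu expected-degree model
  (lognormal weights, σ = 0.5) with drivers' expected degree multiplied by
  `hub_bias`; a `view_overlap` fraction of PPI edges is copied into the
  other views; scores are uniform above each view's threshold;
* features are standard normal with driver rows shifted by
  `feature_shift` in a random half of the columns;
* gene sets include drivers with probability `set_enrichment` vs a 0.1
  baseline;
* labels follow the ~1 : 2.7 positive-to-negative imbalance of curated
  driver corpora (60 : 160 at the default 500 genes), with the remainder
  unlabeled.

Defaults (`feature_shift=1.5`, `hub_bias=3`, `set_enrichment=0.4`) are the
package's standard benchmark conditions. What it does **not** emulate:
scale-free tails beyond Chung–Lu heterogeneity, the true overlap topology
of STRING/CPDB with GO/KEGG-derived networks, correlated omics features
across cancer types, or hub-structured gene-set nesting. Passing tests on
this generator therefore demonstrate that the implementation learns the
kinds of signal the model is built for — mean-shifted features, hub
centrality, set enrichment — not that it attains any particular accuracy
on real corpora.

## Problem sizes used in tests and the acceptance script

Synthetic benchmarks run at 500 genes with d = 32, 5-fold
cross-validation and 5 seeds (the package's desk-scale choice; the model
definition is unchanged at larger d). The null check uses the same sizes
with all planted signal removed; the ablation grid evaluates AUPRC on a
stratified 25 % held-out split per seed. The novel-candidate arithmetic
runs at 1000 genes.

## Numerical notes

* All computation is float64 numpy; gradients of every autodiff primitive
  are finite-difference checked.
* PageRank: power iteration with uniform teleport and uniform dangling
  redistribution, L1 tolerance 1e-10, max 200 iterations (error on
  non-convergence).
* Ranking ties are broken lexicographically by gene symbol, so prediction
  tables are fully deterministic.
* Eval-mode forwards are bit-reproducible; training is deterministic given
  the seed (all RNG streams derive from one `SeedSequence`).

## Known limitations

* Full-graph attention is O(N²) memory per head; beyond ~20 000 genes the
  model refuses to run rather than silently thrash.
* The transductive design scores only genes present in the training graph;
  there is no inductive mode for unseen genes.
* Gene identifiers are opaque strings; no alias/ID mapping is attempted,
  so inputs must be symbol-harmonized upstream.
* The z-scoring convention shares column statistics across CV folds (see
  above); rankings are unaffected but absolute fold metrics can be
  slightly optimistic.
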