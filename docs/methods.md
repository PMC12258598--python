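# Methods

## Model

Given a nonnegative expression matrix `X ∈ R^{m×n}` (m genes, n
cells/spots), 2-D coordinates and a ligand-receptor table, two variational
graph autoencoders are coupled and trained jointly.

**Graphs.** The spatial graph `A_c` is binary and symmetric with
`A_c(i,j) = 1` iff the Euclidean distance between cells i and j is
*strictly* below a threshold (ties at the boundary excluded; documented so
runs are reproducible).  The threshold is either user-supplied or chosen
by a neighbour-count heuristic: the smallest candidate under which
strictly more than 80% of cells have at least three neighbours, reflecting
that most cells in a 2-D tissue touch several adjacent cells.  The default
candidate grid is 20 log-spaced values between the 1st and 50th percentile
of nonzero pairwise distances; if no candidate qualifies the largest is
returned with a warning.  Coordinates are treated as planar Euclidean and
units are the caller's responsibility (μm on typical imaging platforms,
where radii of tens to hundreds of μm are conventional).

The gene graph `A_g` is directed ligand(row) → receptor(column).  Each
database record, possibly a multi-subunit complex on either side, is
expanded to all ordered (ligand subunit → receptor subunit) gene pairs; an
edge is kept only when both genes are present in the expression matrix and
each is nonzero in at least `min_cells_expressing` cells (default 1 — the
gate is per-gene over the whole dataset, not per-cell co-expression;
"expressed" is otherwise underdetermined).  Records naming absent genes
are skipped and counted, never fatal.

**Encoder.** `GCN(A, X) = Ã ReLU(Ã X W₀) W₁` with
`Ã = D_out⁻¹(A + I)` (out-degree row normalisation; the self-loop
guarantees row sums of exactly 1).  The mean and log-std heads share `W₀`.
The per-node posterior is `N(μ_i, diag(σ_i²))` with a standard-normal
prior; training draws one reparameterised sample per autoencoder per
epoch, inference uses `Z = μ` exactly.

**Decoders.** Each latent code of even dimension d splits into a source
half (first d/2 dims) and a target half; edge probabilities are
`σ(⟨z_i^(s), z_j^(t)⟩)`, generally asymmetric, with the diagonal computed
but excluded from all downstream counts and aggregates.  Expression is
reconstructed per node by a two-layer dense network (ReLU hidden, linear
output — nonnegativity of the output is deliberately not enforced, since
the reconstruction target is a variance-stabilised expression scale).

**Objective (minimisation form).** Per autoencoder, a class-weighted
Bernoulli cross-entropy of the adjacency (`pos_weight = (N²−E)/E`,
`norm = N²/(2(N²−E))`, the standard sparse-graph weighting) replaces the
graph log-likelihood of the ELBO, plus `β ×` KL to the prior, plus the
mean squared expression reconstruction error `‖X − X̂‖_F²/(mn)`.  The
coupling term builds the cosine-similarity matrix `S_ij` between cell i's
reconstructed profile from the cell-level decoder and cell j's from the
gene-level decoder and penalises `mean((S − I)²)`; zero-norm profiles get
similarity 0 by convention (and zero gradient — the point is genuinely
non-differentiable).  All component weights default to 1 and are
configurable.

## Numerical and optimisation choices

- **KL scaling.** The summed KL enters the objective divided by N² (the
  per-node mean divided by N again).  This matches the scaling used by
  widely-deployed VGAE implementations.  With the stronger sum/N scaling
  the persistent prior pull, renormalised by Adam, drags the posterior
  mean into the decoder's `Z = 0` saddle at these problem sizes (n ≈ 200)
  and the model learns nothing — verified in isolation on a pure graph
  autoencoder.  The standalone `kl_divergence` primitive reports the
  per-node mean; `β` rescales the term if a different balance is wanted.
- **Feature standardisation.** Encoder features (expression for gene
  nodes, its transpose for cell nodes) are standardised per column; the
  (center, scale) pairs are stored on the trained model and re-applied at
  inference.  Raw all-positive features let a uniform negative drift kill
  every hidden ReLU unit irrecoverably.  Constant columns keep center 0
  and scale 1, so an all-zero gene remains all-zero.  Reconstruction
  targets stay on the unstandardised scale.
- **log1p transform.** The Model facade models `log1p(X)` by default (the
  field's standard variance stabilisation); configurable via
  `log_transform=False`.  The gene-graph expression gate always uses raw
  values (the zero pattern is unchanged by log1p).
- **Stability.** `log σ` is clamped to |·| ≤ 10 (zero gradient outside);
  probabilities are clipped to [1e-7, 1−1e-7] in the probability-space
  loss, while training uses the logit form, which needs no clipping.
  Decoder biases initialise at 0.01 to keep hidden units alive and
  reconstructed profiles off the zero-norm point.  Weights use Glorot
  uniform initialisation.
- **Optimiser.** Full-batch Adam (lr 0.01, β₁ 0.9, β₂ 0.999), 200 epochs,
  latent dim 16, hidden dim 32 in both the GCN and the expression decoder.
  Gradients are analytic (reverse-mode, hand-derived for this fixed
  architecture) and checked against central finite differences in the
  test-suite at 1e-4 relative tolerance.  Training is bit-deterministic
  given the seed: initialisation and the two sampling streams are spawned
  from one `SeedSequence`.
- **Divergence.** A non-finite loss aborts with a diagnostic naming the
  first non-finite component.

## Downstream analyses

- **Type-level aggregation.** Strength(k→l) = mean decoded probability
  over ordered (type-k cell, type-l cell) pairs, i ≠ j; a single-cell
  type's within-type strength (a mean over zero pairs) is defined as 0 and
  flagged.  Aggregation uses the continuous probabilities; binary calls
  (probability ≥ cutoff, default 0.5, diagonal excluded) are used only for
  edge counts, impact ratios and distance histograms.
- **Permutation test.** The whole label vector is permuted uniformly per
  replicate; `p = (1 + #{permuted ≥ observed}) / (1 + n_perm)`, never
  exactly zero.  Calibration under a label-independent network is checked
  in the acceptance suite.
- **LR-pair impact.** For one gene-graph edge: retrain with the edge
  removed, seed and hyperparameters pinned to the reference run, and
  report `max(0, (E_full − E_pert)/E_full)` over binary sender→receiver
  calls (0 when the reference makes no such calls).  Ranking is by ratio
  descending, ties lexicographic on (ligand, receptor), dense ranks.
- **Gene sensitivity.** Score = |AP_perturbed − AP_baseline| where AP
  ranks all ordered non-diagonal cell pairs by decoded probability against
  the spatial edges.  The default knockout ("zero-mask") pins the gene at
  its training-time mean — exactly zero on the standardised features —
  removing its cell-to-cell variation; masking the raw row instead would
  pass through the pinned standardiser as a −mean/std constant, a
  perturbation *larger* for stable background genes than for variable
  signal genes, which inverts the intended measurement.  An all-zero gene
  scores exactly 0.  A within-gene shuffle mode preserves the marginal
  distribution while destroying the spatial pattern.  The perturbation is
  inference-only (the trained model is reused), keeping the analysis
  deterministic and O(genes) rather than O(genes × retrains).
- **Robustness.** Per replicate, a fraction of undirected spatial edges is
  deleted (or `multiplier × E` fake symmetric edges injected, never
  duplicating existing edges or the diagonal), the model is retrained with
  the seed pinned to the reference run, and the perturbed run's
  probabilities are scored by exact Mann-Whitney AUC.  Default positives
  are the reference run's directed predicted edges with an equal-sized
  (capped by availability) sample of non-predicted pairs as negatives;
  `score_against="removed"` instead scores recovery of the deleted edges
  against sampled non-edges of the original graph.  Replicate seeds derive
  from one base seed, making whole protocols reproducible.  30 replicates
  by default; the acceptance checks use 5 at n = 200 to keep a full run in
  tens of seconds on one CPU.

## Metrics

`average_precision` walks the candidate list ranked by score descending
(ties broken by fixed input order, stable sort) and averages
precision-at-rank over the positives — the area under the precision-recall
curve.  `auc` is the exact Mann-Whitney statistic,
`P(pos > neg) + 0.5 P(tie)`.  Both are validated against explicit-loop
oracles to 1e-10.

## Synthetic data

The generator emulates the statistical premise that neighbouring cells are
more likely to communicate.  Cells of K types are placed as Gaussian blobs
(sd = domain/10) at uniform centres in a square domain; a fixed minority
(default 25%) of ordered type pairs is designated communicating; each
ligand-receptor pair serves one communicating type pair (cycled).  Every
ordered cell pair within the neighbour radius whose types match the design
is a ground-truth edge; its sender multiplies the pair's ligand gene, and
its receiver the receptor gene, by `1 + signal_strength` on top of
background `base_mean_g × LogNormal(0, noise_dispersion)` — so
`signal_strength = 0` reproduces the background exactly, and all values
stay strictly positive.  Defaults: 200 cells, 60 genes, 4 types, 10 LR
pairs, domain 100, radius 15, signal 5, dispersion 0.5 — a small dense
tissue patch whose spatial graph has mean degree ≈ 7 under the automatic
threshold.

What the generator does **not** emulate: count noise (values are
continuous), platform artefacts (optical crowding, spot mixtures, dropout
beyond the explicit `corrupt_expression` utility), 3-D geometry, or
signalling beyond pairwise ligand-receptor gating.  Passing tests
therefore demonstrate that the machinery recovers planted proximity-driven
communication under multiplicative noise — not performance on any real
platform's error structure.

## Known limitations

- Whole-graph training only; no minibatching.  Intended scale is ≤ ~10k
  nodes on a desk machine.
- The LR-impact protocol retrains once per candidate edge; ranking many
  pairs is linear in edges × training cost.
- The type-level permutation test conditions on the decoded network; it
  tests label exchangeability, not generative model fit.
- Spectral clustering of the symmetrised network uses k-means on the
  embedding; with `k = n` the solver degenerates to singletons and larger
  k is rejected.
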