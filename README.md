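# spatialccc

Directed cell-cell communication (CCC) inference from spatial
transcriptomics, for computational biologists who have a gene expression
matrix, 2-D cell/spot coordinates and a CellChatDB-style ligand-receptor
table, and want a weighted, directed communication network between
cells — plus the standard downstream analyses (cell-type aggregation with
permutation significance, ligand-receptor pair ranking, gene sensitivity,
robustness protocols).

## The model

Two variational graph autoencoders are trained jointly, one per data view:

- **Cell/spot level.** A spatial neighbour graph `A_c` connects cells whose
  Euclidean distance is below a threshold (chosen so that >80% of cells
  have ≥ 3 neighbours).  A two-layer directed GCN encoder
  `GCN(A, X) = Ã ReLU(Ã X W₀) W₁` over `Ã = D_out⁻¹(A + I)` produces a
  Gaussian posterior `q(z_i) = N(μ_i, diag(σ_i²))` per cell.
- **Gene level.** A directed gene graph `A_g` carries ligand → receptor
  edges (multi-subunit complexes expanded to gene pairs, gated on both
  genes being expressed); the same encoder architecture embeds genes.

Each latent code splits into a source half and a target half, and the graph
decoder emits directed edge probabilities
`p(Â_ij = 1) = σ(⟨z_i^(s), z_j^(t)⟩)`, so even the symmetric spatial graph
is decoded into an asymmetric communication network.  A two-layer dense
decoder reconstructs the expression matrix from the same codes.  The
objective sums, for each autoencoder, the negative graph ELBO
(class-weighted adjacency cross-entropy plus KL to a standard-normal
prior) and the mean squared expression reconstruction error, plus an
**orthogonal coupling loss**: the cosine-similarity matrix `S` between the
two autoencoders' reconstructed per-cell profiles is driven toward the
identity (`L_orth = mean((S − I)²)`), aligning the two views on every cell
while decorrelating distinct cells.

The decoded cell-level probabilities at the posterior mean are the
communication network.  Downstream: type-level strengths are means of the
probabilities over ordered cell pairs with label-permutation p-values;
ligand-receptor pairs are ranked by the *edge reduction ratio* (fraction of
predicted sender→receiver calls lost when one gene-graph edge is removed
and the model retrained under identical seeds); per-gene *sensitivity* is
the change |ΔAP| in spatial-edge recovery when that gene's profile is
knocked out; robustness is measured by retraining on graphs with edges
deleted or fake edges injected and scoring AUC against the reference run.

Everything is testable offline: `spatialccc.datasets` generates synthetic
tissues with per-type spatial clusters, a known communicating-type design
and ligand/receptor over-expression on ground-truth sender→receiver pairs.

## Worked example

```python
import spatialccc as sc

ds = sc.generate_dataset(sc.SynthParams(seed=0))       # 200 cells, 60 genes
model = sc.CellCommunicationModel.from_synthetic(ds)   # graphs built, "auto" radius
res = model.fit(seed=0)                                # 200 epochs, deterministic
print(res.summary())
```

```
Cell-cell communication model (coupled variational graph autoencoders)
========================================================================
cells: 200    genes: 60    spatial edges: 667 (threshold 6.549)    LR edges: 10
latent dim: 16    hidden dim: 32    epochs: 200    lr: 0.01    seed: 0
------------------------------------------------------------------------
component          initial       final
graph_g            11.1799      0.0662
kl_g               10.0261      0.2367
expr_g              3.8950      0.2338
graph_c             1.9293      0.1263
kl_c                0.0426      0.1389
expr_c              1.2524      0.2900
orth                0.0180      0.2148
total              28.3432      1.3068
------------------------------------------------------------------------
strongest type-level communications (sender -> receiver):
  T1 -> T1: 0.3210
  T3 -> T3: 0.2805
  T4 -> T4: 0.2305
  T2 -> T2: 0.2258
  T3 -> T4: 0.1567
```

The total loss falls from 28.3 to 1.31 over 200 epochs.  The strongest
type-level strengths are the average decoded probabilities over ordered
cell pairs; within-type and spatially adjacent type pairs dominate, as
expected for proximity-driven communication.  Significance comes from
label permutations:

```python
ct = res.cell_type_communication(n_perm=500, seed=1)
ct.pvalue          # 4 x 4 sender -> receiver p-values, e.g. T3 -> T4: 0.0020
```

The decoded network separates true spatial edges from non-edges with
AUC ≈ 0.996 (`sc.auc` on edge vs sampled non-edge probabilities), and
`res.gene_sensitivity()` ranks the ligand/receptor genes that carry the
planted signal ~2-3x above background.

A CLI mirrors the library:

```sh
spatial-ccc simulate --out data/ --seed 0
spatial-ccc train --expression data/expression.tsv --coords data/coordinates.tsv \
    --lr data/lr_pairs.tsv --checkpoint model.npz
spatial-ccc infer --expression data/expression.tsv --coords data/coordinates.tsv \
    --labels data/labels.tsv --checkpoint model.npz --out results/
```

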