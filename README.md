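# mirlink

Multi-view graph-autoencoder link prediction for miRNA–disease association
networks.

## The problem

Dysregulated microRNAs (miRNAs) are implicated in many human diseases, but
experimentally validating an individual miRNA–disease association is slow and
expensive. Computational link prediction ranks the unknown cells of the
binary association matrix so that wet-lab effort can be spent on the most
promising candidates. Many existing predictors depend on external similarity
resources (miRNA functional similarity, disease semantic similarity), which
cover only part of the catalogue; `mirlink` uses **only the known association
matrix** as input, so every miRNA and disease in the catalogue can be scored.

## The model

Let `A ∈ {0,1}^{m×n}` be the association matrix over `m` miRNAs and `n`
diseases. Node embeddings are learned from three graph views over the joint
node set:

- **Local view** — the bipartite graph in block form,
  `A_local = [[I_m, A], [Aᵀ, I_n]]`; message passing reaches first-order
  association neighbours.
- **Global view** — a fully connected (all-ones) graph; propagation is a
  near-uniform mean over all nodes and supplies non-local context.
- **Semantic view** — metapath-induced homogeneous networks: miRNAs linked
  iff they share a disease (`A·Aᵀ > 0`), diseases linked iff they share a
  miRNA (`Aᵀ·A > 0`), each with its own encoder.

Each view is encoded by a graph autoencoder whose encoder stacks three
GCN–MLP blocks

```
H_l = ReLU( D̃^{-1/2} (adj + I) D̃^{-1/2} · H_{l-1} · W_gcn + MLP(H_{l-1}) )
```

(the parallel MLP branch counteracts over-smoothing), and whose decoder
reconstructs the view adjacency via `σ(Z·Zᵀ)` under mean binary
cross-entropy. Initial node features are the association profiles (rows of
`A_local`, `A`, or `Aᵀ`).

For a pair `(i, j)` the views are fused into one feature vector

```
F = concat( z_mdm[i],  (z_local[i] ⊕ z_local[j]) + (z_global[i] ⊕ z_global[j]),  z_dmd[j] )
```

(`⊕` = concatenation; width `4·d` at latent width `d`), which a **cascaded
attention classifier** scores: three tapering fully-connected layers produce
hierarchical features, a softmax layer attention mixes the three levels, a
gate-structured feature attention refines the fused vector, and a sigmoid
head outputs the association probability. Training minimizes

```
L = BCE(classifier) + λ · Σ_view BCE(reconstruction)
```

jointly with Adam. Evaluation follows the standard protocol: equal-size
negative sampling from the unknown cells, stratified k-fold cross-validation
with the held-out positives **masked out of every training-view adjacency**,
and AUC / AUPR / accuracy / precision / recall / F1 on the held-out folds.

## Worked example

```python
from mirlink import (SyntheticSpec, generate_planted_dataset,
                     dataset_stats, run_cross_validation)
from mirlink.model import synthetic_preset

ds, truth = generate_planted_dataset(SyntheticSpec())   # 120 x 90, planted rank 4
print(dataset_stats(ds).to_json())
cv = run_cross_validation(ds, synthetic_preset(), k=5, seed=1)
print(cv.summary())
```

prints

```
{
  "known": 321,
  "n_disease": 90,
  "n_mirna": 120,
  "sparse_ratio": 0.0297,
  "unknown": 10479
}
5-fold cross-validation (views: local, global, semantic, attention: on)
  auc        0.9088 +- 0.0275
  aupr       0.9041 +- 0.0393
  accuracy   0.7803 +- 0.0474
  precision  0.8708 +- 0.0413
  recall     0.6633 +- 0.1288
  f1         0.7454 +- 0.0789
```

The synthetic world has 321 known associations (sparse ratio ≈ 0.03, the
sparsity of the curated human catalogues). Mean held-out AUC ≈ 0.91 means
the model ranks a random held-out true association above a random sampled
negative about 91% of the time — most of the planted low-rank structure is
recovered from the masked binary matrix alone (the noiseless ceiling, scoring
by the true propensity, is ≈ 0.97).

The same pipeline runs from the shell:

```
mirlink simulate --outdir sim/                 # write a synthetic pair list
mirlink stats sim/associations.tsv             # known/unknown counts, sparse ratio
mirlink cv sim/associations.tsv --k 5 --lr 1e-3 --latent-dim 64 --outdir cv/
mirlink train sim/associations.tsv --outdir run/
mirlink rank sim/associations.tsv run/checkpoint.json disease-007 --top-k 30
mirlink ablate sim/associations.tsv --outdir ablation/   # view x attention grid
```

`mirlink cv`/`ablate` write per-fold and mean metrics as JSON/CSV plus the
fold assignment and the resolved configuration, so any run can be reproduced
exactly from its output directory.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it generates the default planted synthetic dataset, performs 5-fold
cross-validation of the full model and of its local-only and no-attention
ablations, prints their mean AUC/AUPR to stderr, and writes the results JSON
to `--out`:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
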