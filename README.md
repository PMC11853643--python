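# gitdsp

Prediction of circRNA–disease associations (CDAs) from a multi-source
heterogeneous knowledge graph, using a graph-isomorphism transformer
(GIT) for representation learning and a dual-stream neural predictor
(DSP) for pair scoring.

## The problem

Circular RNAs regulate disease processes, but experimentally verified
circRNA–disease links are scarce: typical catalogues hold a few hundred
associations over tens of thousands of candidate pairs, and most diseases
are linked to ten or fewer circRNAs. `gitdsp` is aimed at computational
biologists who want to prioritize candidate CDAs for experimental
follow-up. It counters the sparsity by pooling five association layers —
circRNA–disease, circRNA–miRNA, miRNA–disease, lncRNA–miRNA and
lncRNA–disease — into one knowledge graph G = (E, R) of typed triples
(h, r, t), augmented with inverse relations and self-loops.

## The model

Three stages, trained in sequence:

1. **Knowledge representation learning.** Entities and relations get
   d-dimensional embeddings; a Transformer encoder processes each
   sequence [e_h, e_r] and the relation-position output ê_r scores a
   triple through the bilinear form f(h,r,t) = ê_rᵀ W_r e_t. Training
   minimizes the BPR ranking loss L1 = −Σ ln σ(f⁺ − f⁻) with
   similarity-aware negative sampling (the 7 most GIP-similar entities to
   the true tail are never used as negatives).
2. **Knowledge-aware propagation.** Four layers of attention-weighted
   message passing, θ(h,r,t) = softmax_{N_h}((W_r e_t)ᵀ tanh(W_r e_h + e_r)),
   feed a Graph Isomorphism Network update
   e_h ← LeakyReLU(MLP((1+ε)·e_h + Σ θ e_t)); sum aggregation preserves
   the neighbor multiset (GCN / GraphSage / Bi-Interaction and mean / max
   reductions are available as ablations).
3. **Dual-stream prediction.** Per-layer embeddings are concatenated
   (e_c ‖ e_d, width 6016 at full scale) and scored by two parallel MLP
   streams ([6016, 3008, 1504, 752] and [6016, 6016, 3008]) whose outputs
   fuse into ŷ ∈ (0,1), trained with BPR plus an L2 penalty:
   L = L1 + L2 + λ‖α‖².

Evaluation follows the strict link-prediction convention: five-fold
cross-validation over the known positives, with **all** unobserved pairs
as negative candidates (AUC with ties ½, step-integrated AUPR, Acc /
Rec / Pre / F1 at ŷ ≥ 0.5, and global Top-K hit counts).

Everything runs on plain numpy (a small built-in reverse-mode autodiff
tape); no GPU or deep-learning framework is required.

## Worked example

No real dataset ships with the package; the synthetic module generates
knowledge graphs with planted low-rank structure at the shape and sparsity
of a published non-cancer benchmark (79 diseases, 330 circRNAs, 404
lncRNAs, 265 miRNAs, 1327 associations):

```python
from gitdsp import GitDsp, generate, scaled_config, SyntheticConfig
from gitdsp.experiments import held_out_recovery

synth = generate(SyntheticConfig(seed=1))          # 3,594 triples
model = GitDsp(**scaled_config(seed=1).estimator_kwargs())
result = held_out_recovery(synth, model)           # fits, then scores
print(f"held-out AUC  {result.auc:.4f}")
print(f"held-out AUPR {result.aupr:.4f}")
print(f"chance control {result.permuted_label_auc(seed=42):.4f}")
```

```
held-out AUC  0.8961
held-out AUPR 0.0904
chance control 0.4881
```

The model ranks the 69 held-out circRNA–disease pairs against all ~25,700
unobserved pairs with AUC ≈ 0.90 — the planted cross-layer structure is
recovered from indirect evidence — while permuting the evaluation labels
collapses performance to chance, confirming the metric pipeline carries no
bias. The AUPR of 0.09 is ~34× the positive prevalence (0.0027), the
informative scale under this extreme class imbalance.

The same pipeline is scriptable from the shell:

```bash
gitdsp synth --seed 1 --out-dir data/
gitdsp build-kg --assoc-dir data/ --catalog data/catalog.tsv --out kg.tsv
gitdsp run --data-dir data/ --out-dir runs/        # 5-fold CV + predictions
gitdsp run --data-dir data/ --out-dir runs/ --sweep reduction
gitdsp eval --checkpoint runs/checkpoint-default.npz --out scores.tsv
```

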