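# Methods

## Problem setting

Curated circRNA–disease association (CDA) catalogues are extremely sparse:
a few hundred verified links over tens of thousands of candidate pairs,
with most diseases linked to ten or fewer circRNAs. `gitdsp` predicts new
CDAs by embedding a *multi-source heterogeneous knowledge graph* that
augments the circRNA–disease layer with circRNA–miRNA, miRNA–disease,
lncRNA–miRNA and lncRNA–disease associations, so that indirect evidence
(e.g. a circRNA and a disease sharing miRNA partners) supports pairs that
have never been observed directly.

## Model

### Knowledge graph

Entities are typed (disease, circRNA, lncRNA, miRNA) and namespaced on load
(`dis:…`, `circ:…`) so identifiers cannot collide across types. Every base
triple (h, r, t) is mirrored by an inverse triple (t, r′, h) under a
distinct relation index — attention transforms therefore differ per
direction — and every entity carries exactly one self-loop under a single
shared self relation. The shared (rather than per-relation) self relation is
a deliberate choice: the self-loop's job is to keep every neighborhood
non-empty (isolated entities still propagate), while the GIN update supplies
the weighted self term separately through its (1+ε) factor.

### Representation phase (Transformer KRL)

Entities and relations share an embedding width d (2048 at full scale).
For each triple the length-2 sequence [e_h, e_r] passes through a
Transformer encoder: multi-head scaled dot-product self-attention with
residual + layer normalization, then a ReLU feed-forward block with
residual + layer normalization. The relation-position output ê_r carries
head context; the head position is discarded. Triples are scored by the
bilinear form

    f(h, r, t) = ê_rᵀ W_r e_t

with one d×d matrix per relation (the printed form of the scoring rule is
dimensionally ambiguous; the bilinear reading matches "relational matrix
multiplication" and yields a scalar). The tail uses its *initial* embedding.
Training minimizes the Bayesian personalized ranking loss
L1 = −Σ ln σ(f_pos − f_neg) with one corrupted tail per positive per epoch.

Corruption is *similarity-aware*: negative tails are drawn uniformly from
entities of the true tail's type, excluding (a) observed tails of the same
(head, relation) and (b) the 7 entities most similar to the true tail under
a Gaussian interaction profile (GIP) kernel over association profiles.
This exclusion is essential, not cosmetic: with plain uniform corruption
the ranking gradient actively pushes apart entities that belong together
(a near-duplicate of the true tail is trained down every time it is drawn),
and on synthetic data with planted structure the learned embeddings end up
*anti*-correlated with the ground truth. Excluding near-duplicates restores
the signal.

### Propagation phase (knowledge-aware attention + GIN)

Each of L = 4 layers computes, per triple, a knowledge-aware attention
score θ(h,r,t) = (W_r e_t)ᵀ tanh(W_r e_h + e_r), softmax-normalized over
the head's neighborhood N_h (tanh applied to the sum, as printed; W_r here
is a per-layer, per-relation map to the relation space, distinct from the
scorer matrix). The ego-network embedding is the reduction of θ-scaled
neighbor embeddings — Sum by default; Mean and Max are ablation
alternatives — followed by the GIN update

    e_h ← LeakyReLU(MLP((1+ε)·e_h + e_N))

with a learnable scalar ε per layer and a single affine map per layer
(printed MLP depth is unspecified; depth 1 is the parsimonious choice and
is configurable). GCN, GraphSage and Bi-Interaction updates are provided
for ablation, exactly as printed. Layer widths default to 512-256-128-64 on
top of the KRL width; the weighted-sum form with normalized θ is the
operative aggregation, with the unweighted sum recovered as its special
case under uniform attention (all-zero W_r).

### Prediction phase (dual-stream predictor)

Per entity, all stages e^(0)…e^(L) are concatenated (width d + Σ widths =
3008 at full scale); a pair is the circRNA and disease concatenation
(width 6016). Two parallel MLP streams read the pair vector — Stream 1
narrowing 6016-3008-1504-752, Stream 2 shallow-wide 6016-6016-3008 — and a
single affine fusion head + sigmoid maps their concatenation to ŷ ∈ (0,1)
(the printed architecture gives stream widths but not the head; one layer
is the minimal consistent reading). Training uses the same BPR form,
L2 = −Σ ln σ(ŷ_pos − ŷ_neg), plus an L2 parameter penalty λ‖α‖²
(λ defaults to 1e-5; its value is not printed).

Negatives are drawn per positive at a 1:10 ratio, in *both* directions
(`neg_mode="mixed"`, the default): half corrupt the circRNA within the
positive's disease, half corrupt the disease of the positive's circRNA,
each excluding the 7 most-similar entities to the true partner (GIP kernel;
for circRNAs fused with a functional-similarity matrix when one is
supplied, taking the functional value wherever it is defined and positive).
Single-direction corruption trains a ranking that is only calibrated within
one margin of the score grid; on planted synthetic data the mixed scheme
raises held-out AUC from ≈0.72–0.76 to ≈0.85–0.96 at the scaled profile.

The two phases are sequential by default (embeddings frozen during
prediction-phase training, which optimizes L2 + λ‖α‖² over propagation and
predictor parameters); this matches the separately-stated per-phase
hyperparameters (100 epochs at lr 1e-4, then 32 epochs at lr 5e-4 with
weight decay 1e-7).

## Evaluation conventions

Five-fold cross-validation partitions the known positives; each fold's
positives are removed from the training graph and every unobserved
circRNA–disease pair of the catalog serves as a negative candidate — the
strictest common convention, and the reason AUPR is small in absolute terms
in this field. AUC counts ties as ½; AUPR uses non-interpolated step
integration (average precision). Classification metrics use the fixed
operating point ŷ ≥ 0.5; metrics with zero denominators are reported
absent rather than zero. Top-K counts held-out positives among the K
highest-scoring candidates of the global ranked list (a per-disease ranking
is also available); ranking ties break by ascending circRNA index. A
leakage guard asserts on every run that no test positive appears in the
fold's training triples.

## Synthetic data

No real dataset ships with the package; the generator emulates the shape
of a published non-cancer benchmark: 79 diseases, 330 circRNAs, 404
lncRNAs, 265 miRNAs, and 1327 associations split 346/146/106/202/527
across the five layers (scaled proportionally by largest remainder for
other budgets). Every entity draws a latent factor: a noisy membership
direction over `latent_rank = 8` functional modules, scaled by a lognormal
activity level (σ = 0.9, direction noise 0.3). Each layer's associations
are the top-scoring latent pairs up to the layer budget; 5% are rewired
uniformly (label noise) and 20% of circRNA–disease positives are held out
as recovery targets. The activity term makes degree distributions
heavy-tailed the way curated data is — about 85% of diseases have ≤ 10
circRNA partners, hubs exist, and held-out edges (which are degree-biased
by construction) usually leave their circRNA connected through other
layers.

What the generator does *not* emulate: identifier nomenclature, sequence or
ontology features, database-specific curation biases, and the much larger
cancer/multi-source benchmarks. Passing the recovery tests therefore shows
that the pipeline can extract planted low-rank, cross-layer structure at
realistic sparsity — not that it attains any particular accuracy on real
catalogues.

### Controls

Two controls are distinguished deliberately. Permuting the *evaluation*
labels over candidate pairs is the no-signal baseline: expected AUC is
exactly 0.5, and deviations measure Monte-Carlo error only. Shuffling the
*training* circRNA–disease layer is **not** a chance baseline for this
model class: degree marginals are preserved and the other four association
layers still carry genuine cross-layer information about held-out pairs, so
a working multi-source model measurably beats 0.5 under that manipulation
(≈0.86 observed at the scaled profile). That behaviour is the premise of
the method — multi-source evidence compensates for missing direct links —
and is exposed as an experiment (`experiments.shuffle_circ_dis`) rather
than used as a pass/fail control.

## Scaled profile and problem sizes

Tests and the reproduction script use a reduced profile chosen once:
d = 64, 4 heads, FFN width 64, propagation widths 32-16-8-8 (pair width
256), 30 representation epochs and 16 predictor epochs on the default
synthetic shape (~1,100 entities, ~3,600 triples, ~26,000 scored pairs).
All formulas, both training phases, attention, and the dual-stream head are
identical to the full-scale model. Because 30/16 epochs at these widths
barely move parameters under the full-scale learning rates, the profile
uses lr 1e-2 (representation) and 5e-3 (prediction) with predictor
minibatches of 128 — set by watching training-loss descent. One end-to-end
run takes well under a minute on a single CPU core.

## Numerical choices

* All computation is dense `float64` on a purpose-built reverse-mode
  autodiff tape (`gitdsp.autodiff`); gradients are verified against central
  finite differences (tolerance 1e-4) in the test-suite.
* Adam (β = 0.9/0.999, ε = 1e-8) with decoupled weight decay; the
  representation phase halves its learning rate when the epoch loss fails
  to improve for 5 epochs (the monitored quantity is the training loss; no
  validation split is carved out of the graph).
* Xavier-uniform initialization everywhere, seed-controlled; every source
  of randomness (init, corruption, dropout, fold splits) derives from the
  single `random_state`/`seed`, making runs bit-reproducible.
* LeakyReLU negative slope 0.01 (unstated in the source description).
* Softmax and segment-softmax subtract the (detached) per-row/segment
  maximum for stability; segment-max ties share the subgradient.
* Similarity matrices are validated to be symmetric within 1e-9 with unit
  diagonal and values in [0,1]; attention normalization is asserted to
  1e-6.
* Degenerate inputs fail loudly: all-zero GIP profiles (undefined
  bandwidth), empty neighborhoods, non-finite scores, NaN losses (with the
  epoch or layer index), single-class AUC inputs.

## Known limitations

* The DSP reads concatenated pair vectors, so it must *learn* multiplicative
  circRNA×disease interactions from a few hundred positives; at small scale
  it recovers less of the available signal than the bilinear KRL scorer
  itself, and regularization choices matter.
* Reduction ablations (sum vs mean vs max) differ only at high-degree nodes
  once attention is normalized; on small synthetic graphs the separation
  between them is within seed noise for individual runs and is therefore
  assessed as a mean over a fixed seed set.
* Sequential two-phase training is the default; the joint reading of the
  total loss (L1 + L2 + λ‖α‖² optimized end-to-end) is not the tested path.
* Full-scale defaults (d = 2048, stream widths 6016…) are exposed but not
  exercised by the tests; at that scale a GPU framework would be the
  appropriate backend.
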