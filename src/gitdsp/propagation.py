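"""Knowledge-aware attention propagation with graph-isomorphism aggregation.

One propagation layer, for every entity h with neighborhood N_h:

1. raw attention per triple (h, r, t):  ``θ = (W_r e_t)ᵀ tanh(W_r e_h + e_r)``,
   softmax-normalised over N_h (the self-loop guarantees N_h is non-empty);
2. ego-network embedding: reduction over θ-scaled neighbor embeddings —
   Sum (default, injective on multisets), Mean, or elementwise Max;
3. GIN update ``e_h ← LeakyReLU(MLP((1+ε)·e_h + e_N))`` with a learnable ε
   and a single affine map per layer, or one of the ablation aggregators
   (GraphSage, Bi-Interaction, GCN).

Stacking L layers (default widths 512-256-128-64 on top of the KRL width d)
yields per-layer embeddings e^(0..L) that the predictor later concatenates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .kg import KnowledgeGraph

AGGREGATORS = ("GIN", "GCN", "GraphSage", "Bi-Interaction")
REDUCTIONS = ("sum", "mean", "max")
LEAKY_SLOPE = 0.01


@dataclass
class PropagationLayerParams:
    w_rel: Tensor                 # (n_relations, in_width, rel_dim) attention maps
    mlp_w: Tensor                 # (in_width or 2*in_width, out_width)
    mlp_b: Tensor
    epsilon: Tensor               # scalar, learnable GIN self-weight

    def parameters(self) -> list[Tensor]:
        return [self.w_rel, self.mlp_w, self.mlp_b, self.epsilon]


@dataclass
class PropagationParams:
    layers: list[PropagationLayerParams]
    aggregator: str = "GIN"
    reduction: str = "sum"
    dropout: float = 0.1

    def parameters(self) -> list[Tensor]:
        out = []
        for lp in self.layers:
            out.extend(lp.parameters())
        return out


def init_propagation(n_relations: int, in_dim: int, widths: list[int],
                     rel_dim: int, rng: np.random.Generator,
                     aggregator: str = "GIN", reduction: str = "sum",
                     dropout: float = 0.1) -> PropagationParams:
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    if reduction not in REDUCTIONS:
        raise ValueError(f"unknown reduction {reduction!r}")
    if any(w <= 0 for w in widths):
        raise ValueError("layer widths must be strictly positive")
    layers = []
    prev = in_dim
    for w in widths:
        mlp_in = 2 * prev if aggregator == "GraphSage" else prev
        layers.append(PropagationLayerParams(
            w_rel=ad.xavier_uniform((n_relations, prev, rel_dim), rng),
            mlp_w=ad.xavier_uniform((mlp_in, w), rng),
            mlp_b=Tensor(np.zeros(w), requires_grad=True),
            epsilon=Tensor(np.zeros(()), requires_grad=True),
        ))
        prev = w
    return PropagationParams(layers=layers, aggregator=aggregator,
                             reduction=reduction, dropout=dropout)


def attention_coeffs(e: Tensor, e_rel: Tensor, w_rel: Tensor,
                     heads: np.ndarray, rels: np.ndarray, tails: np.ndarray,
                     n_entities: int) -> Tensor:
    """Normalised propagation factors θ(h,r,t) for an edge list.

    ``e`` is the (n_entities, w) embedding stage the layer consumes, ``e_rel``
    the (n_relations, rel_dim) relation table and ``w_rel`` the per-relation
    (w, rel_dim) attention transforms.  Raw scores
    ``(W_r e_t)ᵀ tanh(W_r e_h + e_r)`` are softmaxed within each head's
    neighborhood.
    """
    if heads.size == 0:
        raise ValueError("empty neighborhood: self-loop invariant violated")
    # group edges by relation so each projection is one dense matmul
    order = np.argsort(rels, kind="stable")
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(order.size)
    rels_sorted = rels[order]
    e_h = e.take(heads[order])                   # (E, w)
    e_t = e.take(tails[order])
    bounds = np.searchsorted(rels_sorted,
                             np.arange(w_rel.shape[0] + 1))
    proj_h_parts, proj_t_parts = [], []
    for r in range(w_rel.shape[0]):
        lo, hi = bounds[r], bounds[r + 1]
        if lo == hi:
            continue
        w_r = w_rel[r]                           # (w, rel_dim)
        proj_h_parts.append(e_h[lo:hi] @ w_r)
        proj_t_parts.append(e_t[lo:hi] @ w_r)
    proj_h = ad.concat(proj_h_parts, axis=0)
    proj_t = ad.concat(proj_t_parts, axis=0)
    raw_sorted = (proj_t * (proj_h + e_rel.take(rels_sorted)).tanh()).sum(axis=1)
    raw = raw_sorted.take(inv_order)
    return ad.segment_softmax(raw, heads, n_entities)


def ego_embedding(theta: Tensor, neighbor_emb: Tensor, heads: np.ndarray,
                  n_entities: int, reduction: str = "sum") -> Tensor:
    """Reduce θ-scaled neighbor embeddings per head entity."""
    if reduction not in REDUCTIONS:
        raise ValueError(f"unknown reduction {reduction!r}")
    scaled = neighbor_emb * theta.reshape(-1, 1)
    if reduction == "sum":
        return ad.segment_sum(scaled, heads, n_entities)
    if reduction == "mean":
        return ad.segment_mean(scaled, heads, n_entities)
    return ad.segment_max(scaled, heads, n_entities)


def gin_update(e_h: Tensor, e_n: Tensor, epsilon: Tensor, mlp_w: Tensor,
               mlp_b: Tensor) -> Tensor:
    """``LeakyReLU(MLP((1+ε)·e_h + e_N))`` — the GIN node update."""
    combined = e_h * (epsilon + 1.0) + e_n
    return (combined @ mlp_w + mlp_b).leaky_relu(LEAKY_SLOPE)


def alt_aggregator_update(kind: str, e_h: Tensor, e_n: Tensor, w: Tensor,
                          b: Tensor | None = None) -> Tensor:
    """GraphSage / Bi-Interaction / GCN node updates (ablation alternatives)."""
    if b is None:
        b = Tensor(np.zeros(w.shape[1]))
    if kind == "GraphSage":
        return (ad.concat([e_h, e_n], axis=-1) @ w + b).leaky_relu(LEAKY_SLOPE)
    if kind == "Bi-Interaction":
        add = ((e_h + e_n) @ w + b).leaky_relu(LEAKY_SLOPE)
        had = ((e_h * e_n) @ w + b).leaky_relu(LEAKY_SLOPE)
        return add + had
    if kind == "GCN":
        return ((e_h + e_n) @ w + b).leaky_relu(LEAKY_SLOPE)
    raise ValueError(f"unknown aggregator {kind!r}")


def propagate(kg: KnowledgeGraph, e0: Tensor, e_rel: Tensor,
              params: PropagationParams,
              rng: np.random.Generator | None = None,
              training: bool = False) -> list[Tensor]:
    """Apply all propagation layers; returns the stages ``[e^(0), ..., e^(L)]``."""
    n_entities = len(kg.entities)
    heads = kg.triples[:, 0]
    rels = kg.triples[:, 1]
    tails = kg.triples[:, 2]
    drop = rng if rng is not None else np.random.default_rng(0)
    stages = [e0]
    x = e0
    for layer_idx, lp in enumerate(params.layers):
        theta = attention_coeffs(x, e_rel, lp.w_rel, heads, rels, tails,
                                 n_entities)
        e_n = ego_embedding(theta, x.take(tails), heads, n_entities,
                            params.reduction)
        if params.aggregator == "GIN":
            new = gin_update(x, e_n, lp.epsilon, lp.mlp_w, lp.mlp_b)
        else:
            new = alt_aggregator_update(params.aggregator, x, e_n, lp.mlp_w,
                                        lp.mlp_b)
        new = ad.dropout(new, params.dropout, drop, training)
        if not np.all(np.isfinite(new.data)):
            raise FloatingPointError(
                f"non-finite embeddings after propagation layer {layer_idx}")
        stages.append(new)
        x = new
    return stages
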