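"""Transformer-encoder knowledge representation learning (KRL).

Entities and relations share one embedding dimension ``d``.  For a triple
(h, r, t) the sequence ``[e_h, e_r]`` passes through a Transformer encoder
(multi-head scaled dot-product self-attention, residual + layer norm, then a
ReLU feed-forward block with residual + layer norm); the encoder output at
the relation position, ``ê_r``, carries head context.  Triples are scored by
the bilinear form ``f(h,r,t) = ê_rᵀ W_r e_t`` with one transformation matrix
per relation (inverses and the self relation included), and the tables are
trained with the Bayesian personalized ranking (BPR) loss
``L1 = -Σ ln σ(f_pos − f_neg)`` over tail-corrupted negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .kg import KnowledgeGraph


@dataclass
class EncoderLayerParams:
    w_q: Tensor
    w_k: Tensor
    w_v: Tensor
    w_o: Tensor
    ln1_gain: Tensor
    ln1_bias: Tensor
    w_1: Tensor
    b_1: Tensor
    w_2: Tensor
    b_2: Tensor
    ln2_gain: Tensor
    ln2_bias: Tensor


@dataclass
class AttentionEncoderParams:
    """Stack of encoder layers plus the head-count metadata."""

    layers: list[EncoderLayerParams]
    n_heads: int
    dropout: float = 0.2

    def parameters(self) -> list[Tensor]:
        out = []
        for lp in self.layers:
            out.extend([lp.w_q, lp.w_k, lp.w_v, lp.w_o, lp.ln1_gain, lp.ln1_bias,
                        lp.w_1, lp.b_1, lp.w_2, lp.b_2, lp.ln2_gain, lp.ln2_bias])
        return out


@dataclass
class KRLParams:
    entity_emb: Tensor        # (n_entities, d)
    relation_emb: Tensor      # (n_relations, d)
    encoder: AttentionEncoderParams
    scorer: Tensor            # (n_relations, d, d) bilinear relation matrices

    @property
    def dim(self) -> int:
        return self.entity_emb.shape[1]

    def parameters(self) -> list[Tensor]:
        return ([self.entity_emb, self.relation_emb, self.scorer]
                + self.encoder.parameters())


def init_params(n_entities: int, n_relations: int, d: int, n_heads: int,
                n_layers: int, ffn_hidden: int, dropout: float,
                rng: np.random.Generator) -> KRLParams:
    if d % n_heads != 0:
        raise ValueError(f"head count {n_heads} must divide dimension {d}")
    if n_layers < 1:
        raise ValueError("encoder needs at least one layer")
    layers = []
    for _ in range(n_layers):
        layers.append(EncoderLayerParams(
            w_q=ad.xavier_uniform((d, d), rng),
            w_k=ad.xavier_uniform((d, d), rng),
            w_v=ad.xavier_uniform((d, d), rng),
            w_o=ad.xavier_uniform((d, d), rng),
            ln1_gain=Tensor(np.ones(d), requires_grad=True),
            ln1_bias=Tensor(np.zeros(d), requires_grad=True),
            w_1=ad.xavier_uniform((d, ffn_hidden), rng),
            b_1=Tensor(np.zeros(ffn_hidden), requires_grad=True),
            w_2=ad.xavier_uniform((ffn_hidden, d), rng),
            b_2=Tensor(np.zeros(d), requires_grad=True),
            ln2_gain=Tensor(np.ones(d), requires_grad=True),
            ln2_bias=Tensor(np.zeros(d), requires_grad=True),
        ))
    return KRLParams(
        entity_emb=ad.xavier_uniform((n_entities, d), rng),
        relation_emb=ad.xavier_uniform((n_relations, d), rng),
        encoder=AttentionEncoderParams(layers=layers, n_heads=n_heads,
                                       dropout=dropout),
        scorer=ad.xavier_uniform((n_relations, d, d), rng),
    )


def encode_pair(e_h: Tensor, e_r: Tensor, params: AttentionEncoderParams,
                rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
    """Encode batched (head, relation) sequences; returns ê_r of shape (B, d).

    ``e_h`` and ``e_r`` are (B, d).  The two embeddings form a length-2
    sequence per batch item; the relation position of the final layer output
    is returned (the head position is discarded downstream).
    """
    if e_h.shape != e_r.shape:
        raise ValueError("head and relation embeddings must share dimension")
    b, d = e_h.shape
    h = params.n_heads
    dh = d // h
    x = ad.stack([e_h, e_r], axis=1)  # (B, 2, d)
    drop = rng if rng is not None else np.random.default_rng(0)
    for lp in params.layers:
        q = (x @ lp.w_q).reshape(b, 2, h, dh).transpose(0, 2, 1, 3)
        k = (x @ lp.w_k).reshape(b, 2, h, dh).transpose(0, 2, 1, 3)
        v = (x @ lp.w_v).reshape(b, 2, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = ad.softmax(scores, axis=-1)          # (B, H, 2, 2)
        heads = (attn @ v).transpose(0, 2, 1, 3).reshape(b, 2, d)
        proj = ad.dropout(heads @ lp.w_o, params.dropout, drop, training)
        x = ad.layer_norm(x + proj, lp.ln1_gain, lp.ln1_bias)
        ffn = ((x @ lp.w_1 + lp.b_1).relu() @ lp.w_2 + lp.b_2)
        ffn = ad.dropout(ffn, params.dropout, drop, training)
        x = ad.layer_norm(x + ffn, lp.ln2_gain, lp.ln2_bias)
    return x[:, 1, :]


def attention_rows(e_h: np.ndarray, e_r: np.ndarray,
                   params: AttentionEncoderParams) -> np.ndarray:
    """First-layer attention weights (B, H, 2, 2) for inspection/testing."""
    b, d = e_h.shape
    h, dh = params.n_heads, d // params.n_heads
    x = np.stack([e_h, e_r], axis=1)
    lp = params.layers[0]
    q = (x @ lp.w_q.data).reshape(b, 2, h, dh).transpose(0, 2, 1, 3)
    k = (x @ lp.w_k.data).reshape(b, 2, h, dh).transpose(0, 2, 1, 3)
    scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(dh)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=-1, keepdims=True)


def score_triple(e_r_hat: Tensor, e_t: Tensor, w_r: Tensor) -> Tensor:
    """Bilinear triple affinity ``ê_rᵀ W_r e_t`` (batched: (B,d),(B,d),(B,d,d))."""
    if not (np.all(np.isfinite(e_r_hat.data)) and np.all(np.isfinite(e_t.data))
            and np.all(np.isfinite(w_r.data))):
        raise ValueError("non-finite inputs to triple scorer")
    if e_r_hat.ndim == 1:
        return ((e_r_hat.reshape(1, -1) @ w_r) * e_t.reshape(1, -1)).sum()
    b, d = e_r_hat.shape
    transformed = (e_r_hat.reshape(b, 1, d) @ w_r).reshape(b, d)
    return (transformed * e_t).sum(axis=1)


def bpr_loss(pos_scores: Tensor, neg_scores: Tensor) -> Tensor:
    """BPR ranking loss ``-Σ ln σ(f_pos − f_neg)`` (= Σ softplus(−margin))."""
    if pos_scores.data.size == 0:
        raise ValueError("empty score lists")
    if pos_scores.data.shape != neg_scores.data.shape:
        raise ValueError("positive and negative score lists must be matched")
    return (-(pos_scores - neg_scores)).softplus().sum()


def bpr_kg_loss(pos_scores, neg_scores) -> float:
    """Float convenience wrapper over :func:`bpr_loss` for plain arrays."""
    return bpr_loss(Tensor(np.atleast_1d(pos_scores)),
                    Tensor(np.atleast_1d(neg_scores))).item()


@dataclass
class KRLTrainResult:
    params: KRLParams
    losses: list[float] = field(default_factory=list)


class _TailCorruptor:
    """Similarity-aware, type-constrained tail corruption.

    For every training triple the allowed negative tails are precomputed
    once: entities of the true tail's type, minus all observed tails of that
    (head, relation), minus the ``exclusion_k`` entities most similar to the
    true tail under a GIP kernel over association profiles.  Excluding
    near-duplicates of the true tail keeps plausible-but-unobserved
    associations out of the negative set, so ranking gradients do not push
    genuinely related entities apart.  Each epoch draws one tail uniformly
    per triple.
    """

    def __init__(self, kg: KnowledgeGraph, triples: np.ndarray,
                 exclusion_k: int = 7):
        from .similarity import gip_kernel, top_k_similar

        type_pool = {t: kg.entities.indices_of_type(t)
                     for t in set(kg.entities.types)}
        # per-type GIP similarity over binary neighbor profiles
        n = len(kg.entities)
        adj = np.zeros((n, n))
        adj[triples[:, 0], triples[:, 2]] = 1.0
        adj[triples[:, 2], triples[:, 0]] = 1.0
        similar: dict[int, set[int]] = {}
        for etype, pool in type_pool.items():
            profiles = adj[pool]
            if profiles.sum() == 0 or exclusion_k <= 0 \
                    or len(pool) <= exclusion_k + 1:
                continue
            sim = gip_kernel(profiles)
            for local, ent in enumerate(pool.tolist()):
                top = top_k_similar(sim, local, exclusion_k)
                similar[ent] = {int(pool[j]) for j in top}
        observed: dict[tuple[int, int], set[int]] = {}
        for h, r, t in triples.tolist():
            observed.setdefault((h, r), set()).add(t)
        self.pools: list[np.ndarray] = []
        for h, r, t in triples.tolist():
            tail_type = kg.entities.types[t]
            excluded = observed[(h, r)] | similar.get(t, set())
            pool = np.array([c for c in type_pool[tail_type]
                             if c not in excluded], dtype=np.int64)
            self.pools.append(pool if pool.size else np.array([t]))

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p[rng.integers(p.size)] for p in self.pools],
                        dtype=np.int64)


def train_krl(kg: KnowledgeGraph, d: int = 2048, n_heads: int = 16,
              n_layers: int = 1, ffn_hidden: int = 256, dropout: float = 0.2,
              epochs: int = 100, lr: float = 1e-4, batch_size: int = 1024,
              seed: int = 0, lr_patience: int = 5,
              similar_exclusion_k: int = 7) -> KRLTrainResult:
    """Train embeddings, encoder and bilinear scorers with BPR over the KG.

    Positives are the base + inverse triples; one type-constrained corrupted
    tail per positive is resampled every epoch from an epoch-derived seed.
    The learning rate halves when the epoch loss stalls for ``lr_patience``
    epochs.  Fully deterministic under (config, seed).
    """
    rng = np.random.default_rng(seed)
    r_self = kg.relations.self_index
    triples = kg.triples[kg.triples[:, 1] != r_self]
    if len(triples) == 0:
        raise ValueError("knowledge graph has no base triples")
    params = init_params(len(kg.entities), len(kg.relations), d, n_heads,
                         n_layers, ffn_hidden, dropout, rng)
    opt = ad.Adam(params.parameters(), lr=lr)
    sched = ad.ReduceLROnPlateau(opt, factor=0.5, patience=lr_patience)
    corruptor = _TailCorruptor(kg, triples, exclusion_k=similar_exclusion_k)
    losses: list[float] = []
    n = len(triples)
    for epoch in range(epochs):
        ep_rng = np.random.default_rng(seed * 1_000_003 + epoch + 1)
        neg_tails = corruptor.draw(ep_rng)
        order = ep_rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            # sort the batch by relation so each bilinear map is one matmul
            idx = idx[np.argsort(triples[idx, 1], kind="stable")]
            h, r, t = triples[idx, 0], triples[idx, 1], triples[idx, 2]
            t_neg = neg_tails[idx]
            e_h = params.entity_emb.take(h)
            e_r = params.relation_emb.take(r)
            e_r_hat = encode_pair(e_h, e_r, params.encoder, rng=ep_rng,
                                  training=True)
            bounds = np.searchsorted(r, np.arange(len(kg.relations) + 1))
            parts = []
            for rel in range(len(kg.relations)):
                lo, hi = bounds[rel], bounds[rel + 1]
                if lo < hi:
                    parts.append(e_r_hat[lo:hi] @ params.scorer[rel])
            transformed = ad.concat(parts, axis=0)
            f_pos = (transformed * params.entity_emb.take(t)).sum(axis=1)
            f_neg = (transformed * params.entity_emb.take(t_neg)).sum(axis=1)
            loss = bpr_loss(f_pos, f_neg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
        epoch_loss = total / n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"KRL training diverged at epoch {epoch}")
        losses.append(epoch_loss)
        sched.step(epoch_loss)
    return KRLTrainResult(params=params, losses=losses)
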