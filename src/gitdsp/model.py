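"""GIT-DSP estimator: graph-isomorphism transformer + dual-stream predictor.

:class:`GitDsp` is a scikit-learn-style estimator over a
:class:`~gitdsp.kg.KnowledgeGraph`.  ``fit`` runs the two training phases:

1. *representation phase* — Transformer-encoder knowledge representation
   learning over all base + inverse triples (BPR loss L1);
2. *prediction phase* — knowledge-aware attention / GIN propagation stacked
   on the frozen entity table, feeding the dual-stream predictor, trained
   with the ranking loss L2 plus an L2 parameter penalty on circRNA-disease
   pairs (negatives drawn per disease with the top-k-similar exclusion).

``predict_matrix`` scores every circRNA-disease pair of the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .autodiff import Tensor
from .kg import KnowledgeGraph
from .krl import train_krl
from .predictor import (bpr_pred_loss, concat_stages, dsp_forward, init_dsp,
                        total_loss)
from .propagation import init_propagation, propagate
from .similarity import (SimilarityMatrix, fuse_circrna_similarity, gip_kernel,
                         sample_negatives)


@dataclass
class PairScoreMatrix:
    """Predicted affinities ŷ for every (circRNA, disease) pair."""

    scores: np.ndarray            # (n_circ, n_dis) in (0, 1)
    circ_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite pair scores")

    def ranking(self, disease: int) -> np.ndarray:
        """circRNA indices by descending score (ties by ascending index)."""
        col = self.scores[:, disease]
        return np.lexsort((np.arange(len(col)), -col))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (circRNA_id, disease_id, score, per-disease rank)."""
        rows = []
        for j, dis in enumerate(self.disease_ids):
            order = self.ranking(j)
            rank_of = np.empty(len(order), dtype=np.int64)
            rank_of[order] = np.arange(1, len(order) + 1)
            for i, circ in enumerate(self.circ_ids):
                rows.append((circ, dis, self.scores[i, j], rank_of[i]))
        return pd.DataFrame(rows, columns=["circRNA_id", "disease_id",
                                           "score", "rank"])


CHECKPOINT_VERSION = 1


def save_checkpoint(model: "GitDsp", path) -> None:
    """Versioned container: propagated embeddings and DSP weights (what
    prediction needs) plus the full KRL and propagation parameter sets and
    the config hash."""
    model._check_fitted()
    arrays = {
        "version": np.array(CHECKPOINT_VERSION),
        "entity_embeddings": model.entity_embeddings_,
        "circ_indices": model.circ_indices_,
        "disease_indices": model.disease_indices_,
        "head_w": model.dsp_params_.head_w.data,
        "head_b": model.dsp_params_.head_b.data,
        "ids": np.array(model.kg_.entities.ids),
        "types": np.array(model.kg_.entities.types),
        "config_hash": np.array(getattr(model, "config_hash_", "")),
    }
    for name, layers in (("s1", model.dsp_params_.stream1),
                         ("s2", model.dsp_params_.stream2)):
        for i, (w, b) in enumerate(layers):
            arrays[f"{name}_w{i}"] = w.data
            arrays[f"{name}_b{i}"] = b.data
    krl = model.krl_result_.params
    arrays["krl_entity_emb"] = krl.entity_emb.data
    arrays["krl_relation_emb"] = krl.relation_emb.data
    arrays["krl_scorer"] = krl.scorer.data
    for i, lp in enumerate(krl.encoder.layers):
        for field in ("w_q", "w_k", "w_v", "w_o", "ln1_gain", "ln1_bias",
                      "w_1", "b_1", "w_2", "b_2", "ln2_gain", "ln2_bias"):
            arrays[f"enc{i}_{field}"] = getattr(lp, field).data
    for i, lp in enumerate(model.propagation_params_.layers):
        arrays[f"prop{i}_w_rel"] = lp.w_rel.data
        arrays[f"prop{i}_mlp_w"] = lp.mlp_w.data
        arrays[f"prop{i}_mlp_b"] = lp.mlp_b.data
        arrays[f"prop{i}_epsilon"] = lp.epsilon.data
    np.savez(path, **arrays)


def load_checkpoint(path) -> "GitDsp":
    """Rebuild a prediction-ready estimator from :func:`save_checkpoint` output."""
    from .kg import EntityCatalog
    from .predictor import DSPParams

    data = np.load(path, allow_pickle=False)
    if int(data["version"]) != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {int(data['version'])}")
    model = GitDsp()
    model.entity_embeddings_ = data["entity_embeddings"]
    model.circ_indices_ = data["circ_indices"]
    model.disease_indices_ = data["disease_indices"]

    def layers(name):
        out, i = [], 0
        while f"{name}_w{i}" in data:
            out.append((Tensor(data[f"{name}_w{i}"]),
                        Tensor(data[f"{name}_b{i}"])))
            i += 1
        return out

    model.dsp_params_ = DSPParams(stream1=layers("s1"), stream2=layers("s2"),
                                  head_w=Tensor(data["head_w"]),
                                  head_b=Tensor(data["head_b"]))
    catalog = EntityCatalog(ids=[str(s) for s in data["ids"]],
                            types=[str(s) for s in data["types"]])

    class _CatalogOnly:
        def __init__(self, entities):
            self.entities = entities

    model.kg_ = _CatalogOnly(catalog)
    model.config_hash_ = str(data["config_hash"])
    # the complete parameter sets remain accessible for inspection
    model.checkpoint_arrays_ = {k: data[k] for k in data.files}
    return model


class GitDsp(BaseEstimator):
    """circRNA-disease association predictor.

    Parameters follow the model's published configuration; the widths are
    reduced in tests via ``set_params``.  ``random_state`` seeds every source
    of randomness (initialisation, negative sampling, dropout), making runs
    bit-reproducible.

    Parameters
    ----------
    embedding_dim : shared entity/relation embedding width d.
    n_heads, encoder_layers, ffn_hidden, krl_dropout : Transformer encoder
        geometry of the representation phase.
    layer_widths : propagation stage widths (L = len(layer_widths) layers).
    aggregator : ``"GIN"`` (default) or one of the ablation aggregators
        ``"GCN"``, ``"GraphSage"``, ``"Bi-Interaction"``.
    reduction : neighborhood reduction, ``"sum"`` (default) / ``"mean"`` /
        ``"max"``.
    stream1_widths, stream2_widths : DSP stream architectures; when ``None``
        they are derived from the pair width as [p, p/2, p/4, p/8] and
        [p, p, p/2], reproducing the published [6016, 3008, 1504, 752] and
        [6016, 6016, 3008] at full scale.
    neg_ratio : negatives per positive (1:10 default).
    similar_exclusion_k : per positive, its k most similar circRNAs are kept
        out of the negative pool (7 by default).
    lambda_reg : weight of the L2 parameter penalty in the total loss.
    """

    def __init__(self, embedding_dim: int = 2048, n_heads: int = 16,
                 encoder_layers: int = 1, ffn_hidden: int = 256,
                 krl_dropout: float = 0.2,
                 layer_widths: tuple[int, ...] = (512, 256, 128, 64),
                 prop_dropout: float = 0.1, aggregator: str = "GIN",
                 reduction: str = "sum",
                 stream1_widths: tuple[int, ...] | None = None,
                 stream2_widths: tuple[int, ...] | None = None,
                 krl_epochs: int = 100, krl_lr: float = 1e-4,
                 krl_batch_size: int = 1024, pred_epochs: int = 32,
                 pred_lr: float = 5e-4, pred_batch_size: int = 512,
                 weight_decay: float = 1e-7, neg_ratio: int = 10,
                 similar_exclusion_k: int = 7, lambda_reg: float = 1e-5,
                 neg_mode: str = "mixed", random_state: int = 0):
        self.embedding_dim = embedding_dim
        self.n_heads = n_heads
        self.encoder_layers = encoder_layers
        self.ffn_hidden = ffn_hidden
        self.krl_dropout = krl_dropout
        self.layer_widths = layer_widths
        self.prop_dropout = prop_dropout
        self.aggregator = aggregator
        self.reduction = reduction
        self.stream1_widths = stream1_widths
        self.stream2_widths = stream2_widths
        self.krl_epochs = krl_epochs
        self.krl_lr = krl_lr
        self.krl_batch_size = krl_batch_size
        self.pred_epochs = pred_epochs
        self.pred_lr = pred_lr
        self.pred_batch_size = pred_batch_size
        self.weight_decay = weight_decay
        self.neg_ratio = neg_ratio
        self.similar_exclusion_k = similar_exclusion_k
        self.lambda_reg = lambda_reg
        self.neg_mode = neg_mode
        self.random_state = random_state

    # -- derived geometry ------------------------------------------------------
    def pair_width(self) -> int:
        """2 × (d + Σ layer widths); must equal the stream-1 input width."""
        return 2 * (self.embedding_dim + sum(self.layer_widths))

    def _stream_widths(self) -> tuple[list[int], list[int]]:
        p = self.pair_width()
        s1 = list(self.stream1_widths) if self.stream1_widths else \
            [p, p // 2, p // 4, p // 8]
        s2 = list(self.stream2_widths) if self.stream2_widths else [p, p, p // 2]
        if s1[0] != p or s2[0] != p:
            raise ValueError(f"stream input widths ({s1[0]}, {s2[0]}) do not "
                             f"match the pair width {p}")
        return s1, s2

    # -- fitting ----------------------------------------------------------------
    def fit(self, X: KnowledgeGraph, y=None,
            circ_similarity: SimilarityMatrix | None = None) -> "GitDsp":
        """Train on a knowledge graph.

        ``circ_similarity`` optionally supplies a precomputed circRNA
        functional similarity (CFS); it is fused with the GIP kernel over the
        graph's circRNA-disease profiles and used for negative sampling.
        """
        kg = X
        self._stream_widths()  # validate width identity before any training
        seed = int(self.random_state)
        rng = np.random.default_rng(seed + 17)

        self.circ_indices_ = kg.entities.indices_of_type("circRNA")
        self.disease_indices_ = kg.entities.indices_of_type("disease")
        cd_pairs = kg.base_pairs("circ-dis")  # (circ, dis) global indices
        if len(cd_pairs) == 0:
            raise ValueError("knowledge graph has no circRNA–disease triples")
        self.train_pairs_ = cd_pairs

        # fused circRNA similarity for negative sampling
        circ_local = {int(c): i for i, c in enumerate(self.circ_indices_)}
        dis_local = {int(d): j for j, d in enumerate(self.disease_indices_)}
        profiles = np.zeros((len(self.circ_indices_),
                             len(self.disease_indices_)))
        for c, d in cd_pairs.tolist():
            profiles[circ_local[c], dis_local[d]] = 1.0
        cgs = gip_kernel(profiles)
        self.circ_similarity_ = fuse_circrna_similarity(circ_similarity, cgs)
        self.disease_similarity_ = gip_kernel(profiles.T)

        # phase 1: knowledge representation learning
        krl_result = train_krl(
            kg, d=self.embedding_dim, n_heads=self.n_heads,
            n_layers=self.encoder_layers, ffn_hidden=self.ffn_hidden,
            dropout=self.krl_dropout, epochs=self.krl_epochs, lr=self.krl_lr,
            batch_size=self.krl_batch_size, seed=seed)
        self.krl_result_ = krl_result
        self.krl_losses_ = krl_result.losses

        # phase 2: propagation + dual-stream predictor on frozen tables
        entity_emb = Tensor(krl_result.params.entity_emb.data.copy())
        rel_emb = Tensor(krl_result.params.relation_emb.data.copy())
        prop = init_propagation(
            n_relations=len(kg.relations), in_dim=self.embedding_dim,
            widths=list(self.layer_widths), rel_dim=self.embedding_dim,
            rng=rng, aggregator=self.aggregator, reduction=self.reduction,
            dropout=self.prop_dropout)
        s1, s2 = self._stream_widths()
        dsp = init_dsp(s1, s2, self.pair_width(), rng,
                       dropout=self.prop_dropout)
        params = prop.parameters() + dsp.parameters()
        opt = ad.Adam(params, lr=self.pred_lr,
                      weight_decay=self.weight_decay)
        self.pred_losses_ = []
        if self.neg_mode not in ("same-disease", "same-circrna", "mixed"):
            raise ValueError(f"unknown neg_mode {self.neg_mode!r}")
        dc_pairs = cd_pairs[:, [1, 0]]  # (disease, circ) view for sampling

        def draw_negatives(ep_seed: int):
            """Matched positive/negative pair arrays for one epoch.

            ``same-disease`` corrupts the circRNA of each positive within its
            disease; ``same-circrna`` corrupts the disease (the (i, j, j')
            pattern of the ranking loss); ``mixed`` splits the ratio between
            both, which trains the ranking in both directions of the score
            grid.  Both samplers exclude the top-k entities most similar to
            the true partner.
            """
            k_dis = {"same-disease": self.neg_ratio, "same-circrna": 0,
                     "mixed": self.neg_ratio // 2}[self.neg_mode]
            k_circ = self.neg_ratio - k_dis
            pos_parts, neg_parts = [], []
            if k_dis:
                negs = sample_negatives(dc_pairs, self.circ_indices_,
                                        self.circ_similarity_, k_dis,
                                        seed=ep_seed,
                                        exclusion_k=self.similar_exclusion_k)
                n = min(len(cd_pairs) * k_dis, len(negs.pairs))
                pos_parts.append(np.repeat(cd_pairs, k_dis, axis=0)[:n])
                neg_parts.append(negs.pairs[:n][:, [1, 0]])
            if k_circ:
                negs = sample_negatives(cd_pairs, self.disease_indices_,
                                        self.disease_similarity_, k_circ,
                                        seed=ep_seed + 1,
                                        exclusion_k=self.similar_exclusion_k)
                n = min(len(cd_pairs) * k_circ, len(negs.pairs))
                pos_parts.append(np.repeat(cd_pairs, k_circ, axis=0)[:n])
                neg_parts.append(negs.pairs[:n])
            return np.concatenate(pos_parts), np.concatenate(neg_parts)

        for epoch in range(self.pred_epochs):
            ep_seed = (seed * 9_176_011 + epoch * 31 + 1) % (2 ** 31)
            pos_rep, neg_rep = draw_negatives(ep_seed)
            n_match = len(pos_rep)
            pos_c, pos_d = pos_rep[:, 0], pos_rep[:, 1]
            neg_c, neg_d = neg_rep[:, 0], neg_rep[:, 1]
            ep_rng = np.random.default_rng(ep_seed + 7)
            order = ep_rng.permutation(n_match)
            total = 0.0
            for start in range(0, n_match, self.pred_batch_size):
                idx = order[start:start + self.pred_batch_size]
                stages = propagate(kg, entity_emb, rel_emb, prop, rng=ep_rng,
                                   training=True)
                all_emb = concat_stages(stages)
                pair_pos = ad.concat([all_emb.take(pos_c[idx]),
                                      all_emb.take(pos_d[idx])], axis=-1)
                pair_neg = ad.concat([all_emb.take(neg_c[idx]),
                                      all_emb.take(neg_d[idx])], axis=-1)
                y_pos = dsp_forward(pair_pos, dsp, rng=ep_rng, training=True)
                y_neg = dsp_forward(pair_neg, dsp, rng=ep_rng, training=True)
                loss = total_loss(0.0, bpr_pred_loss(y_pos, y_neg), params,
                                  self.lambda_reg)
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += loss.item()
            epoch_loss = total / n_match
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    f"predictor training diverged at epoch {epoch}")
            self.pred_losses_.append(epoch_loss)

        self.propagation_params_ = prop
        self.dsp_params_ = dsp
        stages = propagate(kg, entity_emb, rel_emb, prop, training=False)
        self.stages_ = [s.data for s in stages]
        self.entity_embeddings_ = np.concatenate(self.stages_, axis=-1)
        self.kg_ = kg
        return self

    # -- prediction ---------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "dsp_params_"):
            raise RuntimeError("model is not fitted; call fit() first")

    def predict_pair_scores(self, circ: np.ndarray, dis: np.ndarray,
                            batch: int = 4096) -> np.ndarray:
        """Eval-mode scores ŷ for matched arrays of global entity indices."""
        self._check_fitted()
        circ = np.asarray(circ, dtype=np.int64)
        dis = np.asarray(dis, dtype=np.int64)
        out = np.empty(len(circ))
        for start in range(0, len(circ), batch):
            sl = slice(start, start + batch)
            pair = np.concatenate([self.entity_embeddings_[circ[sl]],
                                   self.entity_embeddings_[dis[sl]]], axis=-1)
            out[sl] = dsp_forward(Tensor(pair), self.dsp_params_,
                                  training=False).data
        return out

    def predict_matrix(self) -> PairScoreMatrix:
        """Affinity scores for every (circRNA, disease) pair of the catalog."""
        self._check_fitted()
        nc, nd = len(self.circ_indices_), len(self.disease_indices_)
        grid_c = np.repeat(self.circ_indices_, nd)
        grid_d = np.tile(self.disease_indices_, nc)
        scores = self.predict_pair_scores(grid_c, grid_d).reshape(nc, nd)
        ids = self.kg_.entities.ids
        return PairScoreMatrix(
            scores=scores,
            circ_ids=[ids[i] for i in self.circ_indices_],
            disease_ids=[ids[j] for j in self.disease_indices_])
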