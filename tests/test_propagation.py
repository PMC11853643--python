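import numpy as np
import pandas as pd
import pytest

from gitdsp import autodiff as ad
from gitdsp.autodiff import Tensor
from gitdsp.kg import EntityCatalog, build_kg
from gitdsp.propagation import (alt_aggregator_update, attention_coeffs,
                                ego_embedding, gin_update, init_propagation,
                                propagate)

SLOPE = 0.01


def theta_for(scores, seg, n):
    """softmax within segments, as plain numpy for expected values."""
    e = np.exp(scores - scores.max())
    out = np.zeros(n)
    np.add.at(out, seg, e)
    return e / out[seg]


class TestAttentionCoeffs:
    def edge_list_kg(self):
        """3 entities: node 0 with two neighbors, each with a self-loop."""
        catalog = EntityCatalog(ids=["circ:a", "dis:b", "dis:c"],
                                types=["circRNA", "disease", "disease"])
        tables = {"circ-dis": pd.DataFrame(
            {"head": ["circ:a", "circ:a"], "tail": ["dis:b", "dis:c"]})}
        return build_kg(tables, catalog)

    def test_single_neighbor_theta_is_one(self):
        kg = self.edge_list_kg()
        rng = np.random.default_rng(0)
        e = Tensor(rng.standard_normal((3, 4)))
        e_rel = Tensor(rng.standard_normal((len(kg.relations), 4)))
        w = Tensor(rng.standard_normal((len(kg.relations), 4, 4)))
        # node 1 has exactly one triple: its inverse edge plus self-loop -> 2
        theta = attention_coeffs(e, e_rel, w, kg.triples[:, 0],
                                 kg.triples[:, 1], kg.triples[:, 2], 3)
        sums = np.zeros(3)
        np.add.at(sums, kg.triples[:, 0], theta.data)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert np.all(theta.data > 0)

    def test_zero_relation_matrices_degenerate_to_uniform(self):
        kg = self.edge_list_kg()
        rng = np.random.default_rng(1)
        e = Tensor(rng.standard_normal((3, 4)))
        e_rel = Tensor(rng.standard_normal((len(kg.relations), 4)))
        w = Tensor(np.zeros((len(kg.relations), 4, 4)))
        theta = attention_coeffs(e, e_rel, w, kg.triples[:, 0],
                                 kg.triples[:, 1], kg.triples[:, 2], 3)
        counts = np.bincount(kg.triples[:, 0], minlength=3)
        assert np.allclose(theta.data, 1.0 / counts[kg.triples[:, 0]])

    def test_closed_form_softmax_values(self):
        # raw scores [ln 2, 0] in one neighborhood -> [2/3, 1/3]
        seg = np.array([0, 0])
        theta = ad.segment_softmax(Tensor(np.array([np.log(2.0), 0.0])),
                                   seg, 1)
        assert np.allclose(theta.data, [2 / 3, 1 / 3])

    def test_empty_neighborhood_fatal(self):
        with pytest.raises(ValueError, match="self-loop"):
            attention_coeffs(Tensor(np.zeros((1, 2))),
                             Tensor(np.zeros((1, 2))),
                             Tensor(np.zeros((1, 2, 2))),
                             np.array([], dtype=int), np.array([], dtype=int),
                             np.array([], dtype=int), 1)


class TestEgoEmbedding:
    def test_single_neighbor_identity(self):
        out = ego_embedding(Tensor(np.array([1.0])),
                            Tensor(np.array([[3.0, -1.0]])),
                            np.array([0]), 1)
        assert np.allclose(out.data, [[3.0, -1.0]])

    def test_equal_weights_midpoint(self):
        out = ego_embedding(Tensor(np.array([0.5, 0.5])),
                            Tensor(np.array([[1.0, 0.0], [0.0, 1.0]])),
                            np.array([0, 0]), 1)
        assert np.allclose(out.data, [[0.5, 0.5]])

    def test_hand_weighted_sum(self):
        out = ego_embedding(Tensor(np.array([2 / 3, 1 / 3])),
                            Tensor(np.array([[3.0, 0.0], [0.0, 3.0]])),
                            np.array([0, 0]), 1)
        assert np.allclose(out.data, [[2.0, 1.0]])

    def test_convex_combination_norm_bound(self):
        rng = np.random.default_rng(0)
        nbrs = rng.standard_normal((5, 3))
        theta = theta_for(rng.standard_normal(5), np.zeros(5, int), 1)
        out = ego_embedding(Tensor(theta), Tensor(nbrs), np.zeros(5, int), 1)
        assert np.linalg.norm(out.data) <= \
            np.linalg.norm(nbrs, axis=1).max() + 1e-12


class TestGinUpdate:
    def test_degenerate_parameters_give_plain_sum(self):
        e_h = Tensor(np.array([[1.0, 2.0]]))
        e_n = Tensor(np.array([[0.5, 0.25]]))
        out = gin_update(e_h, e_n, Tensor(np.zeros(())),
                         Tensor(np.eye(2)), Tensor(np.zeros(2)))
        assert np.allclose(out.data, [[1.5, 2.25]])

    def test_epsilon_scales_self_term(self):
        out = gin_update(Tensor(np.array([[1.0]])), Tensor(np.array([[2.0]])),
                         Tensor(np.array(1.0)), Tensor(np.eye(1)),
                         Tensor(np.zeros(1)))
        assert np.allclose(out.data, [[4.0]])  # LeakyReLU((1+1)*1 + 2)

    def test_sum_separates_multisets_that_mean_confuses(self):
        """Multisets {1,1,2,2} and {1,2}: equal under Mean, distinct under Sum."""
        big = Tensor(np.array([[1.0], [1.0], [2.0], [2.0]]))
        small = Tensor(np.array([[1.0], [2.0]]))
        ones4, ones2 = Tensor(np.ones(4)), Tensor(np.ones(2))
        seg4, seg2 = np.zeros(4, int), np.zeros(2, int)
        sum_big = ego_embedding(ones4, big, seg4, 1, "sum").data
        sum_small = ego_embedding(ones2, small, seg2, 1, "sum").data
        mean_big = ego_embedding(ones4, big, seg4, 1, "mean").data
        mean_small = ego_embedding(ones2, small, seg2, 1, "mean").data
        assert sum_big[0, 0] == pytest.approx(6.0)
        assert sum_small[0, 0] == pytest.approx(3.0)
        assert mean_big[0, 0] == pytest.approx(1.5)
        assert mean_small[0, 0] == pytest.approx(1.5)
        # the GIN node update therefore differs under Sum, not under Mean
        mlp = (Tensor(np.eye(1)), Tensor(np.zeros(1)))
        eps = Tensor(np.zeros(()))
        e_h = Tensor(np.zeros((1, 1)))
        upd = lambda e_n: gin_update(e_h, Tensor(e_n), eps, *mlp).data
        assert not np.allclose(upd(sum_big), upd(sum_small))
        assert np.allclose(upd(mean_big), upd(mean_small))


class TestAltAggregators:
    def test_gcn_elementwise_leaky_relu(self):
        out = alt_aggregator_update("GCN", Tensor(np.array([[1.0, -3.0]])),
                                    Tensor(np.array([[1.0, 1.0]])),
                                    Tensor(np.eye(2)))
        assert np.allclose(out.data, [[2.0, -2.0 * SLOPE]])

    def test_bi_interaction_absorbs_zero_ego(self):
        rng = np.random.default_rng(0)
        e_h = Tensor(rng.standard_normal((1, 3)))
        w = Tensor(rng.standard_normal((3, 3)))
        out = alt_aggregator_update("Bi-Interaction", e_h,
                                    Tensor(np.zeros((1, 3))), w)
        expected = np.maximum(e_h.data @ w.data, 0) + \
            SLOPE * np.minimum(e_h.data @ w.data, 0)
        assert np.allclose(out.data, expected)

    def test_graphsage_concatenates_before_projection(self):
        w = Tensor(np.ones((4, 1)))
        out = alt_aggregator_update("GraphSage", Tensor(np.array([[1.0, 2.0]])),
                                    Tensor(np.array([[3.0, 4.0]])), w)
        assert np.allclose(out.data, [[10.0]])

    def test_unknown_kind_fatal(self):
        with pytest.raises(ValueError, match="unknown aggregator"):
            alt_aggregator_update("Laplacian", Tensor(np.zeros((1, 2))),
                                  Tensor(np.zeros((1, 2))),
                                  Tensor(np.zeros((2, 2))))


class TestPropagate:
    def toy(self, n_widths):
        catalog = EntityCatalog(
            ids=["circ:a", "circ:b", "dis:c", "dis:d", "mi:e", "mi:f"],
            types=["circRNA", "circRNA", "disease", "disease", "miRNA",
                   "miRNA"])
        tables = {
            "circ-dis": pd.DataFrame({"head": ["circ:a", "circ:b"],
                                      "tail": ["dis:c", "dis:d"]}),
            "circ-mi": pd.DataFrame({"head": ["circ:a"], "tail": ["mi:e"]}),
            "mi-dis": pd.DataFrame({"head": ["mi:f"], "tail": ["dis:d"]}),
        }
        kg = build_kg(tables, catalog)
        rng = np.random.default_rng(0)
        params = init_propagation(len(kg.relations), 4, n_widths, 4, rng)
        e0 = Tensor(rng.standard_normal((6, 4)))
        e_rel = Tensor(rng.standard_normal((len(kg.relations), 4)))
        return kg, e0, e_rel, params

    def test_zero_layers_returns_input_stage_only(self):
        kg, e0, e_rel, _ = self.toy([3])
        rng = np.random.default_rng(0)
        params = init_propagation(len(kg.relations), 4, [], 4, rng)
        stages = propagate(kg, e0, e_rel, params)
        assert len(stages) == 1 and stages[0] is e0

    def test_stage_widths_follow_config(self):
        kg, e0, e_rel, params = self.toy([3, 2])
        stages = propagate(kg, e0, e_rel, params)
        assert [s.shape[1] for s in stages] == [4, 3, 2]

    def test_isolated_entity_propagates_from_itself(self):
        """An entity with only its self-loop evolves deterministically from
        its own embedding: independent of every other entity's features."""
        catalog = EntityCatalog(ids=["circ:a", "dis:b", "lnc:x"],
                                types=["circRNA", "disease", "lncRNA"])
        tables = {"circ-dis": pd.DataFrame({"head": ["circ:a"],
                                            "tail": ["dis:b"]})}
        kg = build_kg(tables, catalog)
        rng = np.random.default_rng(1)
        params = init_propagation(len(kg.relations), 4, [3], 4, rng)
        e0 = rng.standard_normal((3, 4))
        out1 = propagate(kg, Tensor(e0), Tensor(np.zeros((11, 4))), params)
        e0_mod = e0.copy()
        e0_mod[:2] += 1.0  # perturb everyone except the isolated lncRNA
        out2 = propagate(kg, Tensor(e0_mod), Tensor(np.zeros((11, 4))), params)
        assert np.allclose(out1[1].data[2], out2[1].data[2])

    def test_permutation_equivariance(self):
        kg, e0, e_rel, params = self.toy([3, 2])
        stages = propagate(kg, e0, e_rel, params)
        # permute entity indices, rebuild the triple array, re-propagate
        perm = np.array([3, 0, 5, 1, 4, 2])  # new index of old entity i
        catalog = kg.entities
        perm_catalog = EntityCatalog(
            ids=[catalog.ids[i] for i in np.argsort(perm)],
            types=[catalog.types[i] for i in np.argsort(perm)])
        from gitdsp.kg import KnowledgeGraph
        perm_triples = kg.triples.copy()
        perm_triples[:, 0] = perm[kg.triples[:, 0]]
        perm_triples[:, 2] = perm[kg.triples[:, 2]]
        perm_kg = KnowledgeGraph(entities=perm_catalog,
                                 relations=kg.relations,
                                 triples=perm_triples)
        perm_stages = propagate(perm_kg, Tensor(e0.data[np.argsort(perm)]),
                                e_rel, params)
        for s, ps in zip(stages, perm_stages):
            assert np.allclose(ps.data[perm], s.data, atol=1e-12)

    def test_attention_sums_to_one_each_layer(self):
        kg, e0, e_rel, params = self.toy([3, 2])
        x = e0
        for lp in params.layers:
            theta = attention_coeffs(x, e_rel, lp.w_rel, kg.triples[:, 0],
                                     kg.triples[:, 1], kg.triples[:, 2],
                                     len(kg.entities))
            sums = np.zeros(len(kg.entities))
            np.add.at(sums, kg.triples[:, 0], theta.data)
            assert np.allclose(sums, 1.0, atol=1e-6)
            x = Tensor(np.ones((len(kg.entities), lp.mlp_w.shape[1])))
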