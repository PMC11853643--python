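import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gitdsp import autodiff as ad
from gitdsp.autodiff import Tensor
from gitdsp.krl import (AttentionEncoderParams, EncoderLayerParams,
                        attention_rows, bpr_kg_loss, bpr_loss, encode_pair,
                        init_params, score_triple, train_krl)
from gitdsp.synthetic import SyntheticConfig, generate


def degenerate_encoder(d: int) -> AttentionEncoderParams:
    """1 head, W_Q = W_K = 0, W_V = W_o = I, zero FFN, unit layer norms."""
    z, eye = np.zeros((d, d)), np.eye(d)
    lp = EncoderLayerParams(
        w_q=Tensor(z.copy()), w_k=Tensor(z.copy()), w_v=Tensor(eye.copy()),
        w_o=Tensor(eye.copy()), ln1_gain=Tensor(np.ones(d)),
        ln1_bias=Tensor(np.zeros(d)), w_1=Tensor(np.zeros((d, d))),
        b_1=Tensor(np.zeros(d)), w_2=Tensor(np.zeros((d, d))),
        b_2=Tensor(np.zeros(d)), ln2_gain=Tensor(np.ones(d)),
        ln2_bias=Tensor(np.zeros(d)))
    return AttentionEncoderParams(layers=[lp], n_heads=1, dropout=0.0)


class TestEncodePair:
    def test_output_preserves_dimension(self):
        rng = np.random.default_rng(0)
        params = init_params(4, 3, 16, 4, 1, 8, 0.0, rng)
        out = encode_pair(Tensor(rng.standard_normal((5, 16))),
                          Tensor(rng.standard_normal((5, 16))),
                          params.encoder)
        assert out.shape == (5, 16)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        params = init_params(4, 3, 16, 4, 1, 8, 0.0, rng)
        rows = attention_rows(rng.standard_normal((7, 16)),
                              rng.standard_normal((7, 16)), params.encoder)
        assert np.allclose(rows.sum(axis=-1), 1.0, atol=1e-6)

    def test_degenerate_weights_reduce_to_layernorm_of_mean_residual(self):
        # with zero Q/K the attention is uniform, so each position's value is
        # the mean of both positions; zero FFN + unit gains leave exactly
        # LayerNorm(x + mean) (layer norm is idempotent at unit gain/bias)
        e_h = np.array([[1.0, -2.0, 0.5, 3.0]])
        e_r = np.array([[0.25, 1.0, -1.0, 2.0]])
        out = encode_pair(Tensor(e_h), Tensor(e_r), degenerate_encoder(4)).data

        def layer_norm_ref(v):
            mu, var = v.mean(), v.var()
            return (v - mu) / np.sqrt(var + 1e-6)

        expected = layer_norm_ref(e_r[0] + (e_h[0] + e_r[0]) / 2.0)
        assert np.allclose(out[0], expected, atol=1e-9)

    def test_dimension_mismatch_fatal(self):
        with pytest.raises(ValueError):
            encode_pair(Tensor(np.zeros((2, 4))), Tensor(np.zeros((2, 6))),
                        degenerate_encoder(4))


class TestScoreTriple:
    @pytest.mark.parametrize("er, et, w, expected", [
        ([1.0, 0.0], [1.0, 0.0], np.eye(2), 1.0),       # unit vector identity
        ([1.0, 2.0], [3.0, 4.0], np.eye(2), 11.0),      # plain dot product
        ([1.0, 0.0], [0.0, 1.0], [[0.0, 2.0], [0.0, 0.0]], 2.0),
    ])
    def test_hand_evaluated_bilinear_forms(self, er, et, w, expected):
        out = score_triple(Tensor(np.array(er)), Tensor(np.array(et)),
                           Tensor(np.array(w, dtype=float)))
        assert out.item() == pytest.approx(expected)

    def test_non_finite_inputs_fatal(self):
        with pytest.raises(ValueError, match="non-finite"):
            score_triple(Tensor(np.array([np.nan, 0.0])),
                         Tensor(np.zeros(2)), Tensor(np.eye(2)))


class TestBprLoss:
    def test_zero_margin_is_ln2_per_pair(self):
        assert bpr_kg_loss([1.0], [1.0]) == pytest.approx(np.log(2.0))

    def test_unit_margin(self):
        assert bpr_kg_loss([2.0], [1.0]) == \
            pytest.approx(np.log(1 + np.exp(-1.0)))

    def test_large_margin_vanishes(self):
        assert bpr_kg_loss([60.0], [0.0]) == pytest.approx(0.0, abs=1e-12)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            bpr_kg_loss([], [])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.floats(-20, 20))
    def test_antisymmetry_of_margin(self, m):
        # swapping pos/neg maps margin m -> -m: ln(1+e^-m) <-> ln(1+e^m)
        assert bpr_kg_loss([m], [0.0]) == pytest.approx(np.log1p(np.exp(-m)))
        assert bpr_kg_loss([0.0], [m]) == pytest.approx(np.log1p(np.exp(m)))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        pos = Tensor(rng.standard_normal(6), requires_grad=True)
        neg = Tensor(rng.standard_normal(6), requires_grad=True)
        loss = bpr_loss(pos, neg)
        loss.backward()
        eps = 1e-6
        for t in (pos, neg):
            for i in range(6):
                orig = t.data[i]
                t.data[i] = orig + eps
                hi = bpr_loss(Tensor(pos.data), Tensor(neg.data)).item()
                t.data[i] = orig - eps
                lo = bpr_loss(Tensor(pos.data), Tensor(neg.data)).item()
                t.data[i] = orig
                assert t.grad[i] == pytest.approx((hi - lo) / (2 * eps),
                                                  abs=1e-4)


@pytest.fixture(scope="module")
def tiny_synth():
    return generate(SyntheticConfig(n_disease=6, n_circ=10, n_lnc=5,
                                    n_mi=5, n_associations=30,
                                    latent_rank=3, held_out_fraction=0.0,
                                    seed=0))


class TestTrainKrl:

    def test_loss_descends_on_toy_graph(self, tiny_synth):
        res = train_krl(tiny_synth.kg, d=8, n_heads=2, ffn_hidden=8,
                        epochs=5, lr=1e-2, seed=0)
        assert res.losses[-1] < res.losses[0]
        assert np.all(np.isfinite(res.losses))

    def test_identical_seed_gives_identical_trajectory(self, tiny_synth):
        kw = dict(d=8, n_heads=2, ffn_hidden=8, epochs=3, lr=1e-2, seed=11)
        a = train_krl(tiny_synth.kg, **kw)
        b = train_krl(tiny_synth.kg, **kw)
        assert a.losses == b.losses
        assert np.array_equal(a.params.entity_emb.data,
                              b.params.entity_emb.data)

    def test_head_divisibility_enforced(self, tiny_synth):
        with pytest.raises(ValueError, match="divide"):
            train_krl(tiny_synth.kg, d=10, n_heads=3, epochs=1, seed=0)

    def test_planted_positives_outscore_negatives_after_training(self):
        """Held-out triple scores exceed random corrupted-tail scores."""
        synth = generate(SyntheticConfig(n_disease=20, n_circ=50, n_lnc=20,
                                         n_mi=20, n_associations=300,
                                         latent_rank=4,
                                         held_out_fraction=0.2, seed=2))
        kg = synth.kg
        res = train_krl(kg, d=16, n_heads=2, ffn_hidden=16, epochs=30,
                        lr=1e-2, seed=2)
        r_cd = kg.relations.index["circ-dis"]
        E = res.params.entity_emb.data
        W = res.params.scorer.data[r_cd]
        e_r = res.params.relation_emb.data[r_cd]

        def score(c, d):
            e_hat = encode_pair(Tensor(E[None, c]), Tensor(e_r[None, :]),
                                res.params.encoder).data[0]
            return float(e_hat @ W @ E[d])

        rng = np.random.default_rng(0)
        dis = kg.entities.indices_of_type("disease")
        pos = [score(c, d) for c, d in synth.held_out.tolist()]
        neg = [score(c, int(rng.choice(dis)))
               for c, _ in synth.held_out.tolist()]
        assert np.mean(pos) > np.mean(neg)
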