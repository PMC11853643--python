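import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gitdsp.similarity import (SimilarityMatrix, fuse_circrna_similarity,
                               gip_kernel, load_or_default_dss,
                               load_similarity_tsv, sample_negatives,
                               top_k_similar, write_similarity_tsv)


class TestGipKernel:
    def test_identical_profiles_give_one(self):
        k = gip_kernel(np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]]))
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_two_profiles(self):
        # profiles [1,0] and [0,1]: gamma = 2/(1+1) = 1, K = exp(-2)
        k = gip_kernel(np.array([[1, 0], [0, 1]]))
        assert k.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        k = gip_kernel(rng.integers(0, 2, size=(12, 30)).astype(float) + 0.0)
        assert np.allclose(np.diag(k.values), 1.0)
        assert np.allclose(k.values, k.values.T, atol=1e-9)

    def test_all_zero_profiles_fatal(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gip_kernel(np.zeros((3, 4)))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_column_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        profiles = rng.integers(0, 2, size=(6, 15)).astype(float)
        profiles[0, 0] = 1  # guard against the all-zero degenerate case
        perm = rng.permutation(profiles.shape[1])
        a = gip_kernel(profiles).values
        b = gip_kernel(profiles[:, perm]).values
        assert np.allclose(a, b, atol=1e-12)


class TestDss:
    def test_supplied_matrix_passthrough(self, tmp_path):
        m = np.array([[1.0, 0.4], [0.4, 1.0]])
        write_similarity_tsv(SimilarityMatrix(m), ["d0", "d1"],
                             tmp_path / "dss.tsv")
        out = load_or_default_dss(tmp_path / "dss.tsv")
        assert np.allclose(out.values, m)

    def test_fallback_is_gip_kernel(self):
        profiles = np.array([[1.0, 0], [0, 1], [1, 1]])
        out = load_or_default_dss(None, fallback_profiles=profiles)
        assert np.allclose(out.values, gip_kernel(profiles).values)

    def test_out_of_range_value_fatal(self, tmp_path):
        frame = pd.DataFrame([[1.0, 1.2], [1.2, 1.0]], index=["a", "b"],
                             columns=["a", "b"])
        frame.to_csv(tmp_path / "bad.tsv", sep="\t")
        with pytest.raises(ValueError, match=r"out of \[0,1\]"):
            load_similarity_tsv(tmp_path / "bad.tsv")


class TestFusion:
    def test_absent_cfs_returns_cgs(self):
        cgs = SimilarityMatrix(np.eye(3))
        assert fuse_circrna_similarity(None, cgs) is cgs

    @pytest.mark.parametrize("cfs_val, cgs_val, expected",
                             [(0.8, 0.3, 0.8), (0.0, 0.3, 0.3)])
    def test_cfs_precedence_and_zero_fallback(self, cfs_val, cgs_val, expected):
        cfs = SimilarityMatrix(np.array([[1.0, cfs_val], [cfs_val, 1.0]]))
        cgs = SimilarityMatrix(np.array([[1.0, cgs_val], [cgs_val, 1.0]]))
        fused = fuse_circrna_similarity(cfs, cgs)
        assert fused.values[0, 1] == pytest.approx(expected)

    def test_axis_mismatch_fatal(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_circrna_similarity(SimilarityMatrix(np.eye(2)),
                                    SimilarityMatrix(np.eye(3)))


class TestTopK:
    def test_tie_broken_by_ascending_index(self):
        sim = SimilarityMatrix(np.array([
            [1.0, 0.9, 0.2, 0.9],
            [0.9, 1.0, 0.1, 0.1],
            [0.2, 0.1, 1.0, 0.1],
            [0.9, 0.1, 0.1, 1.0]]))
        assert top_k_similar(sim, 0, 2).tolist() == [1, 3]

    def test_two_entity_matrix(self):
        sim = SimilarityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert top_k_similar(sim, 0, 1).tolist() == [1]

    @pytest.mark.parametrize("k", [0, -1, 4])
    def test_invalid_k_fatal(self, k):
        sim = SimilarityMatrix(np.eye(4))
        with pytest.raises(ValueError):
            top_k_similar(sim, 0, k)


class TestSampleNegatives:
    def setup_method(self):
        rng = np.random.default_rng(5)
        profiles = rng.integers(0, 2, (20, 8)).astype(float)
        profiles[:, 0] = 1
        self.sim = gip_kernel(profiles)
        self.candidates = np.arange(20)
        self.positives = np.array([[100, 0], [100, 3], [101, 5], [102, 1],
                                   [103, 7]])

    def test_ratio_contract_and_no_positive_overlap(self):
        out = sample_negatives(self.positives, self.candidates, self.sim,
                               ratio=10, seed=0, exclusion_k=2)
        assert len(out.pairs) == 50
        pos_set = {tuple(p) for p in self.positives.tolist()}
        assert not pos_set & {tuple(p) for p in out.pairs.tolist()}

    def test_deterministic_under_seed(self):
        a = sample_negatives(self.positives, self.candidates, self.sim, 10, 42)
        b = sample_negatives(self.positives, self.candidates, self.sim, 10, 42)
        assert np.array_equal(a.pairs, b.pairs)

    def test_pool_exhaustion_flags_shortfall(self):
        small = np.arange(3)
        with pytest.warns(UserWarning, match="exhausted"):
            out = sample_negatives(np.array([[9, 0]]), small, None, ratio=10,
                                   seed=0, exclusion_k=0)
        assert out.shortfall == 8  # pool of 3 minus the known positive
        assert len(out.pairs) == 2

    def test_never_intersects_positives_over_many_draws(self):
        pos_set = {tuple(p) for p in self.positives.tolist()}
        drawn = []
        for seed in range(1000):
            out = sample_negatives(self.positives, self.candidates, None,
                                   ratio=2, seed=seed, exclusion_k=0)
            drawn.extend(map(tuple, out.pairs.tolist()))
        assert not pos_set & set(drawn)

    def test_similar_entities_excluded(self):
        out = sample_negatives(np.array([[50, 4]]), self.candidates, self.sim,
                               ratio=12, seed=1, exclusion_k=7)
        banned = {int(self.candidates[j])
                  for j in top_k_similar(self.sim, 4, 7)}
        assert not banned & {t for _, t in out.pairs.tolist()}
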