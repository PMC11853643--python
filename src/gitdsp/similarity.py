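"""Similarity matrices and similarity-aware negative sampling.

The fused similarity network combines disease semantic similarity (DSS),
circRNA Gaussian interaction profile kernel similarity (CGS) and circRNA
functional similarity (CFS).  DSS and CFS are accepted as precomputed
matrices; when absent, the Gaussian interaction profile (GIP) kernel over
binary association profiles is the fallback.  The fused circRNA similarity
drives negative sampling: candidate negatives that are near-duplicates of a
known positive partner (its top-k most similar circRNAs, k = 7 by default)
are excluded from the pool to keep negative labels clean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_SIMILAR_EXCLUSION = 7  # "seven most similar circRNAs"


@dataclass
class SimilarityMatrix:
    """Symmetric, unit-diagonal similarity over an ordered entity axis."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("similarity out of [0,1]")
        v = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class NegativeSampleSet:
    """Sampled negative (head, tail) pairs at a fixed negatives-per-positive ratio."""

    pairs: np.ndarray  # (n, 2) of (head, tail)
    ratio: int
    shortfall: int = 0  # number of requested negatives that could not be drawn


def gip_kernel(profiles: np.ndarray) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over binary association profiles.

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2) with the bandwidth normalised
    by the mean squared profile norm: gamma = n / sum_k ||IP(k)||^2.
    """
    ip = np.asarray(profiles, dtype=np.float64)
    if ip.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    norms_sq = (ip ** 2).sum(axis=1)
    total = norms_sq.sum()
    if total == 0:
        raise ValueError("all-zero profile matrix: GIP bandwidth undefined")
    gamma = ip.shape[0] / total
    # squared euclidean distances via the Gram matrix
    gram = ip @ ip.T
    d2 = norms_sq[:, None] + norms_sq[None, :] - 2.0 * gram
    d2 = np.maximum(d2, 0.0)
    return SimilarityMatrix(np.exp(-gamma * d2))


def load_similarity_tsv(path: str | Path) -> SimilarityMatrix:
    """Read a dense similarity matrix with a header row of entity ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(frame.to_numpy(dtype=np.float64))


def write_similarity_tsv(sim: SimilarityMatrix, ids: list[str],
                         path: str | Path) -> None:
    pd.DataFrame(sim.values, index=ids, columns=ids).to_csv(path, sep="\t")


def load_or_default_dss(source: str | Path | None,
                        fallback_profiles: np.ndarray | None = None
                        ) -> SimilarityMatrix:
    """Disease semantic similarity: supplied matrix, else GIP over profiles."""
    if source is not None:
        return load_similarity_tsv(source)
    if fallback_profiles is None:
        raise ValueError("either a DSS matrix file or disease profiles required")
    return gip_kernel(fallback_profiles)


def fuse_circrna_similarity(cfs: SimilarityMatrix | None,
                            cgs: SimilarityMatrix) -> SimilarityMatrix:
    """Functional similarity where defined (> 0), GIP kernel elsewhere."""
    if cfs is None:
        return cgs
    if len(cfs) != len(cgs):
        raise ValueError("similarity axis mismatch")
    fused = np.where(cfs.values > 0, cfs.values, cgs.values)
    return SimilarityMatrix(fused)


def top_k_similar(sim: SimilarityMatrix, entity: int, k: int) -> np.ndarray:
    """Indices of the k most similar entities (query excluded, ties by index)."""
    n = len(sim)
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of entities {n}")
    row = sim.values[entity].copy()
    row[entity] = -np.inf
    # stable sort on (-similarity, index) gives descending similarity with
    # ties broken by ascending index
    order = np.lexsort((np.arange(n), -row))
    return order[:k]


def sample_negatives(positives: np.ndarray, candidate_tails: np.ndarray,
                     sim: SimilarityMatrix | None, ratio: int, seed: int,
                     exclusion_k: int = DEFAULT_SIMILAR_EXCLUSION
                     ) -> NegativeSampleSet:
    """Draw ``ratio`` negative tails per positive (head, tail) pair.

    For each positive, candidates exclude (a) all known positive partners of
    the head and (b) the ``exclusion_k`` tails most similar to the true tail
    (when a tail-similarity matrix is supplied).  Sampling is uniform without
    replacement within one positive, reproducible under ``seed``.  When the
    pool is smaller than ``ratio`` the shortfall is flagged with a warning.
    """
    positives = np.asarray(positives, dtype=np.int64).reshape(-1, 2)
    candidate_tails = np.asarray(candidate_tails, dtype=np.int64)
    if ratio <= 0:
        raise ValueError("ratio must be a positive integer")
    rng = np.random.default_rng(seed)

    known: dict[int, set[int]] = {}
    for h, t in positives.tolist():
        known.setdefault(h, set()).add(t)

    cand_pos = {t: i for i, t in enumerate(candidate_tails.tolist())}
    similar_cache: dict[int, set[int]] = {}

    out: list[tuple[int, int]] = []
    shortfall = 0
    for h, t in positives.tolist():
        excluded = set(known[h])
        if sim is not None and exclusion_k > 0 and t in cand_pos:
            if t not in similar_cache:
                local = top_k_similar(sim, cand_pos[t], min(exclusion_k,
                                                            len(sim) - 1))
                similar_cache[t] = {int(candidate_tails[j]) for j in local}
            excluded |= similar_cache[t]
        pool = np.array([c for c in candidate_tails if c not in excluded],
                        dtype=np.int64)
        take = min(ratio, pool.size)
        if take < ratio:
            shortfall += ratio - take
        if take > 0:
            chosen = rng.choice(pool, size=take, replace=False)
            out.extend((h, int(c)) for c in chosen)
    if shortfall:
        warnings.warn(f"negative sampling pool exhausted: {shortfall} "
                      "negatives short of the requested ratio")
    pairs = (np.array(out, dtype=np.int64).reshape(-1, 2)
             if out else np.empty((0, 2), dtype=np.int64))
    return NegativeSampleSet(pairs=pairs, ratio=ratio, shortfall=shortfall)
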