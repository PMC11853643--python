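"""Synthetic heterogeneous knowledge graphs with planted low-rank structure.

The generator emulates the shape and sparsity of a published non-cancer CDA
benchmark (79 diseases, 330 circRNAs, 404 lncRNAs, 265 miRNAs; 1327
associations split 346/146/106/202/527 across the five layers, with roughly
85% of diseases linked to at most 10 circRNAs).  Every entity carries a
latent factor vector shared across all five association layers, so
cross-type edges (circRNA-miRNA, miRNA-disease, ...) genuinely carry
information about held-out circRNA-disease pairs — the premise that
multi-source relations alleviate CDA sparsity.

Each entity's latent factor is a noisy membership direction over
``latent_rank`` functional modules scaled by a lognormal "activity" level,
so association counts are heavy-tailed (hub molecules exist) the way curated
CDA data is.  Associations of each layer are the top-scoring latent pairs up
to that layer's budget; a small fraction is rewired uniformly at random
(label noise), and a fraction of the circRNA-disease positives is held out
of the graph as recovery targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kg import (BASE_RELATIONS, EntityCatalog, KnowledgeGraph, build_kg,
                 namespace_id)

#: per-layer association budget proportions of the emulated benchmark
LAYER_BUDGET = {"circ-dis": 346, "circ-mi": 146, "mi-dis": 106,
                "lnc-mi": 202, "lnc-dis": 527}


@dataclass
class SyntheticConfig:
    n_disease: int = 79
    n_circ: int = 330
    n_lnc: int = 404
    n_mi: int = 265
    n_associations: int = 1327
    latent_rank: int = 8
    cluster_spread: float = 0.3     # within-module direction noise
    activity_sigma: float = 0.9     # lognormal sigma of per-entity activity
    noise_rate: float = 0.05
    held_out_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_disease", "n_circ", "n_lnc", "n_mi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if not 0 <= self.held_out_fraction < 1:
            raise ValueError("held_out_fraction must be in [0, 1)")
        sizes = self.type_sizes()
        for name, budget in self.layer_budgets().items():
            ht, tt = BASE_RELATIONS[name]
            if budget > sizes[ht] * sizes[tt]:
                raise ValueError(f"budget for {name} exceeds feasible pairs")

    def type_sizes(self) -> dict[str, int]:
        return {"disease": self.n_disease, "circRNA": self.n_circ,
                "lncRNA": self.n_lnc, "miRNA": self.n_mi}

    def layer_budgets(self) -> dict[str, int]:
        """Split the total budget across layers proportionally (largest-remainder)."""
        total_ref = sum(LAYER_BUDGET.values())
        raw = {k: self.n_associations * v / total_ref
               for k, v in LAYER_BUDGET.items()}
        floors = {k: int(np.floor(v)) for k, v in raw.items()}
        remainder = self.n_associations - sum(floors.values())
        order = sorted(LAYER_BUDGET, key=lambda k: raw[k] - floors[k],
                       reverse=True)
        for k in order[:remainder]:
            floors[k] += 1
        return floors


@dataclass
class SyntheticKG:
    kg: KnowledgeGraph
    tables: dict[str, pd.DataFrame]          # training association layers
    held_out: np.ndarray                     # (n, 2) circ-dis entity indices
    latent: np.ndarray                       # (n_entities, rank) ground truth
    config: SyntheticConfig = field(repr=False, default=None)


def _make_catalog(config: SyntheticConfig) -> EntityCatalog:
    ids, types = [], []
    for etype, count, stem in (("disease", config.n_disease, "D"),
                               ("circRNA", config.n_circ, "C"),
                               ("lncRNA", config.n_lnc, "L"),
                               ("miRNA", config.n_mi, "M")):
        for i in range(count):
            ids.append(namespace_id(f"{stem}{i:04d}", etype))
            types.append(etype)
    return EntityCatalog(ids=ids, types=types)


def _top_pairs(scores: np.ndarray, budget: int) -> np.ndarray:
    """Row/col indices of the ``budget`` largest entries of a score matrix."""
    flat = np.argsort(scores, axis=None)[::-1][:budget]
    return np.column_stack(np.unravel_index(flat, scores.shape))


def generate(config: SyntheticConfig) -> SyntheticKG:
    """Draw a planted-structure synthetic KG; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    catalog = _make_catalog(config)
    n_total = len(catalog)

    # module membership direction x lognormal activity, shared by all layers
    clusters = rng.integers(config.latent_rank, size=n_total)
    direction = (np.eye(config.latent_rank)[clusters]
                 + config.cluster_spread
                 * rng.standard_normal((n_total, config.latent_rank)))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    activity = rng.lognormal(0.0, config.activity_sigma, size=n_total)
    latent = direction * activity[:, None]

    type_idx = {t: catalog.indices_of_type(t) for t in config.type_sizes()}
    budgets = config.layer_budgets()

    layer_pairs: dict[str, np.ndarray] = {}
    for name, budget in budgets.items():
        head_type, tail_type = BASE_RELATIONS[name]
        heads, tails = type_idx[head_type], type_idx[tail_type]
        scores = latent[heads] @ latent[tails].T
        local = _top_pairs(scores, budget)
        pairs = np.column_stack((heads[local[:, 0]], tails[local[:, 1]]))
        # rewire a noise fraction to uniform random non-duplicate pairs
        n_noise = int(round(config.noise_rate * budget))
        if n_noise > 0:
            existing = {tuple(p) for p in pairs.tolist()}
            replace = rng.choice(budget, size=n_noise, replace=False)
            for row in replace:
                for _ in range(1000):
                    cand = (int(rng.choice(heads)), int(rng.choice(tails)))
                    if cand not in existing:
                        existing.discard(tuple(pairs[row]))
                        existing.add(cand)
                        pairs[row] = cand
                        break
        layer_pairs[name] = pairs

    # hold out recovery targets from the circRNA-disease layer only
    cd = layer_pairs["circ-dis"]
    n_hold = int(round(config.held_out_fraction * len(cd)))
    hold_rows = rng.choice(len(cd), size=n_hold, replace=False)
    mask = np.ones(len(cd), dtype=bool)
    mask[hold_rows] = False
    held_out = cd[~mask]
    layer_pairs["circ-dis"] = cd[mask]

    tables = {
        name: pd.DataFrame({"head": [catalog.ids[h] for h, _ in pairs],
                            "tail": [catalog.ids[t] for _, t in pairs]})
        for name, pairs in layer_pairs.items()
    }
    kg = build_kg(tables, catalog)
    return SyntheticKG(kg=kg, tables=tables, held_out=held_out,
                       latent=latent, config=config)


def sparsity_profile(synth: SyntheticKG) -> float:
    """Fraction of diseases with at most 10 circRNA partners in the graph."""
    kg = synth.kg
    disease_idx = kg.entities.indices_of_type("disease")
    pairs = kg.base_pairs("circ-dis")  # (circ, dis)
    counts = np.zeros(len(kg.entities), dtype=np.int64)
    for _, d in pairs.tolist():
        counts[d] += 1
    return float(np.mean(counts[disease_idx] <= 10))


def write_tables(synth: SyntheticKG, out_dir: str | Path) -> dict[str, Path]:
    """Emit the five association TSVs + catalog consumed by the KG builder."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, frame in synth.tables.items():
        p = out_dir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", header=False, index=False)
        paths[name] = p
    synth.kg.entities.to_tsv(out_dir / "catalog.tsv")
    paths["catalog"] = out_dir / "catalog.tsv"
    return paths
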