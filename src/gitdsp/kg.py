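"""Heterogeneous ncRNA-disease knowledge graph construction.

Entities are diseases, circRNAs, lncRNAs and miRNAs; the five base relations
are the association layers circRNA-disease, circRNA-miRNA, miRNA-disease,
lncRNA-miRNA and lncRNA-disease.  The graph materialises, for every base
triple (h, r, t), the inverse triple (t, r', h) under a distinct inverse
relation, and gives every entity exactly one self-loop triple (e, r'', e)
under a single shared self relation, so that isolated entities still have a
non-empty neighborhood during propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ENTITY_TYPES = ("disease", "circRNA", "lncRNA", "miRNA")

#: short namespace prefixes applied to raw identifiers on load
TYPE_PREFIX = {"disease": "dis", "circRNA": "circ", "lncRNA": "lnc", "miRNA": "mi"}

#: base association layers: name -> (head entity type, tail entity type)
BASE_RELATIONS: dict[str, tuple[str, str]] = {
    "circ-dis": ("circRNA", "disease"),
    "circ-mi": ("circRNA", "miRNA"),
    "mi-dis": ("miRNA", "disease"),
    "lnc-mi": ("lncRNA", "miRNA"),
    "lnc-dis": ("lncRNA", "disease"),
}

SELF_RELATION = "self"


def namespace_id(raw_id: str, entity_type: str) -> str:
    """Prefix a raw identifier with its entity type (``"circ:hsa_..."``)."""
    if entity_type not in TYPE_PREFIX:
        raise ValueError(f"unknown entity type {entity_type!r}")
    prefix = TYPE_PREFIX[entity_type] + ":"
    return raw_id if raw_id.startswith(prefix) else prefix + raw_id


@dataclass
class EntityCatalog:
    """Bijection between namespaced entity ids and dense 0-based indices."""

    ids: list[str]
    types: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        if len(self.ids) != len(self.types):
            raise ValueError("ids and types must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Series(self.ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate entity ids: {dupes[:5]}")
        for t in self.types:
            if t not in ENTITY_TYPES:
                raise ValueError(f"unknown entity type {t!r}")
        self.index = {eid: i for i, eid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def indices_of_type(self, entity_type: str) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.types) if t == entity_type],
                        dtype=np.int64)

    def resolve(self, entity_id: str) -> int:
        try:
            return self.index[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity id {entity_id!r}") from None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EntityCatalog":
        """Build from a two-column (id, type) frame; ids are namespaced here."""
        ids = [namespace_id(str(r), str(t)) for r, t in
               zip(frame.iloc[:, 0], frame.iloc[:, 1])]
        return cls(ids=ids, types=[str(t) for t in frame.iloc[:, 1]])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EntityCatalog":
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if frame.shape[1] < 2:
            raise ValueError(f"{path}: catalog needs (id, type) columns")
        return cls.from_frame(frame)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.ids, "type": self.types}).to_csv(
            path, sep="\t", header=False, index=False)


@dataclass
class RelationCatalog:
    """Base relations, their materialised inverses and the shared self relation.

    Relation indices are laid out as ``[base..., inverse..., self]`` so that
    ``inverse(inverse(r)) == r`` and the self relation is its own inverse.
    """

    base_names: tuple[str, ...] = tuple(BASE_RELATIONS)

    def __post_init__(self):
        self.names: list[str] = (list(self.base_names)
                                 + [n + "_inv" for n in self.base_names]
                                 + [SELF_RELATION])
        self.index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_base(self) -> int:
        return len(self.base_names)

    @property
    def self_index(self) -> int:
        return len(self.names) - 1

    def inverse_of(self, r: int) -> int:
        nb = self.n_base
        if r == self.self_index:
            return r
        return r + nb if r < nb else r - nb


@dataclass
class KnowledgeGraph:
    entities: EntityCatalog
    relations: RelationCatalog
    triples: np.ndarray  # (n, 3) int64 rows of (h, r, t)
    _neighbors: dict[int, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self):
        self.triples = np.asarray(self.triples, dtype=np.int64).reshape(-1, 3)
        uniq = {tuple(row) for row in self.triples.tolist()}
        if len(uniq) != len(self.triples):
            raise ValueError("duplicate triples in knowledge graph")
        order = np.lexsort((self.triples[:, 2], self.triples[:, 1],
                            self.triples[:, 0]))
        self.triples = self.triples[order]
        self._neighbors = {}
        starts = np.searchsorted(self.triples[:, 0], np.arange(len(self.entities)))
        ends = np.searchsorted(self.triples[:, 0], np.arange(len(self.entities)),
                               side="right")
        for h in range(len(self.entities)):
            self._neighbors[h] = self.triples[starts[h]:ends[h]]

    def __len__(self) -> int:
        return len(self.triples)

    def neighborhood(self, h: int) -> np.ndarray:
        """All triples (h, r, t) whose head is ``h`` (includes the self-loop)."""
        if not 0 <= h < len(self.entities):
            raise IndexError(f"entity index {h} out of range")
        return self._neighbors[h]

    def base_pairs(self, relation_name: str) -> np.ndarray:
        """(head, tail) index pairs for one base association layer."""
        r = self.relations.index[relation_name]
        mask = self.triples[:, 1] == r
        return self.triples[mask][:, [0, 2]]

    def write_triples_tsv(self, path: str | Path) -> None:
        names = self.relations.names
        rows = [(self.entities.ids[h], names[r], self.entities.ids[t])
                for h, r, t in self.triples.tolist()]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def load_associations(paths: dict[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Load the five association layers from two-column delimited files.

    Returns namespaced, de-duplicated (head, tail) frames keyed by relation
    name.  Raw ids are namespaced by the entity type each column carries for
    that relation, which rules out cross-type id collisions by construction.
    """
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        if name not in BASE_RELATIONS:
            raise ValueError(f"unknown association type {name!r}")
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"association file missing: {path}")
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        for line_no, row in enumerate(frame.itertuples(index=False), start=1):
            if len(row) < 2 or any(pd.isna(v) for v in row[:2]):
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
        head_type, tail_type = BASE_RELATIONS[name]
        heads = [namespace_id(v, head_type) for v in frame.iloc[:, 0]]
        tails = [namespace_id(v, tail_type) for v in frame.iloc[:, 1]]
        pairs = pd.DataFrame({"head": heads, "tail": tails}).drop_duplicates()
        tables[name] = pairs.reset_index(drop=True)
    if "circ-dis" in tables and len(tables["circ-dis"]) == 0:
        raise ValueError("no circRNA–disease associations")
    return tables


def build_kg(tables: dict[str, pd.DataFrame],
             catalog: EntityCatalog) -> KnowledgeGraph:
    """Assemble base + inverse + self triples and the neighborhood index."""
    relations = RelationCatalog()
    rows: list[tuple[int, int, int]] = []
    for name, pairs in tables.items():
        r = relations.index[name]
        r_inv = relations.inverse_of(r)
        for head_id, tail_id in pairs.itertuples(index=False):
            h = catalog.resolve(head_id)
            t = catalog.resolve(tail_id)
            rows.append((h, r, t))
            rows.append((t, r_inv, h))
    r_self = relations.self_index
    rows.extend((e, r_self, e) for e in range(len(catalog)))
    return KnowledgeGraph(entities=catalog, relations=relations,
                          triples=np.array(rows, dtype=np.int64))


def kg_from_files(assoc_paths: dict[str, str | Path],
                  catalog_path: str | Path) -> KnowledgeGraph:
    catalog = EntityCatalog.read_tsv(catalog_path)
    tables = load_associations(assoc_paths)
    return build_kg(tables, catalog)


def read_triples_tsv(path: str | Path, catalog: EntityCatalog) -> KnowledgeGraph:
    """Reload a canonical triple TSV written by :meth:`KnowledgeGraph.write_triples_tsv`."""
    relations = RelationCatalog()
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    rows = [(catalog.resolve(h), relations.index[r], catalog.resolve(t))
            for h, r, t in frame.itertuples(index=False)]
    return KnowledgeGraph(entities=catalog, relations=relations,
                          triples=np.array(rows, dtype=np.int64))
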