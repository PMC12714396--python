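"""Microbe-metabolite-drug heterogeneous graph: domain types, assembly, I/O.

The graph has three node types (microbe, metabolite, drug) and five
undirected edge types:

* ``ss`` microbe-microbe, weighted by aggregated microbe similarity,
* ``dd`` drug-drug, weighted by aggregated drug similarity,
* ``sm`` microbe-metabolite, ``mm`` metabolite-metabolite and
  ``dm`` drug-metabolite, all unit-weight relational edges.

There is deliberately no microbe-drug edge type: labeled associations
supervise the downstream classifier and never enter the walk substrate.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MICROBE = "microbe"
METABOLITE = "metabolite"
DRUG = "drug"
NODE_TYPES = (MICROBE, METABOLITE, DRUG)

#: the five edge types, in canonical order (indexes into transition matrices)
EDGE_TYPES = ("ss", "sm", "mm", "dm", "dd")
EDGE_TYPE_INDEX = {t: i for i, t in enumerate(EDGE_TYPES)}

#: node-type pair -> edge type; only these pairs may carry edges
_ENDPOINT_TYPES = {
    "ss": (MICROBE, MICROBE),
    "sm": (MICROBE, METABOLITE),
    "mm": (METABOLITE, METABOLITE),
    "dm": (DRUG, METABOLITE),
    "dd": (DRUG, DRUG),
}


class GraphError(ValueError):
    """Raised on malformed registries, edge tables or graph files."""


@dataclass(frozen=True)
class NodeRegistry:
    """Typed node universe with dense 0-based per-type indices.

    Files carry string ids only; indices are internal. Ids are
    case-sensitive, whitespace-trimmed and must be unique across all
    three node types so that the type lookup is a function.
    """

    microbes: tuple[str, ...]
    metabolites: tuple[str, ...]
    drugs: tuple[str, ...]
    _lookup: dict[str, tuple[str, int]] = field(repr=False, compare=False, default_factory=dict)

    @classmethod
    def build(cls, microbes, metabolites, drugs) -> "NodeRegistry":
        lists = {
            MICROBE: tuple(str(x).strip() for x in microbes),
            METABOLITE: tuple(str(x).strip() for x in metabolites),
            DRUG: tuple(str(x).strip() for x in drugs),
        }
        lookup: dict[str, tuple[str, int]] = {}
        for ntype, ids in lists.items():
            for idx, nid in enumerate(ids):
                if not nid:
                    raise GraphError(f"empty id at {ntype} position {idx}")
                if nid in lookup:
                    raise GraphError(f"duplicate node id {nid!r} ({lookup[nid][0]} vs {ntype})")
                lookup[nid] = (ntype, idx)
        reg = cls(lists[MICROBE], lists[METABOLITE], lists[DRUG])
        object.__setattr__(reg, "_lookup", lookup)
        return reg

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def ids_of(self, ntype: str) -> tuple[str, ...]:
        return {MICROBE: self.microbes, METABOLITE: self.metabolites, DRUG: self.drugs}[ntype]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._lookup

    def type_of(self, node_id: str) -> str:
        return self._lookup[node_id][0]

    def locate(self, node_id: str) -> tuple[str, int]:
        """Return ``(node_type, per-type index)`` for *node_id*."""
        try:
            return self._lookup[node_id]
        except KeyError:
            raise GraphError(f"unknown node id {node_id!r}") from None


@dataclass
class AssociationMatrix:
    """Binary microbe x drug association matrix ``I``.

    ``provenance`` records whether the matrix holds the full label set or
    a training fold only (GIP similarity must be fit on training folds).
    """

    microbes: tuple[str, ...]
    drugs: tuple[str, ...]
    values: np.ndarray  # (Ns, Nd) uint8
    provenance: str = "full"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.microbes), len(self.drugs)):
            raise GraphError("association matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise GraphError("association matrix entries must be 0/1")
        self.values = self.values.astype(np.uint8)

    @classmethod
    def from_pairs(cls, registry: NodeRegistry, pairs, provenance: str = "full"):
        vals = np.zeros((registry.n_microbes, registry.n_drugs), dtype=np.uint8)
        for m, d in pairs:
            mt, mi = registry.locate(m)
            dt, di = registry.locate(d)
            if mt != MICROBE or dt != DRUG:
                raise GraphError(f"pair ({m!r}, {d!r}) is not (microbe, drug)")
            vals[mi, di] = 1
        return cls(registry.microbes, registry.drugs, vals, provenance)

    def pairs(self) -> list[tuple[str, str]]:
        mi, di = np.nonzero(self.values)
        return [(self.microbes[i], self.drugs[j]) for i, j in zip(mi, di)]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())


@dataclass
class EdgeReport:
    """Ids seen in an edge table but absent from the registry."""

    unknown_ids: set[str] = field(default_factory=set)
    dropped_rows: int = 0


def load_edge_table(path, kind: str, registry: NodeRegistry | None = None):
    """Read a 2-column TSV of edges, deduplicated, weight 1.

    ``kind`` selects the expected endpoint types (``sm``, ``mm``, ``dm``).
    Rows referencing ids missing from *registry* are dropped and reported.
    Returns ``(edges, report)`` where edges is a set of id pairs.
    """
    if kind not in ("sm", "mm", "dm"):
        raise GraphError(f"kind must be one of sm/mm/dm, got {kind!r}")
    edges: set[tuple[str, str]] = set()
    report = EdgeReport()
    src_t, dst_t = _ENDPOINT_TYPES[kind]
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and len(header.rstrip("\n").split("\t")) != 2:
            raise GraphError(f"{path}: header must have 2 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise GraphError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            a, b = parts[0].strip(), parts[1].strip()
            if not a or not b:
                raise GraphError(f"{path}:{lineno}: empty id")
            if registry is not None:
                ok = True
                for nid, want in ((a, src_t), (b, dst_t)):
                    if nid not in registry or registry.type_of(nid) != want:
                        report.unknown_ids.add(nid)
                        ok = False
                if not ok:
                    report.dropped_rows += 1
                    continue
            edges.add(_canonical_pair(kind, a, b))
    if not edges:
        logger.warning("edge table %s (%s) produced no edges", path, kind)
    return edges, report


def load_association_table(path, registry: NodeRegistry | None = None,
                           provenance: str = "full"):
    """Read a TSV of labeled microbe-drug associations.

    Returns an :class:`AssociationMatrix` when a registry is given,
    otherwise the deduplicated pair list.
    """
    pairs: list[tuple[str, str]] = []
    seen = set()
    report = EdgeReport()
    with open(path) as fh:
        fh.readline()  # header: microbe<TAB>drug
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise GraphError(f"{path}:{lineno}: expected 2 columns")
            m, d = parts[0].strip(), parts[1].strip()
            if registry is not None:
                ok = (m in registry and registry.type_of(m) == MICROBE
                      and d in registry and registry.type_of(d) == DRUG)
                if not ok:
                    report.unknown_ids.update(x for x in (m, d) if x not in registry)
                    report.dropped_rows += 1
                    continue
            if (m, d) not in seen:
                seen.add((m, d))
                pairs.append((m, d))
    if registry is None:
        return pairs, report
    return AssociationMatrix.from_pairs(registry, pairs, provenance), report


def _canonical_pair(kind: str, a: str, b: str) -> tuple[str, str]:
    # within-type edges stored once with sorted endpoints; cross-type edges
    # stored as (microbe-or-drug id, metabolite id)
    if kind in ("ss", "mm", "dd"):
        return (a, b) if a <= b else (b, a)
    return (a, b)


class HeteroGraph:
    """The walk substrate: typed nodes plus five typed weighted edge sets.

    Adjacency is precomputed per node in deterministic order (by neighbor
    type in microbe/metabolite/drug order, then per-type index) so that
    step distributions and corpora are reproducible.
    """

    def __init__(self, registry: NodeRegistry, edge_sets: dict[str, dict[tuple[str, str], float]]):
        self.registry = registry
        self.edges: dict[str, dict[tuple[str, str], float]] = {t: {} for t in EDGE_TYPES}
        for etype, es in edge_sets.items():
            if etype not in EDGE_TYPES:
                raise GraphError(f"unknown edge type {etype!r}")
            src_t, dst_t = _ENDPOINT_TYPES[etype]
            for (a, b), w in es.items():
                ta, _ = registry.locate(a)
                tb, _ = registry.locate(b)
                if (ta, tb) != (src_t, dst_t):
                    raise GraphError(
                        f"edge ({a!r}, {b!r}) typed {etype} but endpoints are ({ta}, {tb})")
                if a == b:
                    raise GraphError(f"self-loop {a!r} in {etype}")
                if etype in ("sm", "mm", "dm") and w != 1:
                    raise GraphError(f"{etype} edge ({a}, {b}) must have weight 1, got {w}")
                if etype in ("ss", "dd") and not (0 < w <= 1):
                    raise GraphError(f"{etype} edge ({a}, {b}) weight {w} outside (0, 1]")
                self.edges[etype][_canonical_pair(etype, a, b)] = float(w)
        self._adj = self._build_adjacency()

    def _build_adjacency(self):
        adj: dict[str, list[tuple[str, float, str]]] = {
            nid: [] for t in NODE_TYPES for nid in self.registry.ids_of(t)}
        for etype, es in self.edges.items():
            for (a, b), w in es.items():
                adj[a].append((b, w, etype))
                adj[b].append((a, w, etype))
        order = {t: i for i, t in enumerate(NODE_TYPES)}
        for nid, lst in adj.items():
            lst.sort(key=lambda e: (order[self.registry.type_of(e[0])],
                                    self.registry.locate(e[0])[1]))
        return adj

    # -- queries ---------------------------------------------------------
    def neighbors(self, v: str, type_filter: str | None = None):
        """Neighbors of *v* as ``(node id, edge weight, edge type)`` triples.

        Deterministic order: neighbor type (microbe, metabolite, drug),
        then per-type index. Undirected edges are visible from both ends.
        """
        self.registry.locate(v)
        lst = self._adj[v]
        if type_filter is None:
            return list(lst)
        if type_filter not in NODE_TYPES:
            raise GraphError(f"unknown node type {type_filter!r}")
        return [e for e in lst if self.registry.type_of(e[0]) == type_filter]

    def edge_type(self, u: str, v: str) -> str:
        """The edge-type map Q(u, v); raises for non-edges."""
        tu = self.registry.type_of(u)
        tv = self.registry.type_of(v)
        for etype, (sa, sb) in _ENDPOINT_TYPES.items():
            key = None
            if (tu, tv) == (sa, sb):
                key = _canonical_pair(etype, u, v)
            elif (tv, tu) == (sa, sb):
                key = _canonical_pair(etype, v, u)
            if key is not None and key in self.edges[etype]:
                return etype
        raise GraphError(f"no edge between {u!r} and {v!r}")

    def present_edge_types(self) -> set[str]:
        return {t for t, es in self.edges.items() if es}

    def n_edges(self) -> int:
        return sum(len(es) for es in self.edges.values())

    # -- I/O -------------------------------------------------------------
    def save(self, out_dir):
        """Write ``nodes.tsv`` and ``edges.tsv`` (weights at 17 sig digits)."""
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "nodes.tsv"), "w") as fh:
            fh.write("id\ttype\n")
            for t in NODE_TYPES:
                for nid in self.registry.ids_of(t):
                    fh.write(f"{nid}\t{t}\n")
        with open(os.path.join(out_dir, "edges.tsv"), "w") as fh:
            fh.write("source\ttarget\ttype\tweight\n")
            for etype in EDGE_TYPES:
                for (a, b), w in sorted(self.edges[etype].items()):
                    fh.write(f"{a}\t{b}\t{etype}\t{w:.17g}\n")

    @classmethod
    def load(cls, in_dir) -> "HeteroGraph":
        nodes = pd.read_csv(os.path.join(in_dir, "nodes.tsv"), sep="\t", dtype=str)
        by_type = {t: [] for t in NODE_TYPES}
        for _, row in nodes.iterrows():
            if row["type"] not in NODE_TYPES:
                raise GraphError(f"unknown node type {row['type']!r} in nodes.tsv")
            by_type[row["type"]].append(row["id"])
        registry = NodeRegistry.build(by_type[MICROBE], by_type[METABOLITE], by_type[DRUG])
        edges = pd.read_csv(os.path.join(in_dir, "edges.tsv"), sep="\t",
                            dtype={"source": str, "target": str, "type": str, "weight": float},
                            float_precision="round_trip")
        edge_sets: dict[str, dict[tuple[str, str], float]] = {t: {} for t in EDGE_TYPES}
        for _, row in edges.iterrows():
            edge_sets[row["type"]][(row["source"], row["target"])] = row["weight"]
        return cls(registry, edge_sets)


def assemble_graph(registry: NodeRegistry, sm_edges, mm_edges, dm_edges,
                   microbe_sim, drug_sim, alpha: float = 0.65) -> HeteroGraph:
    """Assemble the heterogeneous graph from edge tables and similarities.

    Similarity-gated edges: a microbe-microbe (drug-drug) edge is created
    iff the aggregated similarity is strictly above the threshold
    ``alpha`` (default 0.65), and carries the similarity as its weight.
    Metabolite-touching edge sets are copied with weight 1.

    *microbe_sim* / *drug_sim* are :class:`~metamda.similarity.SimilarityMatrix`
    instances (or anything with ``ids`` and ``values``).
    """
    if not (0.0 <= alpha <= 1.0):
        raise GraphError(f"alpha must lie in [0, 1], got {alpha}")
    edge_sets: dict[str, dict[tuple[str, str], float]] = {t: {} for t in EDGE_TYPES}
    for kind, table in (("sm", sm_edges), ("mm", mm_edges), ("dm", dm_edges)):
        for a, b in table:
            edge_sets[kind][_canonical_pair(kind, a, b)] = 1.0
    for etype, sim, ids in (("ss", microbe_sim, registry.microbes),
                            ("dd", drug_sim, registry.drugs)):
        if sim is None:
            continue
        _check_similarity(sim, ids, etype)
        vals = np.asarray(sim.values, dtype=float)
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if vals[i, j] > alpha:
                    edge_sets[etype][_canonical_pair(etype, ids[i], ids[j])] = float(vals[i, j])
    return HeteroGraph(registry, edge_sets)


def _check_similarity(sim, ids, label):
    vals = np.asarray(sim.values, dtype=float)
    if tuple(sim.ids) != tuple(ids):
        raise GraphError(f"{label}: similarity ids do not match registry order")
    if vals.shape != (len(ids), len(ids)):
        raise GraphError(f"{label}: similarity matrix has wrong shape")
    if not np.allclose(vals, vals.T, atol=1e-9):
        raise GraphError(f"{label}: similarity matrix is not symmetric")
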