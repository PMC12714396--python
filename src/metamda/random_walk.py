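"""Typed random walks on the microbe-metabolite-drug graph.

Two transition strategies, selected by the type of the current node:

* at a **metabolite**, the next node is drawn with probability
  proportional to ``w_vn * M[Q(u,v), Q(v,n)]`` where ``M`` is the 5x5
  edge-type transition matrix and ``Q`` the edge-type map (at a walk
  start, with no previous node, the ``M`` factor is 1);
* at a **microbe or drug** ``v``, a gate ``rho(v)`` splits the
  probability mass: with mass ``rho(v)`` the walker moves to a
  same-type neighbor (probability proportional to the similarity edge
  weight), with mass ``1 - rho(v)`` to a metabolite neighbor
  (proportional to ``w_vn``, 1 by default).

The gate is ``rho(v) = 1`` when v has no metabolite edges at all
(``T = 0``), otherwise ``f(S_v_max)`` with the steep sigmoid
``f(x) = 1 / (1 + exp(-k (x - t)))`` (k=100, t=0.85) applied to the
highest similarity among v's same-type neighbors; a node with
metabolite edges but no same-type neighbors has ``rho = 0``. The
intuition: a microbe or drug without strongly similar same-type
neighbors should route its walks through the metabolite space, where
the mechanistic microbe-metabolite-drug paths live.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .mmd_graph import DRUG, EDGE_TYPE_INDEX, METABOLITE, MICROBE, GraphError, HeteroGraph

__all__ = [
    "WalkConfig", "WalkCorpus", "WalkEngine", "rho", "sigmoid_gate",
    "metabolite_step_probs", "typed_step_probs", "generate_corpus",
]


@dataclass(frozen=True)
class WalkConfig:
    """Walk budget and gate parameters.

    ``walk_length`` counts nodes, so a length-10 walk makes 9
    transitions. ``w_default`` and ``alpha_pq`` are the constant edge
    weight / normalization factor of the transition laws (both 1).
    """

    walks_per_node: int = 100
    walk_length: int = 10
    k: float = 100.0
    t: float = 0.85
    w_default: float = 1.0
    alpha_pq: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if not (0.0 < self.t < 1.0):
            raise ValueError("t must lie in (0, 1)")

    def with_seed(self, seed: int) -> "WalkConfig":
        return replace(self, seed=seed)


@dataclass
class WalkCorpus:
    """Node sequences from the walker, plus node types for the skip-gram."""

    sentences: list[list[str]]
    node_types: dict[str, str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.sentences)

    def save(self, corpus_path, types_path=None):
        with open(corpus_path, "w") as fh:
            for sent in self.sentences:
                fh.write(" ".join(sent) + "\n")
        if types_path is None:
            types_path = os.fspath(corpus_path) + ".types.tsv"
        with open(types_path, "w") as fh:
            fh.write("id\ttype\n")
            for nid in sorted(self.node_types):
                fh.write(f"{nid}\t{self.node_types[nid]}\n")

    @classmethod
    def load(cls, corpus_path, types_path=None) -> "WalkCorpus":
        with open(corpus_path) as fh:
            sentences = [line.split() for line in fh if line.strip()]
        if types_path is None:
            types_path = os.fspath(corpus_path) + ".types.tsv"
        node_types = {}
        with open(types_path) as fh:
            fh.readline()
            for line in fh:
                nid, ntype = line.rstrip("\n").split("\t")
                node_types[nid] = ntype
        return cls(sentences, node_types)


def sigmoid_gate(x: float, k: float = 100.0, t: float = 0.85) -> float:
    """The gate sigmoid f(x) = 1 / (1 + exp(-k (x - t)))."""
    return 1.0 / (1.0 + math.exp(-k * (x - t)))


def rho(graph: HeteroGraph, v: str, cfg: WalkConfig = WalkConfig()) -> float:
    """Same-type-move gate for a microbe or drug node.

    Returns 1 when v has no metabolite edges (T = 0); otherwise
    ``f(S_v_max)`` over the same-type neighbor similarities, or 0 when
    there is no same-type neighbor to move to.
    """
    ntype = graph.registry.type_of(v)
    if ntype not in (MICROBE, DRUG):
        raise GraphError(f"rho is defined for microbe/drug nodes, not {ntype}")
    t_count = len(graph.neighbors(v, METABOLITE))
    if t_count == 0:
        return 1.0
    same = graph.neighbors(v, ntype)
    if not same:
        return 0.0
    s_max = max(w for _, w, _ in same)
    return sigmoid_gate(s_max, cfg.k, cfg.t)


def metabolite_step_probs(graph: HeteroGraph, M, u: str | None, v: str,
                          cfg: WalkConfig = WalkConfig()):
    """Next-node law at a metabolite: p(n) prop. to w_vn * M[Q(u,v), Q(v,n)].

    Returns ``(neighbor ids, probabilities)``; both empty when v is
    isolated (the walk truncates). With no previous node the edge-type
    coupling factor is 1 for every candidate.
    """
    if graph.registry.type_of(v) != METABOLITE:
        raise GraphError(f"{v!r} is not a metabolite")
    nbrs = graph.neighbors(v)
    if not nbrs:
        return [], np.array([])
    mvals = np.asarray(M.values if hasattr(M, "values") else M, dtype=float)
    if u is None:
        factors = np.ones(len(nbrs))
    else:
        q_in = EDGE_TYPE_INDEX[graph.edge_type(u, v)]
        factors = np.array([mvals[q_in, EDGE_TYPE_INDEX[et]] for _, _, et in nbrs])
    weights = np.array([w for _, w, _ in nbrs]) * factors * cfg.alpha_pq
    total = weights.sum()
    if total <= 0:
        return [], np.array([])
    return [n for n, _, _ in nbrs], weights / total


def typed_step_probs(graph: HeteroGraph, v: str, u: str | None = None,
                     cfg: WalkConfig = WalkConfig(), rho_value: float | None = None):
    """Next-node law at a microbe/drug: gated two-block distribution.

    Mass ``rho(v)`` goes to same-type neighbors proportionally to the
    similarity edge weight; mass ``1 - rho(v)`` to metabolite neighbors
    proportionally to ``w_vn``. Returns ``(neighbor ids, probabilities)``.
    """
    ntype = graph.registry.type_of(v)
    if ntype not in (MICROBE, DRUG):
        raise GraphError(f"typed step is for microbe/drug nodes, not {ntype}")
    same = graph.neighbors(v, ntype)
    mets = graph.neighbors(v, METABOLITE)
    if not same and not mets:
        return [], np.array([])
    r = rho(graph, v, cfg) if rho_value is None else float(rho_value)
    ids: list[str] = []
    probs: list[float] = []
    if same and r > 0:
        sims = np.array([w for _, w, _ in same])
        block = r * sims / sims.sum()
        ids += [n for n, _, _ in same]
        probs += list(block)
    if mets and r < 1:
        ws = np.array([w for _, w, _ in mets])
        block = (1.0 - r) * ws / ws.sum()
        ids += [n for n, _, _ in mets]
        probs += list(block)
    p = np.asarray(probs)
    total = p.sum()
    if total <= 0:
        return [], np.array([])
    return ids, p / total


class WalkEngine:
    """Caches per-node step distributions for fast corpus generation.

    The typed law at a microbe/drug depends only on the current node
    (alpha_pq is constant); the metabolite law depends additionally on
    the incoming edge type, of which there are at most three (sm, mm,
    dm). Both are precomputed as cumulative distributions.
    """

    def __init__(self, graph: HeteroGraph, M, cfg: WalkConfig = WalkConfig()):
        self.graph = graph
        self.cfg = cfg
        reg = graph.registry
        self.nodes: list[str] = [nid for t in (MICROBE, METABOLITE, DRUG)
                                 for nid in reg.ids_of(t)]
        self._cache: dict[tuple[str, str | None], tuple[list[str], list[str], np.ndarray]] = {}
        for v in self.nodes:
            ntype = reg.type_of(v)
            if ntype == METABOLITE:
                nbrs = graph.neighbors(v)
                incoming = {None} | {et for _, _, et in nbrs}
                for q in incoming:
                    self._cache[(v, q)] = self._metabolite_dist(v, nbrs, M, q)
            else:
                ids, p = typed_step_probs(graph, v, None, cfg)
                etypes = self._etypes_for(v, ids)
                self._cache[(v, None)] = (ids, etypes, np.cumsum(p))

    def _metabolite_dist(self, v, nbrs, M, q_in):
        mvals = np.asarray(M.values if hasattr(M, "values") else M, dtype=float)
        if not nbrs:
            return [], [], np.array([])
        if q_in is None:
            factors = np.ones(len(nbrs))
        else:
            qi = EDGE_TYPE_INDEX[q_in]
            factors = np.array([mvals[qi, EDGE_TYPE_INDEX[et]] for _, _, et in nbrs])
        weights = np.array([w for _, w, _ in nbrs]) * factors
        total = weights.sum()
        if total <= 0:
            return [], [], np.array([])
        ids = [n for n, _, _ in nbrs]
        etypes = [et for _, _, et in nbrs]
        return ids, etypes, np.cumsum(weights / total)

    def _etypes_for(self, v, ids):
        out = []
        for n in ids:
            out.append(self.graph.edge_type(v, n))
        return out

    def step(self, prev: str | None, cur: str, rng: np.random.Generator):
        """One transition; returns ``(next node, edge type)`` or ``(None, None)``."""
        ntype = self.graph.registry.type_of(cur)
        if ntype == METABOLITE:
            q = None if prev is None else self.graph.edge_type(prev, cur)
            ids, etypes, cum = self._cache[(cur, q)]
        else:
            ids, etypes, cum = self._cache[(cur, None)]
        if not ids:
            return None, None
        j = int(np.searchsorted(cum, rng.random(), side="right"))
        j = min(j, len(ids) - 1)
        return ids[j], etypes[j]

    def walk(self, start: str, rng: np.random.Generator, length: int | None = None):
        """A single walk of up to ``length`` nodes (engine default otherwise).

        Returns ``(node sequence, traversed edge types)``; isolated
        starts yield a length-1 sequence.
        """
        if length is None:
            length = self.cfg.walk_length
        seq = [start]
        etypes: list[str] = []
        prev: str | None = None
        while len(seq) < length:
            nxt, et = self.step(prev, seq[-1], rng)
            if nxt is None:
                break
            etypes.append(et)
            prev = seq[-1]
            seq.append(nxt)
        return seq, etypes


def _walk_rng(seed: int, node_index: int, walk_index: int) -> np.random.Generator:
    # per-walk stream keyed by (node, walk) so corpora are independent of
    # generation order
    ss = np.random.SeedSequence(seed, spawn_key=(node_index, walk_index))
    return np.random.default_rng(ss)


def generate_corpus(graph: HeteroGraph, M, cfg: WalkConfig = WalkConfig(),
                    collect_edge_types: bool = False):
    """Generate ``walks_per_node`` walks from every node of the graph.

    Walks truncate at dead ends (isolated nodes yield length-1
    sequences, which are kept). Fully reproducible for a given
    ``(graph, M, cfg)``.
    """
    engine = WalkEngine(graph, M, cfg)
    sentences: list[list[str]] = []
    all_etypes: list[list[str]] = []
    for ni, start in enumerate(engine.nodes):
        for wi in range(cfg.walks_per_node):
            rng = _walk_rng(cfg.seed, ni, wi)
            seq, ets = engine.walk(start, rng)
            sentences.append(seq)
            if collect_edge_types:
                all_etypes.append(ets)
    node_types = {nid: graph.registry.type_of(nid) for nid in engine.nodes}
    tag = hashlib.sha1(repr((cfg, len(sentences))).encode()).hexdigest()[:12]
    corpus = WalkCorpus(sentences, node_types, provenance=f"cfg:{tag} seed:{cfg.seed}")
    if collect_edge_types:
        return corpus, all_etypes
    return corpus
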