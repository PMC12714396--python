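"""EM estimation of the 5x5 edge-type transition matrix M.

``M[i, j]`` is the (symmetric) transition weight between edge types i
and j; it couples the incoming and outgoing edge types of a step taken
at a metabolite node. The matrix is estimated from the graph itself:

* **E-step** — generate trial walks under the current M and record,
  per walk, the count vector of traversed edge types;
* **M-step** — for every pair of edge types, set
  ``M[i, j] = sigmoid(Pearson r(counts_i, counts_j))``.

Edge types that co-occur on walks reinforce each other; a pair with a
zero-variance count vector gets r = 0, hence weight 0.5. Edge types
absent from the graph keep their prior value, and the diagonal of a
present type is pinned at r = 1 (perfect self-correlation). All
entries therefore stay in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mmd_graph import EDGE_TYPES, HeteroGraph
from .random_walk import WalkConfig, WalkEngine, _walk_rng

logger = logging.getLogger(__name__)


@dataclass
class EdgeTypeTransitionMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("transition matrix shape mismatch")
        if not np.isfinite(v).all() or (v <= 0).any():
            raise ValueError("transition weights must be finite and strictly positive")
        if not np.allclose(v, v.T):
            raise ValueError("transition matrix must be symmetric")
        self.values = v

    def to_csv(self, path):
        pd.DataFrame(self.values, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "EdgeTypeTransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.columns), df.to_numpy(dtype=float))


def init_uniform() -> EdgeTypeTransitionMatrix:
    """Uniform prior: all transition weights 1 (the M factor cancels)."""
    return EdgeTypeTransitionMatrix(EDGE_TYPES, np.ones((5, 5)))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def em_fit(graph: HeteroGraph, cfg: WalkConfig | None = None,
           iterations: int = 5, walks_per_node: int = 10,
           trial_length: int = 10, seed: int = 0) -> EdgeTypeTransitionMatrix:
    """Fit M by the EM loop over trial walks.

    Trial walks use the full walker (both transition strategies) under
    the current M; ``walks_per_node`` short walks are started from every
    node at each iteration. Fully reproducible given *seed*.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if graph.n_edges() == 0:
        raise ValueError("cannot fit a transition matrix on an edgeless graph")
    cfg = cfg or WalkConfig()
    present = sorted(EDGE_TYPES.index(t) for t in graph.present_edge_types())
    absent = [t for t in EDGE_TYPES if EDGE_TYPES.index(t) not in present]
    if absent:
        logger.info("edge types absent from graph keep prior weights: %s", absent)
    M = init_uniform()
    for it in range(iterations):
        engine = WalkEngine(graph, M, cfg)
        counts = []
        for ni, start in enumerate(engine.nodes):
            for wi in range(walks_per_node):
                rng = _walk_rng(seed * (iterations + 1) + it, ni, wi)
                _, ets = engine.walk(start, rng, length=trial_length)
                vec = np.zeros(5)
                for et in ets:
                    vec[EDGE_TYPES.index(et)] += 1
                counts.append(vec)
        counts = np.asarray(counts)
        vals = M.values.copy()
        for i in present:
            for j in present:
                if i == j:
                    r = 1.0
                else:
                    r = _pearson(counts[:, i], counts[:, j])
                vals[i, j] = vals[j, i] = _sigmoid(r)
        M = EdgeTypeTransitionMatrix(EDGE_TYPES, vals)
    return M
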