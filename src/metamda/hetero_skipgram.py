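"""Node-type-aware skip-gram with negative sampling.

A standard skip-gram-with-negative-sampling trainer with one change
that matters on heterogeneous corpora: for each (center, context)
pair, the negative nodes are drawn only from the node type of the
context node, using per-type unigram^0.75 noise distributions. With
type-blind sampling, a metabolite context is overwhelmingly contrasted
against whichever type dominates the corpus, and the objective mostly
learns to separate node types rather than nodes; restricting negatives
to the context's type keeps the contrast informative.

The trainer is sequential SGD (one update per pair, in corpus order)
with a linearly decaying learning rate, compiled with numba. The
negative sampler is a standalone compiled function so its contract
(same type as the context, never the context itself) can be tested
directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .mmd_graph import DRUG, METABOLITE, MICROBE

__all__ = ["EmbeddingTable", "train_embeddings", "save_embeddings", "load_embeddings"]

_TYPE_CODE = {MICROBE: 0, METABOLITE: 1, DRUG: 2}


@dataclass
class EmbeddingTable:
    ids: tuple[str, ...]
    vectors: np.ndarray  # (V, d) float32
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("vector count does not match id list")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding values")
        self._index = {nid: i for i, nid in enumerate(self.ids)}

    def __contains__(self, nid: str) -> bool:
        return nid in self._index

    def __getitem__(self, nid: str) -> np.ndarray:
        return self.vectors[self._index[nid]]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@njit(cache=True)
def _rand_u64(state):
    # xorshift64*: fast, reproducible across platforms
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return x * np.uint64(2685821657736338717)


@njit(cache=True)
def _rand_uniform(state):
    return float(_rand_u64(state) >> np.uint64(11)) / 9007199254740992.0


@njit(cache=True)
def sample_negative(ctx, ctx_type, type_cum, type_nodes, type_sizes, state):
    """Draw one negative for a context node: same type, never the context.

    ``type_cum[t, :type_sizes[t]]`` is the cumulative unigram^0.75 noise
    distribution over ``type_nodes[t]``. Returns -1 when the context's
    type has no other node to sample.
    """
    n = type_sizes[ctx_type]
    if n <= 1:
        return -1
    for _ in range(32):
        u = _rand_uniform(state)
        lo, hi = 0, n - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if type_cum[ctx_type, mid] < u:
                lo = mid + 1
            else:
                hi = mid
        cand = type_nodes[ctx_type, lo]
        if cand != ctx:
            return cand
    return -1


@njit(cache=True)
def _train_sgns(tokens, offsets, token_types, type_cum, type_nodes, type_sizes,
                W, C, window, negatives, epochs, lr0, min_lr, seed):
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed * 2654435761 + 1)
    d = W.shape[1]
    # count pairs once for the lr schedule
    total_pairs = 0
    for s in range(len(offsets) - 1):
        length = offsets[s + 1] - offsets[s]
        for i in range(length):
            lo = max(0, i - window)
            hi = min(length, i + window + 1)
            total_pairs += hi - lo - 1
    total_updates = total_pairs * epochs
    done = 0
    neu1e = np.zeros(d, dtype=np.float32)
    for _ep in range(epochs):
        for s in range(len(offsets) - 1):
            start, end = offsets[s], offsets[s + 1]
            length = end - start
            for i in range(length):
                center = tokens[start + i]
                lo = max(0, i - window)
                hi = min(length, i + window + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = tokens[start + j]
                    lr = lr0 * (1.0 - done / total_updates)
                    if lr < min_lr:
                        lr = min_lr
                    done += 1
                    for kk in range(d):
                        neu1e[kk] = 0.0
                    for neg in range(negatives + 1):
                        if neg == 0:
                            target = ctx
                            label = 1.0
                        else:
                            target = sample_negative(ctx, token_types[ctx], type_cum,
                                                     type_nodes, type_sizes, state)
                            if target < 0:
                                continue
                            label = 0.0
                        dot = 0.0
                        for kk in range(d):
                            dot += W[center, kk] * C[target, kk]
                        if dot > 8.0:
                            f = 1.0
                        elif dot < -8.0:
                            f = 0.0
                        else:
                            f = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - f) * lr
                        for kk in range(d):
                            neu1e[kk] += g * C[target, kk]
                        for kk in range(d):
                            C[target, kk] += g * W[center, kk]
                    for kk in range(d):
                        W[center, kk] += neu1e[kk]


def _build_noise_tables(counts: np.ndarray, type_codes: np.ndarray):
    """Per-type unigram^0.75 cumulative distributions (padded 2D arrays)."""
    n_types = 3
    sizes = np.zeros(n_types, dtype=np.int64)
    node_lists = []
    for t in range(n_types):
        members = np.where(type_codes == t)[0]
        node_lists.append(members)
        sizes[t] = len(members)
    width = max(1, int(sizes.max()))
    type_cum = np.ones((n_types, width), dtype=np.float64)
    type_nodes = np.zeros((n_types, width), dtype=np.int64)
    for t in range(n_types):
        members = node_lists[t]
        if len(members) == 0:
            continue
        type_nodes[t, :len(members)] = members
        w = counts[members].astype(np.float64) ** 0.75
        cum = np.cumsum(w / w.sum())
        cum[-1] = 1.0
        type_cum[t, :len(members)] = cum
    return type_cum, type_nodes, sizes


def train_embeddings(corpus, d: int = 1024, window: int = 9, negatives: int = 5,
                     epochs: int = 5, seed: int = 0, lr: float = 0.025,
                     min_lr: float = 1e-4, min_count: int = 1) -> EmbeddingTable:
    """Train type-aware SGNS embeddings on a walk corpus.

    Defaults follow the framework's operating point (d=1024, window=9);
    negatives/epochs/learning rate are the usual skip-gram settings.
    Deterministic for a fixed seed (single-threaded trainer).
    """
    if d < 1 or window < 1:
        raise ValueError("d and window must be >= 1")
    counts = Counter(tok for sent in corpus.sentences for tok in sent)
    vocab = sorted(nid for nid, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("empty vocabulary")
    index = {nid: i for i, nid in enumerate(vocab)}
    type_codes = np.array([_TYPE_CODE[corpus.node_types[nid]] for nid in vocab],
                          dtype=np.int64)
    tokens: list[int] = []
    offsets = [0]
    n_pairs_possible = 0
    for sent in corpus.sentences:
        kept = [index[t] for t in sent if t in index]
        if len(kept) >= 2:
            n_pairs_possible += 1
        tokens.extend(kept)
        offsets.append(len(tokens))
    if n_pairs_possible == 0:
        raise ValueError("corpus yields no (center, context) pairs")
    freq = np.array([counts[nid] for nid in vocab], dtype=np.int64)
    type_cum, type_nodes, sizes = _build_noise_tables(freq, type_codes)
    rng = np.random.default_rng(seed)
    W = ((rng.random((len(vocab), d)) - 0.5) / d).astype(np.float32)
    C = np.zeros((len(vocab), d), dtype=np.float32)
    _train_sgns(np.asarray(tokens, dtype=np.int64), np.asarray(offsets, dtype=np.int64),
                type_codes, type_cum, type_nodes, sizes, W, C,
                window, negatives, epochs, lr, min_lr, seed)
    meta = {"d": d, "window": window, "negatives": negatives, "epochs": epochs,
            "seed": seed, "min_count": min_count}
    # input (center) vectors are the node embeddings
    return EmbeddingTable(tuple(vocab), W, meta)


def save_embeddings(table: EmbeddingTable, path):
    """word2vec text format: header ``N d``, then one node per line."""
    with open(path, "w") as fh:
        fh.write(f"{len(table.ids)} {table.dim}\n")
        for nid, vec in zip(table.ids, table.vectors):
            fh.write(nid + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def load_embeddings(path) -> EmbeddingTable:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("bad embedding header (expected 'N d')")
        n, d = int(header[0]), int(header[1])
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(f"embedding row for {parts[0]!r} has wrong dimension")
            ids.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.float32))
    if len(ids) != n:
        raise ValueError(f"header says {n} rows, file has {len(ids)}")
    return EmbeddingTable(tuple(ids), np.vstack(rows))
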