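"""Synthetic microbe-metabolite-drug datasets with planted structure.

The generator emulates the real inputs (production/consumption edges,
reaction-pair edges, drug-metabolite edges, functional similarity
matrices, labeled associations) with a planted-partition design:
microbes, metabolites and drugs are assigned to latent groups, and a
microbe and a drug are truly associated iff they share a group. The
association is *mediated*: within-group microbe-metabolite and
drug-metabolite edges appear with probability ``p_in``, cross-group
edges with ``p_out``, so true pairs are linked through shared
metabolites — the mechanism the pipeline is built to exploit. A stated
fraction of the true pairs is observed as labels; the rest is held-out
ground truth.

The planted signal in the functional similarity matrices is scaled by
the normalized edge contrast ``(p_in - p_out) / max(p_in, p_out)``, so
a single pair of probabilities controls all planted structure:
``p_in = p_out`` is a complete null in which group membership is
unrecoverable from any input.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from .evaluation import MDADataset
from .mmd_graph import NodeRegistry
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    ns: int = 30            # microbes
    nm: int = 40            # metabolites
    nd: int = 30            # drugs
    n_groups: int = 3
    p_in: float = 0.5       # within-group SM/DM edge probability
    p_out: float = 0.02     # cross-group SM/DM edge probability
    mm_density: float = 0.05
    sigma: float = 0.1      # similarity noise sd
    label_fraction: float = 0.5  # share of true pairs observed as labels
    seed: int = 0

    def __post_init__(self):
        for name in ("p_in", "p_out", "mm_density", "label_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.p_in < self.p_out:
            raise ValueError("p_in < p_out gives an adversarial planting; use p_in >= p_out")
        if self.n_groups < 1 or min(self.ns, self.nm, self.nd) < self.n_groups:
            raise ValueError("each node class needs at least n_groups members")


def _assign_groups(rng, n, n_groups):
    for attempt in range(100):
        groups = rng.integers(0, n_groups, size=n)
        if len(np.unique(groups)) == n_groups:
            if attempt:
                logger.info("group assignment redrawn %d time(s)", attempt)
            return groups
    raise RuntimeError("could not draw a group assignment without empty groups")


def _noisy_group_similarity(rng, groups, signal, sigma):
    n = len(groups)
    base = (groups[:, None] == groups[None, :]).astype(float) * signal
    noise = rng.normal(0.0, sigma, size=(n, n))
    vals = np.clip(base + 0.5 * (noise + noise.T), 0.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    return vals


def generate(cfg: SynthConfig = SynthConfig()):
    """Generate a dataset; returns ``(MDADataset, truth, groups)``.

    *truth* is the full set of planted (microbe, drug) pairs (labeled
    ones included); *groups* maps each node id to its latent group.
    """
    rng = np.random.default_rng(cfg.seed)
    microbes = tuple(f"microbe{i:03d}" for i in range(cfg.ns))
    metabolites = tuple(f"met{i:03d}" for i in range(cfg.nm))
    drugs = tuple(f"drug{i:03d}" for i in range(cfg.nd))
    registry = NodeRegistry.build(microbes, metabolites, drugs)

    g_s = _assign_groups(rng, cfg.ns, cfg.n_groups)
    g_m = _assign_groups(rng, cfg.nm, cfg.n_groups)
    g_d = _assign_groups(rng, cfg.nd, cfg.n_groups)

    def bipartite(row_ids, row_groups, col_ids, col_groups):
        probs = np.where(row_groups[:, None] == col_groups[None, :], cfg.p_in, cfg.p_out)
        draw = rng.random(probs.shape) < probs
        return {(row_ids[i], col_ids[j]) for i, j in zip(*np.nonzero(draw))}

    sm_edges = bipartite(microbes, g_s, metabolites, g_m)
    dm_edges = bipartite(drugs, g_d, metabolites, g_m)
    mm_edges = set()
    for i in range(cfg.nm):
        for j in range(i + 1, cfg.nm):
            if rng.random() < cfg.mm_density:
                mm_edges.add((metabolites[i], metabolites[j]))

    signal = ((cfg.p_in - cfg.p_out) / cfg.p_in) if cfg.p_in > 0 else 0.0
    microbe_functional = SimilarityMatrix(
        microbes, _noisy_group_similarity(rng, g_s, signal, cfg.sigma))
    drug_functional = SimilarityMatrix(
        drugs, _noisy_group_similarity(rng, g_d, signal, cfg.sigma))

    truth = [(microbes[i], drugs[j])
             for i in range(cfg.ns) for j in range(cfg.nd) if g_s[i] == g_d[j]]
    n_labeled = int(round(cfg.label_fraction * len(truth)))
    labeled_idx = rng.choice(len(truth), size=n_labeled, replace=False)
    positives = [truth[i] for i in sorted(labeled_idx)]

    dataset = MDADataset(registry, sm_edges, mm_edges, dm_edges,
                         microbe_functional, drug_functional, positives)
    groups = {**{microbes[i]: int(g_s[i]) for i in range(cfg.ns)},
              **{metabolites[i]: int(g_m[i]) for i in range(cfg.nm)},
              **{drugs[i]: int(g_d[i]) for i in range(cfg.nd)}}
    return dataset, set(truth), groups


def write_dataset(dataset: MDADataset, truth, out_dir):
    """Write the dataset in the same formats the real loaders consume."""
    os.makedirs(out_dir, exist_ok=True)

    def write_edges(name, edges):
        with open(os.path.join(out_dir, name), "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in sorted(edges):
                fh.write(f"{a}\t{b}\n")

    write_edges("sm_edges.tsv", dataset.sm_edges)
    write_edges("mm_edges.tsv", dataset.mm_edges)
    write_edges("dm_edges.tsv", dataset.dm_edges)
    with open(os.path.join(out_dir, "associations.tsv"), "w") as fh:
        fh.write("microbe\tdrug\n")
        for m, d in dataset.positives:
            fh.write(f"{m}\t{d}\n")
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("microbe\tdrug\n")
        for m, d in sorted(truth):
            fh.write(f"{m}\t{d}\n")
    with open(os.path.join(out_dir, "nodes.tsv"), "w") as fh:
        fh.write("id\ttype\n")
        for t, ids in (("microbe", dataset.registry.microbes),
                       ("metabolite", dataset.registry.metabolites),
                       ("drug", dataset.registry.drugs)):
            for nid in ids:
                fh.write(f"{nid}\t{t}\n")
    dataset.microbe_functional.to_csv(os.path.join(out_dir, "microbe_functional.csv"))
    dataset.drug_functional.to_csv(os.path.join(out_dir, "drug_functional.csv"))


def load_dataset(in_dir) -> tuple[MDADataset, set]:
    """Round-trip loader for :func:`write_dataset` output."""
    import pandas as pd

    from .mmd_graph import load_association_table, load_edge_table

    nodes = pd.read_csv(os.path.join(in_dir, "nodes.tsv"), sep="\t", dtype=str)
    by_type = {t: list(nodes[nodes["type"] == t]["id"]) for t in
               ("microbe", "metabolite", "drug")}
    registry = NodeRegistry.build(by_type["microbe"], by_type["metabolite"],
                                  by_type["drug"])
    sm, _ = load_edge_table(os.path.join(in_dir, "sm_edges.tsv"), "sm", registry)
    mm, _ = load_edge_table(os.path.join(in_dir, "mm_edges.tsv"), "mm", registry)
    dm, _ = load_edge_table(os.path.join(in_dir, "dm_edges.tsv"), "dm", registry)
    assoc, _ = load_association_table(os.path.join(in_dir, "associations.tsv"), registry)
    microbe_f = SimilarityMatrix.from_csv(os.path.join(in_dir, "microbe_functional.csv"))
    drug_f = SimilarityMatrix.from_csv(os.path.join(in_dir, "drug_functional.csv"))
    truth_path = os.path.join(in_dir, "truth.tsv")
    truth: set = set()
    if os.path.exists(truth_path):
        pairs, _ = load_association_table(truth_path)
        truth = set(pairs)
    return MDADataset(registry, sm, mm, dm, microbe_f, drug_f, assoc.pairs()), truth
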