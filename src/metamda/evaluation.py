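"""Cross-validation protocol, negative sampling and metrics.

Observed associations are split into k equal folds; each fold serves
once as the test set while the rest train the pipeline. Per fold, the
GIP similarity from the association matrix is recomputed from the
training positives only, the graph is reassembled, the transition
matrix refit, walks and embeddings regenerated — no held-out positive
influences any training-time quantity. Metabolite-side edges and the
functional similarities do not depend on labels and stay fold-invariant.

Negatives are sampled uniformly (1:1 by default) from unlabeled
microbe-drug pairs; methods that score all unlabeled pairs as
negatives inflate accuracy under class imbalance, which is why
AUROC/AUPR on balanced samples are the headline metrics here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import similarity as sim_mod
from .mmd_graph import AssociationMatrix, NodeRegistry, assemble_graph
from .hetero_skipgram import train_embeddings
from .predictor import ClassifierSpec, pair_features, score_pairs, train_classifier
from .random_walk import WalkConfig, generate_corpus
from .transition_model import em_fit

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """The four headline metrics plus confusion counts at the threshold."""

    auroc: float
    aupr: float
    acc: float
    f1: float
    precision: float
    recall: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auroc", "aupr", "acc", "f1", "precision", "recall",
                 "tp", "fp", "tn", "fn")}


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """AUROC (rank statistic), AUPR (PR step integration), ACC and F1.

    ACC = (TP+TN)/(TP+TN+FP+FN); F1 = 2 P R / (P + R) with
    P = TP/(TP+FP), R = TP/(TP+FN), at the given score threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to compute AUROC/AUPR")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    acc = (tp + tn) / len(labels)
    return MetricReport(
        auroc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        acc=acc, f1=f1, precision=precision, recall=recall,
        tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """ACC/F1/precision/recall straight from confusion counts."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    return {"acc": acc, "f1": f1, "precision": precision, "recall": recall}


@dataclass
class FoldPlan:
    """Partition of the positives plus per-fold sampled negatives."""

    k: int
    folds: list[list[tuple[str, str]]]
    negatives: list[list[tuple[str, str]]]
    seed: int

    def train_positives(self, fold: int) -> list[tuple[str, str]]:
        return [p for f, fold_pairs in enumerate(self.folds) if f != fold
                for p in fold_pairs]


def make_folds(positives, k: int, seed: int, universe=None,
               negative_ratio: float = 1.0, exclude=None) -> FoldPlan:
    """Uniform random k-fold split with per-fold negative samples.

    Fold sizes differ by at most one. Negatives are drawn without
    replacement from *universe* (all microbe-drug pairs) minus the
    positives minus *exclude*; with the default 1:1 ratio each fold
    gets as many negatives as it has held-out positives.
    """
    positives = list(dict.fromkeys(tuple(p) for p in positives))
    if len(positives) < k:
        raise ValueError(f"{len(positives)} positives cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds: list[list[tuple[str, str]]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(positives[idx])
    negatives: list[list[tuple[str, str]]] = [[] for _ in range(k)]
    if universe is not None:
        forbidden = set(positives) | set(tuple(p) for p in (exclude or ()))
        candidates = [p for p in universe if tuple(p) not in forbidden]
        need = [int(round(negative_ratio * len(f))) for f in folds]
        total = sum(need)
        if total > len(candidates):
            raise ValueError("not enough unlabeled pairs to sample negatives")
        chosen = rng.choice(len(candidates), size=total, replace=False)
        flat = [tuple(candidates[i]) for i in chosen]
        at = 0
        for f in range(k):
            negatives[f] = flat[at:at + need[f]]
            at += need[f]
    return FoldPlan(k, folds, negatives, seed)


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run."""

    alpha: float = 0.65
    walk: WalkConfig = field(default_factory=WalkConfig)
    embed_dim: int = 1024
    window: int = 9
    negatives: int = 5
    epochs: int = 5
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    em_iterations: int = 5
    em_walks_per_node: int = 10
    negative_ratio: float = 1.0


@dataclass
class MDADataset:
    """Everything run_cv needs: the label-free graph inputs plus labels."""

    registry: NodeRegistry
    sm_edges: set
    mm_edges: set
    dm_edges: set
    microbe_functional: "sim_mod.SimilarityMatrix | None"
    drug_functional: "sim_mod.SimilarityMatrix | None"
    positives: list[tuple[str, str]]

    def bipartite_matrix(self, edges, row_ids, col_ids) -> np.ndarray:
        rows = {r: i for i, r in enumerate(row_ids)}
        cols = {c: j for j, c in enumerate(col_ids)}
        mat = np.zeros((len(row_ids), len(col_ids)))
        for a, b in edges:
            mat[rows[a], cols[b]] = 1.0
        return mat

    @property
    def sm_matrix(self) -> np.ndarray:
        return self.bipartite_matrix(self.sm_edges, self.registry.microbes,
                                     self.registry.metabolites)

    @property
    def dm_matrix(self) -> np.ndarray:
        return self.bipartite_matrix(self.dm_edges, self.registry.drugs,
                                     self.registry.metabolites)

    def universe(self) -> list[tuple[str, str]]:
        return [(m, d) for m in self.registry.microbes for d in self.registry.drugs]


def fit_fold(dataset: MDADataset, train_positives, cfg: PipelineConfig, seed: int,
             keep_artifacts: bool = False):
    """Train the full pipeline on one fold's training positives.

    Returns ``(model, embeddings, artifacts)``; artifacts (graph, M,
    train association matrix) are kept only on request.
    """
    reg = dataset.registry
    train_I = AssociationMatrix.from_pairs(reg, train_positives, "training-fold")
    microbe_sim = sim_mod.microbe_similarity(train_I, dataset.sm_matrix,
                                             functional=dataset.microbe_functional)
    drug_sim = sim_mod.drug_similarity(train_I, dataset.dm_matrix,
                                       functional=dataset.drug_functional)
    graph = assemble_graph(reg, dataset.sm_edges, dataset.mm_edges, dataset.dm_edges,
                           microbe_sim, drug_sim, alpha=cfg.alpha)
    walk_cfg = cfg.walk.with_seed(seed)
    M = em_fit(graph, walk_cfg, iterations=cfg.em_iterations,
               walks_per_node=cfg.em_walks_per_node, seed=seed)
    corpus = generate_corpus(graph, M, walk_cfg)
    embeddings = train_embeddings(corpus, d=cfg.embed_dim, window=cfg.window,
                                  negatives=cfg.negatives, epochs=cfg.epochs,
                                  seed=seed)
    artifacts = {}
    if keep_artifacts:
        artifacts = {"graph": graph, "M": M, "train_I": train_I, "corpus": corpus}
    return embeddings, artifacts


@dataclass
class CVReport:
    folds: list[MetricReport]
    means: dict
    artifacts: list[dict] = field(default_factory=list)


def run_cv(dataset: MDADataset, cfg: PipelineConfig = PipelineConfig(), k: int = 5,
           seed: int = 0, negative_exclude=None, keep_artifacts: bool = False) -> CVReport:
    """k-fold cross-validation of the full pipeline.

    *negative_exclude* optionally removes known true pairs (e.g. a
    simulation's ground truth) from the negative-sampling universe.
    """
    plan = make_folds(dataset.positives, k, seed, universe=dataset.universe(),
                      negative_ratio=cfg.negative_ratio, exclude=negative_exclude)
    reports: list[MetricReport] = []
    all_artifacts: list[dict] = []
    rng = np.random.default_rng(seed + 104729)
    forbidden_base = set(tuple(p) for p in dataset.positives)
    if negative_exclude:
        forbidden_base |= set(tuple(p) for p in negative_exclude)
    for fold in range(plan.k):
        fold_seed = seed + 7919 * (fold + 1)
        train_pos = plan.train_positives(fold)
        test_pos = plan.folds[fold]
        test_neg = plan.negatives[fold]
        embeddings, artifacts = fit_fold(dataset, train_pos, cfg, fold_seed,
                                         keep_artifacts)
        # training negatives: unlabeled pairs, disjoint from this fold's
        # test negatives so no test item is seen in training
        forbidden = forbidden_base | set(test_neg)
        candidates = [p for p in dataset.universe() if p not in forbidden]
        idx = rng.choice(len(candidates),
                         size=min(len(train_pos), len(candidates)), replace=False)
        train_neg = [candidates[i] for i in idx]
        feats, _ = pair_features(embeddings, train_pos + train_neg,
                                 [1] * len(train_pos) + [0] * len(train_neg))
        model = train_classifier(feats, cfg.classifier)
        eval_pairs = list(test_pos) + list(test_neg)
        labels = [1] * len(test_pos) + [0] * len(test_neg)
        scored, skipped = score_pairs(model, embeddings, eval_pairs)
        if skipped:
            kept = {p for p, _ in scored}
            labels = [y for p, y in zip(eval_pairs, labels) if tuple(p) in kept]
        report = compute_metrics([s for _, s in scored], labels)
        reports.append(report)
        logger.info("fold %d: AUROC=%.4f AUPR=%.4f ACC=%.4f F1=%.4f",
                    fold, report.auroc, report.aupr, report.acc, report.f1)
        if keep_artifacts:
            all_artifacts.append(artifacts)
    means = {key: float(np.mean([getattr(r, key) for r in reports]))
             for key in ("auroc", "aupr", "acc", "f1", "precision", "recall")}
    return CVReport(reports, means, all_artifacts)
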