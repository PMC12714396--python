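"""Pair features and the boosted-tree association classifier.

A (microbe, drug) pair is represented by the Hadamard (element-wise)
product of the two node embeddings, ``d_uv[j] = z_u[j] * z_v[j]``,
which emphasizes shared embedding directions — i.e. the metabolic
context the two nodes have in common. The default classifier is a
gradient-boosted tree ensemble with K=564 trees and the binary
logistic loss; alternates (logistic regression, random forest, ...)
plug in behind the same interface for ablation.

Because features come from the graph embedding rather than from the
label matrix, nodes with zero labeled associations — e.g. a drug known
only through its metabolite edges — still get scored and ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hetero_skipgram import EmbeddingTable

logger = logging.getLogger(__name__)


@dataclass
class PairFeature:
    microbe: str
    drug: str
    vector: np.ndarray
    label: int | None = None  # 1 / 0 / None (unknown)


@dataclass
class ClassifierSpec:
    """Boosted-tree settings: K weak learners, logistic loss, seeded.

    Tree regularization (gamma, lambda) stays at library defaults.
    ``kind`` selects an alternate model family for ablations.
    """

    n_trees: int = 564
    kind: str = "xgboost"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def pair_features(embeddings: EmbeddingTable, pairs, labels=None):
    """Hadamard features for (microbe, drug) pairs.

    Pairs with a missing embedding are skipped and reported. Returns
    ``(features, skipped)``.
    """
    feats: list[PairFeature] = []
    skipped: list[tuple[str, str]] = []
    labels = list(labels) if labels is not None else [None] * len(pairs)
    for (m, d), y in zip(pairs, labels):
        if m not in embeddings or d not in embeddings:
            skipped.append((m, d))
            continue
        feats.append(PairFeature(m, d, embeddings[m] * embeddings[d], y))
    if skipped:
        logger.warning("skipped %d pairs with missing embeddings", len(skipped))
    return feats, skipped


def _feature_matrix(feats: list[PairFeature]) -> np.ndarray:
    return np.vstack([f.vector for f in feats])


def train_classifier(feats: list[PairFeature], spec: ClassifierSpec = ClassifierSpec()):
    """Fit the classifier on labeled pair features.

    Requires both classes; returns a fitted model exposing
    ``predict_proba``.
    """
    labeled = [f for f in feats if f.label is not None]
    if not labeled:
        raise ValueError("no labeled pairs")
    y = np.array([f.label for f in labeled])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = _feature_matrix(labeled)
    model = _make_model(spec)
    model.fit(X, y)
    return model


def _make_model(spec: ClassifierSpec):
    if spec.kind == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=spec.n_trees, objective="binary:logistic",
                             random_state=spec.seed, n_jobs=1, **spec.extra)
    if spec.kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(n_estimators=spec.n_trees,
                                      random_state=spec.seed, n_jobs=1, **spec.extra)
    if spec.kind == "logistic":
        from sklearn.linear_model import LogisticRegression
        return LogisticRegression(max_iter=1000, random_state=spec.seed, **spec.extra)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


def score_pairs(model, embeddings: EmbeddingTable, pairs):
    """Association probability for each pair; missing embeddings skipped."""
    feats, skipped = pair_features(embeddings, pairs)
    if not feats:
        return [], skipped
    probs = model.predict_proba(_feature_matrix(feats))[:, 1]
    return [((f.microbe, f.drug), float(p)) for f, p in zip(feats, probs)], skipped


def rank_candidates(model, embeddings: EmbeddingTable, query: str,
                    candidates, exclude=()):
    """Rank candidate partners of *query* by predicted score, descending.

    ``candidates`` are the partner ids (microbes for a drug query and
    vice versa); pairs in *exclude* (as (microbe, drug) tuples) are
    omitted. Ties break by candidate id, so rankings are stable. Works
    for queries absent from the labeled data, as long as they are in
    the graph (hence embedded).
    """
    if query not in embeddings:
        raise KeyError(f"query node {query!r} has no embedding")
    exclude = set(exclude)
    pairs = []
    for c in candidates:
        if c == query:
            continue
        pair = (c, query) if (c, query) not in exclude and (query, c) not in exclude else None
        if pair is None:
            continue
        pairs.append((c, query))
    # orientation of (microbe, drug) does not matter for the Hadamard
    # feature; keep (candidate, query) ordering for scoring
    scored, _ = score_pairs(model, embeddings, pairs)
    ranked = sorted(((c, s) for (c, _q), s in scored), key=lambda x: (-x[1], x[0]))
    return ranked


def save_predictions(scored, path):
    """Write a predictions TSV: microbe, drug, score (6 decimals)."""
    with open(path, "w") as fh:
        fh.write("microbe\tdrug\tscore\n")
        for (m, d), s in scored:
            fh.write(f"{m}\t{d}\t{s:.6f}\n")
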