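"""Precision/recall/F scoring, cross-validation, learning curves, key-words.

The positive class is 1 (interaction). F is the harmonic mean
2PR/(P+R). Zero-denominator conventions: precision is 0 when nothing is
predicted positive, recall is 0 when there are no gold positives, F is 0
when P + R = 0.

Cross-validation is stratified at the instance level; each fold's model is
fit from scratch, so vocabularies and random embedding rows are rebuilt
from that fold's training instances only (no information about held-out
surface forms leaks into embedding construction).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._seeds import derive_seed
from .corpus_io import ValidationError
from .estimator import PathCNNClassifier
from .sdp import extract_sequences

logger = logging.getLogger(__name__)

__all__ = ["Metrics", "CvReport", "score", "cross_validate", "learning_curve", "keyword_report"]


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class CvReport:
    folds: list[Metrics]
    fold_assignment: dict[str, int]

    @property
    def mean_precision(self) -> float:
        return float(np.mean([m.precision for m in self.folds]))

    @property
    def mean_recall(self) -> float:
        return float(np.mean([m.recall for m in self.folds]))

    @property
    def mean_f(self) -> float:
        return float(np.mean([m.f for m in self.folds]))


def score(predictions, golds) -> Metrics:
    """Confusion counts and P/R/F for aligned binary label lists."""
    pred = np.asarray(predictions, dtype=int)
    gold = np.asarray(golds, dtype=int)
    if pred.shape != gold.shape:
        raise ValidationError(
            f"prediction/gold length mismatch: {pred.shape} vs {gold.shape}"
        )
    return Metrics(
        tp=int(np.sum((pred == 1) & (gold == 1))),
        fp=int(np.sum((pred == 1) & (gold == 0))),
        fn=int(np.sum((pred == 0) & (gold == 1))),
        tn=int(np.sum((pred == 0) & (gold == 0))),
    )


def _sequences_and_labels(instances, parses, estimator):
    seqs = extract_sequences(parses, instances, truncate=estimator.truncate)
    X = [s.tokens[: s.raw_length] for s in seqs]
    y = np.array([inst.label for inst in instances], dtype=int)
    return X, y


def cross_validate(
    instances,
    parses,
    estimator: PathCNNClassifier | None = None,
    k: int = 10,
    seed: int = 0,
) -> CvReport:
    """Stratified k-fold cross-validation of the path classifier.

    The sdp extraction is deterministic and parse-local, so paths are
    extracted once up front; everything fit from data (vocabulary,
    embeddings, weights) is rebuilt inside each fold.
    """
    if len(instances) < k:
        raise ValidationError(f"need at least k={k} instances, got {len(instances)}")
    estimator = estimator if estimator is not None else PathCNNClassifier()
    X, y = _sequences_and_labels(instances, parses, estimator)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=derive_seed(seed, "folds"))
    folds: list[Metrics] = []
    assignment: dict[str, int] = {}
    for fold_idx, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignment[instances[i].instance_id] = fold_idx
        if not np.any(y[test_idx] == 1):
            logger.warning("fold %d has no positive gold instances", fold_idx)
        model = clone(estimator)
        model.set_params(seed=derive_seed(seed, f"fold:{fold_idx}"))
        model.fit([X[i] for i in train_idx], y[train_idx])
        pred = model.predict([X[i] for i in test_idx])
        folds.append(score(pred, y[test_idx]))
    return CvReport(folds=folds, fold_assignment=assignment)


def learning_curve(
    instances,
    parses,
    estimator: PathCNNClassifier | None = None,
    test_fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    seed: int = 0,
    n_seeds: int = 1,
    min_train: int = 10,
) -> list[tuple[float, Metrics]]:
    """Performance as a function of the held-out test proportion.

    For each fraction, a stratified train/test split is drawn, a fresh
    model trained on the remainder and scored on the test portion; with
    ``n_seeds > 1`` the split/training is repeated and all (fraction,
    Metrics) rows are returned, one per repeat.
    """
    estimator = estimator if estimator is not None else PathCNNClassifier()
    X, y = _sequences_and_labels(instances, parses, estimator)
    rows: list[tuple[float, Metrics]] = []
    for frac in test_fractions:
        if not 0.0 < frac < 1.0:
            raise ValidationError(f"test fraction must be in (0, 1), got {frac}")
        if round(len(y) * (1 - frac)) < min_train:
            logger.warning("fraction %.2f leaves fewer than %d training instances; skipped",
                           frac, min_train)
            continue
        for rep in range(n_seeds):
            s = derive_seed(seed, f"curve:{frac}:{rep}")
            idx_train, idx_test = train_test_split(
                np.arange(len(y)), test_size=frac, stratify=y, random_state=s % (2**31)
            )
            model = clone(estimator)
            model.set_params(seed=s)
            model.fit([X[i] for i in idx_train], y[idx_train])
            pred = model.predict([X[i] for i in idx_test])
            rows.append((float(frac), score(pred, y[idx_test])))
    return rows


def keyword_report(model: PathCNNClassifier, instances, parses) -> list[tuple[str, int]]:
    """Key-word frequencies over predicted-positive instances.

    Every filter of the model nominates one key-word per instance (the
    middle token of its maximally responding window); counts are
    aggregated over all instances the model predicts positive and ranked
    descending, ties broken by token string. On trained models the top
    entries are typically the planted/observed interaction verbs.
    """
    X, _ = _sequences_and_labels(instances, parses, model)
    if not X:
        return []
    pred = model.predict(X)
    counter: Counter[str] = Counter()
    for xi, p in zip(X, pred):
        if p == 1:
            counter.update(model.key_words([xi])[0])
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
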