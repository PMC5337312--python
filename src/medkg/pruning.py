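"""Contextual pruning of meaningless inference chains.

Medical prose is context sensitive: around the sentence stating a relation
R(e1, e2) that takes part in a valid chain, the neighboring entities of the
chain (the precedent relation's e0 and the antecedent relation's far
entity) tend to be co-mentioned.  This module turns that signal into a
binary classification problem: for each relation of a chain, the supporting
sentence plus the N preceding and N following sentences (the N-contextual
sentences, N-CS) are counted into a bag-of-words block; blocks are
concatenated in chain order and followed by per-relation entity-name
term-count blocks.  A standard classifier (naive Bayes, logistic
regression, linear SVM, or an entropy-criterion decision tree) then
separates meaningful from meaningless chains; evaluation is stratified
k-fold cross-validation reporting pooled precision and recall of the
positive (meaningful) class, alongside the accept-everything baseline whose
precision is the positive-class prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .corpus import Document
from .errors import (
    ConfigurationError,
    FeatureError,
    ModelCompatibilityError,
    ProvenanceError,
    TrainingError,
)
from .inference import MEANINGFUL, MEANINGLESS, InferenceChain
from .kg import Relation

CLASSIFIERS = ("naive_bayes", "logistic_regression", "linear_svm", "decision_tree")


@dataclass
class PruningConfig:
    """Configuration of the pruning classifier.

    Defaults: context range N=3, logistic regression, 5-fold stratified CV.
    """

    context_range_n: int = 3
    classifier: str = "logistic_regression"
    cv_folds: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.context_range_n < 0:
            raise ConfigurationError("context_range_n must be >= 0")
        if self.classifier not in CLASSIFIERS:
            raise ConfigurationError(
                f"classifier must be one of {CLASSIFIERS}, got {self.classifier!r}"
            )
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


def build_classifier(name: str, random_seed: int = 0):
    """Library-default classifiers; the decision tree uses the entropy criterion."""
    if name == "naive_bayes":
        return MultinomialNB()
    if name == "logistic_regression":
        return LogisticRegression(max_iter=5000)
    if name == "linear_svm":
        return LinearSVC()
    if name == "decision_tree":
        return DecisionTreeClassifier(criterion="entropy", random_state=random_seed)
    raise ConfigurationError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class ContextWindow:
    """The N-CS sentence indices of one supporting sentence."""

    document_id: str
    sentence_indices: tuple[int, ...]


def extract_ncs(
    relation: Relation, corpus: dict[str, Document], n: int
) -> list[ContextWindow]:
    """One clipped window {s-N, ..., s, ..., s+N} per provenance sentence."""
    if not relation.provenance:
        raise FeatureError(f"relation {relation.key} has no provenance")
    windows = []
    for doc_id, s in relation.provenance:
        doc = corpus.get(doc_id)
        if doc is None:
            raise ProvenanceError(f"relation {relation.key}: unknown document {doc_id!r}")
        if not 0 <= s < len(doc.sentences):
            raise ProvenanceError(
                f"relation {relation.key}: sentence {s} outside document {doc_id!r}"
            )
        lo = max(0, s - n)
        hi = min(len(doc.sentences) - 1, s + n)
        windows.append(
            ContextWindow(document_id=doc_id, sentence_indices=tuple(range(lo, hi + 1)))
        )
    return windows


def _entity_name_terms(relation: Relation) -> list[str]:
    terms = []
    for entity in (relation.subject, relation.object):
        terms.extend(entity.canonical_name.lower().split())
    return terms


class Vocabulary:
    """Ordered term -> column map, fixed after fitting."""

    def __init__(self, terms) -> None:
        self.terms: tuple[str, ...] = tuple(terms)
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocabulary) and self.terms == other.terms


def fit_vocabulary(
    labeled_chains: list[InferenceChain], corpus: dict[str, Document], n: int
) -> Vocabulary:
    """Sorted union of all token surfaces in training N-CS plus entity names."""
    if not labeled_chains:
        raise ConfigurationError("cannot fit a vocabulary on an empty training set")
    terms: set[str] = set()
    for chain in labeled_chains:
        for step in chain.steps:
            for window in extract_ncs(step.relation, corpus, n):
                doc = corpus[window.document_id]
                for idx in window.sentence_indices:
                    terms.update(t.surface.lower() for t in doc.sentences[idx].tokens)
            terms.update(_entity_name_terms(step.relation))
    return Vocabulary(sorted(terms))


def featurize_chain(
    chain: InferenceChain,
    corpus: dict[str, Document],
    vocab: Vocabulary,
    n: int,
) -> np.ndarray:
    """Feature vector of a chain: per-relation N-CS blocks then entity-name blocks.

    For each relation, term counts are summed over the union of its context
    windows; the per-relation blocks are concatenated in chain order, then
    one entity-name term-count block per relation is appended in the same
    order.  Dimensionality: 2 * len(chain.steps) * len(vocab).  Unseen terms
    are ignored.  Pure function of (chain, corpus, vocab, n).
    """
    v = len(vocab)
    k = len(chain.steps)
    x = np.zeros(2 * k * v, dtype=np.int64)
    for i, step in enumerate(chain.steps):
        windows = extract_ncs(step.relation, corpus, n)
        seen: set[tuple[str, int]] = set()
        for window in windows:
            for idx in window.sentence_indices:
                seen.add((window.document_id, idx))
        block = x[i * v : (i + 1) * v]
        for doc_id, idx in seen:
            for tok in corpus[doc_id].sentences[idx].tokens:
                col = vocab.index.get(tok.surface.lower())
                if col is not None:
                    block[col] += 1
        name_block = x[(k + i) * v : (k + i + 1) * v]
        for term in _entity_name_terms(step.relation):
            col = vocab.index.get(term)
            if col is not None:
                name_block[col] += 1
    return x


def featurize_chains(
    chains: list[InferenceChain],
    corpus: dict[str, Document],
    vocab: Vocabulary,
    n: int,
) -> np.ndarray:
    if not chains:
        return np.zeros((0, 0), dtype=np.int64)
    return np.vstack([featurize_chain(c, corpus, vocab, n) for c in chains])


def _labels(chains: list[InferenceChain]) -> np.ndarray:
    for chain in chains:
        if chain.label not in (MEANINGFUL, MEANINGLESS):
            raise TrainingError(
                f"chain {chain.entity_ids} is unlabeled; training requires labeled chains"
            )
    return np.array([1 if c.label == MEANINGFUL else 0 for c in chains])


class ChainPruner:
    """A fitted chain classifier carrying its vocabulary and configuration."""

    def __init__(self, config: PruningConfig | None = None) -> None:
        self.config = config or PruningConfig()
        self.vocabulary_: Vocabulary | None = None
        self.classifier_ = None
        self.n_steps_: int | None = None

    # -- fitting ----------------------------------------------------------
    def fit(self, labeled_chains: list[InferenceChain], corpus: dict[str, Document]) -> "ChainPruner":
        y = _labels(labeled_chains)
        if len(set(y)) < 2:
            raise TrainingError("training data must contain both chain labels")
        lengths = {len(c.steps) for c in labeled_chains}
        if len(lengths) != 1:
            raise TrainingError(f"training chains must share one length, got {sorted(lengths)}")
        self.n_steps_ = lengths.pop()
        self.vocabulary_ = fit_vocabulary(labeled_chains, corpus, self.config.context_range_n)
        x = featurize_chains(labeled_chains, corpus, self.vocabulary_, self.config.context_range_n)
        self.classifier_ = build_classifier(self.config.classifier, self.config.random_seed)
        self.classifier_.fit(x, y)
        return self

    def _check_fitted(self, chains: list[InferenceChain]) -> None:
        if self.vocabulary_ is None or self.classifier_ is None:
            raise ModelCompatibilityError("pruner is not fitted")
        bad = [c for c in chains if len(c.steps) != self.n_steps_]
        if bad:
            raise ModelCompatibilityError(
                f"pruner was fitted on {self.n_steps_}-relation chains; "
                f"got a {len(bad[0].steps)}-relation chain"
            )

    def predict(self, chains: list[InferenceChain], corpus: dict[str, Document]) -> list[str]:
        self._check_fitted(chains)
        if not chains:
            return []
        x = featurize_chains(chains, corpus, self.vocabulary_, self.config.context_range_n)
        y = self.classifier_.predict(x)
        return [MEANINGFUL if v == 1 else MEANINGLESS for v in y]

    def prune(
        self, chains: list[InferenceChain], corpus: dict[str, Document]
    ) -> tuple[list[InferenceChain], list[InferenceChain]]:
        """Partition chains into (retained, discarded) by predicted label."""
        labels = self.predict(chains, corpus)
        retained = [c for c, lab in zip(chains, labels) if lab == MEANINGFUL]
        discarded = [c for c, lab in zip(chains, labels) if lab == MEANINGLESS]
        return retained, discarded


def train(
    labeled_chains: list[InferenceChain],
    corpus: dict[str, Document],
    config: PruningConfig | None = None,
) -> ChainPruner:
    """Fit a ChainPruner on labeled chains (positive class = meaningful)."""
    return ChainPruner(config).fit(labeled_chains, corpus)


def prune(
    chains: list[InferenceChain],
    model: ChainPruner,
    corpus: dict[str, Document],
) -> tuple[list[InferenceChain], list[InferenceChain]]:
    return model.prune(chains, corpus)


@dataclass
class EvaluationReport:
    """Cross-validated evaluation of the pruning classifier."""

    classifier: str
    precision: float
    recall: float
    folds: list[dict] = field(default_factory=list)
    baseline_precision: float = float("nan")
    n_chains: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "classifier": self.classifier,
                    "precision": self.precision,
                    "recall": self.recall,
                    "baseline_precision": self.baseline_precision,
                    "n_chains": self.n_chains,
                    "folds": self.folds,
                },
                indent=1,
                sort_keys=True,
            ),
            encoding="utf-8",
        )


def evaluate(
    labeled_chains: list[InferenceChain],
    corpus: dict[str, Document],
    config: PruningConfig | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of chain pruning.

    Vocabulary and classifier are refitted on each training fold; the report
    pools the per-fold confusion matrices and gives precision/recall of the
    meaningful class, plus the no-pruning baseline (accept everything),
    whose precision is the positive prevalence and whose recall is 1 by
    construction.
    """
    config = config or PruningConfig()
    # canonical order: fold assignment must not depend on presentation order
    chains = sorted(labeled_chains, key=lambda c: (c.entity_ids, c.label))
    y = _labels(chains)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if min(n_pos, n_neg) < config.cv_folds:
        raise ConfigurationError(
            f"need at least {config.cv_folds} chains per class, got {n_pos}/{n_neg}"
        )
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.random_seed
    )
    folds = []
    tp = fp = tn = fn = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        fold_train = [chains[i] for i in train_idx]
        fold_test = [chains[i] for i in test_idx]
        model = ChainPruner(config).fit(fold_train, corpus)
        pred = np.array(
            [1 if lab == MEANINGFUL else 0 for lab in model.predict(fold_test, corpus)]
        )
        truth = y[test_idx]
        f_tp = int(((pred == 1) & (truth == 1)).sum())
        f_fp = int(((pred == 1) & (truth == 0)).sum())
        f_tn = int(((pred == 0) & (truth == 0)).sum())
        f_fn = int(((pred == 0) & (truth == 1)).sum())
        folds.append({"tp": f_tp, "fp": f_fp, "tn": f_tn, "fn": f_fn})
        tp, fp, tn, fn = tp + f_tp, fp + f_fp, tn + f_tn, fn + f_fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvaluationReport(
        classifier=config.classifier,
        precision=precision,
        recall=recall,
        folds=folds,
        baseline_precision=n_pos / len(y),
        n_chains=len(y),
    )
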