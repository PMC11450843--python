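"""Random Forest recognition of atropopeptide-modifying P450s.

The model is organised statsmodels-style: :class:`P450ClassifierModel`
is built from labeled training sequences (segmented, reduced, and
vectorized against a positive-defined k-mer feature space) and its
``fit`` method returns a :class:`ClassifierResults` object carrying the
trained forest, the held-out evaluation report and a ``summary`` table.

Classes are balanced by random oversampling of the minority class, the
balanced set is split 60:40 (stratified) into training and internal
validation, and the forest scores a query as the fraction of trees
voting positive. A query is called positive when its score exceeds
0.15 strictly — a deliberately permissive threshold that favours recall
at the enzyme-classification stage, because the downstream precursor
search discards false positives cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from atropomine.features import (
    FeatureVector,
    KmerFeatureSpace,
    build_feature_space,
    reduce_segments,
    vectorize,
)
from atropomine.seqprep import (
    DEFAULT_ALPHABET,
    DereplicationParams,
    ProteinSeq,
    ReducedAlphabet,
    ReferenceScheme,
    dereplicate,
    segment_by_reference,
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Random Forest and evaluation settings.

    ``max_depth`` defaults to 10 for the initial training round; the
    refinement round on an expanded positive set uses depth 14.
    ``score_threshold`` applies strictly (score must exceed it).
    """

    n_trees: int = 100
    max_depth: int = 10
    min_samples_leaf: int = 1
    split_fraction: float = 0.6
    score_threshold: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must be in (0, 1)")
        if not 0 < self.score_threshold < 1:
            raise ValueError("score threshold must be in (0, 1)")
        if self.max_depth < 1:
            raise ValueError("max depth must be >= 1")


ROUND2_CONFIG_CHANGES = {"max_depth": 14}


@dataclass(frozen=True)
class EvalReport:
    """Held-out validation metrics; balanced accuracy is
    (recall + specificity) / 2."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f1_positive(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def balanced_accuracy(self) -> float:
        return (self.recall + self.specificity) / 2

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "EvalReport":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "recall": self.recall,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1_positive": self.f1_positive,
            "balanced_accuracy": self.balanced_accuracy,
        }


def oversample_balance(
    vectors: np.ndarray, labels: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random oversampling: duplicate minority items until classes match.

    Every original item is kept; the minority class is topped up by
    sampling with replacement (seeded) from its own members, so the set
    of distinct samples is preserved and class counts end equal.
    """
    vectors = np.asarray(vectors)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("oversampling requires both classes present")
    rng = np.random.default_rng(seed)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == n_neg:
        return vectors, labels
    minority = labels if n_pos < n_neg else ~labels
    deficit = abs(n_neg - n_pos)
    idx = np.flatnonzero(minority)
    extra = rng.choice(idx, size=deficit, replace=True)
    out_v = np.concatenate([vectors, vectors[extra]])
    out_y = np.concatenate([labels, labels[extra]])
    return out_v, out_y


def _vote_fraction(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Score = fraction of trees whose leaf majority votes positive."""
    votes = np.stack([tree.predict(X) for tree in forest.estimators_])
    return votes.mean(axis=0)


class P450ClassifierModel:
    """Feature-space construction plus Random Forest training data.

    Built either from raw labeled sequences (``from_sequences``, which
    segments each P450 against the reference scheme, recodes it into the
    reduced alphabet, derives the positive-defined k-mer feature space
    and vectorizes everything) or directly from a prepared design matrix.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        feature_space: KmerFeatureSpace,
        ids: Sequence[str] | None = None,
    ):
        X = np.asarray(X)
        y = np.asarray(y, dtype=bool)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if X.shape[1] != feature_space.n_features:
            raise ValueError(
                f"X has {X.shape[1]} columns but the feature space defines "
                f"{feature_space.n_features} features"
            )
        self.X = X
        self.y = y
        self.feature_space = feature_space
        self.ids = list(ids) if ids is not None else [""] * X.shape[0]
        # kept so refinement rounds can rebuild the space from the union
        self._positive_seqs: list[ProteinSeq] | None = None
        self._negative_seqs: list[ProteinSeq] | None = None
        self._scheme: ReferenceScheme | None = None
        self._alphabet: ReducedAlphabet = DEFAULT_ALPHABET

    @classmethod
    def from_sequences(
        cls,
        positives: Sequence[ProteinSeq],
        negatives: Sequence[ProteinSeq],
        scheme: ReferenceScheme,
        alphabet: ReducedAlphabet = DEFAULT_ALPHABET,
        k: int = 4,
        min_positive_fraction: float = 0.5,
    ) -> "P450ClassifierModel":
        pos_segs = [
            reduce_segments(segment_by_reference(p, scheme), alphabet)
            for p in positives
        ]
        neg_segs = [
            reduce_segments(segment_by_reference(n, scheme), alphabet)
            for n in negatives
        ]
        space = build_feature_space(pos_segs, k, min_positive_fraction)
        vectors = [
            vectorize(s, space, p.id)
            for s, p in zip(pos_segs + neg_segs, [*positives, *negatives])
        ]
        X = np.stack([v.values for v in vectors])
        y = np.array([True] * len(positives) + [False] * len(negatives))
        model = cls(X, y, space, ids=[v.source_id for v in vectors])
        model._positive_seqs = list(positives)
        model._negative_seqs = list(negatives)
        model._scheme = scheme
        model._alphabet = alphabet
        return model

    def fit(self, config: ClassifierConfig = ClassifierConfig()) -> "ClassifierResults":
        """Balance, split 60:40 stratified, train, evaluate held-out."""
        Xb, yb = oversample_balance(self.X, self.y, config.seed)
        X_tr, X_va, y_tr, y_va = train_test_split(
            Xb,
            yb,
            train_size=config.split_fraction,
            stratify=yb,
            random_state=config.seed,
        )
        if y_tr.all() or (~y_tr).all() or y_va.all() or (~y_va).all():
            raise ValueError("degenerate split: a partition lost a class")
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=config.seed,
        )
        forest.fit(X_tr, y_tr)
        scores = _vote_fraction(forest, X_va)
        report = EvalReport.from_predictions(
            y_va, scores > config.score_threshold
        )
        return ClassifierResults(self, forest, config, report)

    def refine(
        self,
        new_positives: Sequence[ProteinSeq],
        config: ClassifierConfig | None = None,
        derep_params: DereplicationParams = DereplicationParams(),
    ) -> "P450ClassifierModel":
        """Second-round iteration: fold newly mined positives back in.

        New positives are dereplicated together with the existing
        positive set, the feature space is rebuilt from the union, and
        the returned model is ready to fit with the round-2 depth.
        """
        if self._positive_seqs is None or self._scheme is None:
            raise ValueError(
                "refine requires a model built via from_sequences"
            )
        union = dereplicate(
            [*self._positive_seqs, *new_positives], derep_params
        )
        return P450ClassifierModel.from_sequences(
            union,
            self._negative_seqs or [],
            self._scheme,
            self._alphabet,
            k=self.feature_space.k,
            min_positive_fraction=self.feature_space.min_positive_fraction,
        )


@dataclass
class ClassifierResults:
    """A fitted forest plus its held-out evaluation."""

    model: P450ClassifierModel
    forest: RandomForestClassifier
    config: ClassifierConfig
    report: EvalReport

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X))
        return _vote_fraction(self.forest, X)

    def classify(
        self, X: np.ndarray, threshold: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Scores and positive calls; positive iff score > threshold."""
        if threshold is None:
            threshold = self.config.score_threshold
        scores = self.score(X)
        return scores > threshold, scores

    def classify_proteins(
        self,
        proteins: Sequence[ProteinSeq],
        scheme: ReferenceScheme,
        alphabet: ReducedAlphabet = DEFAULT_ALPHABET,
        threshold: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Segment, reduce, vectorize and classify raw P450 sequences."""
        vectors = [
            vectorize(
                reduce_segments(segment_by_reference(p, scheme), alphabet),
                self.model.feature_space,
                p.id,
            )
            for p in proteins
        ]
        X = np.stack([v.values for v in vectors])
        return self.classify(X, threshold)

    def summary(self) -> str:
        r = self.report
        space = self.model.feature_space
        lines = [
            "Atropopeptide P450 classifier — held-out validation",
            "=" * 53,
            f"trees: {self.config.n_trees}   max depth: "
            f"{self.config.max_depth}   min samples/leaf: "
            f"{self.config.min_samples_leaf}",
            f"features: {space.n_features} reduced-alphabet "
            f"{space.k}-mers over 5 functional regions "
            f"(from {space.n_positives} positives)",
            f"score threshold: > {self.config.score_threshold}",
            "-" * 53,
            f"TP {r.tp:5d}   FP {r.fp:5d}   TN {r.tn:5d}   FN {r.fn:5d}",
            f"recall            {r.recall:8.4f}",
            f"specificity       {r.specificity:8.4f}",
            f"precision         {r.precision:8.4f}",
            f"f1 (positive)     {r.f1_positive:8.4f}",
            f"balanced accuracy {r.balanced_accuracy:8.4f}",
        ]
        return "\n".join(lines)


def round2_config(config: ClassifierConfig) -> ClassifierConfig:
    """The refinement-round configuration (deeper trees)."""
    return replace(config, **ROUND2_CONFIG_CHANGES)
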