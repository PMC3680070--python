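"""Information-gain feature ranking, difficulty prediction, baseline learners.

Information gain is the reduction in Shannon entropy of the class label
achieved by conditioning on a (possibly discretized) feature.  Continuous
features are discretized by a supervised binary split maximizing IG,
recursing once on each side (at most four bins) — a deterministic,
C4.5-flavored rule.  Each ranked feature carries the sign of its
point-biserial correlation with the binary class indicator.

Difficulty prediction trains a CART-style decision tree on the surface
feature space to predict D/N/E; interaction baselines train simple
non-kernel learners on the same features under strict document-level
cross-validation (any document shared between train and test folds is a
hard error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .evaluation import (
    ConfusionCounts,
    MulticlassReport,
    multiclass_report_from_matrix,
    prf,
)
from .model import FoldAssignment, ValidationError

__all__ = [
    "entropy_of_labels",
    "discretize_feature",
    "information_gain",
    "InfoGainEntry",
    "rank_features",
    "EvalProtocol",
    "DifficultyModel",
    "train_difficulty_model",
    "evaluate_difficulty_model",
    "BaselineSpec",
    "train_interaction_baselines",
    "majority_baseline",
]


def entropy_of_labels(labels: Sequence) -> float:
    """Shannon entropy (bits) of the empirical label distribution."""
    arr = pd.Series(list(labels))
    if arr.empty:
        raise ValidationError("empty label sequence")
    counts = arr.value_counts().to_numpy()
    return float(stats.entropy(counts, base=2))


def _split_ig(values: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    left = labels[values <= threshold]
    right = labels[values > threshold]
    if len(left) == 0 or len(right) == 0:
        return -1.0
    h = entropy_of_labels(labels)
    n = len(labels)
    return h - (
        len(left) / n * entropy_of_labels(left)
        + len(right) / n * entropy_of_labels(right)
    )


def _best_threshold(values: np.ndarray, labels: np.ndarray) -> float | None:
    uniq = np.unique(values)
    if len(uniq) < 2:
        return None
    if len(uniq) > 64:  # cap candidate thresholds on dense features
        uniq = np.unique(np.quantile(values, np.linspace(0, 1, 65)))
    mids = (uniq[:-1] + uniq[1:]) / 2
    gains = [_split_ig(values, labels, t) for t in mids]
    best = int(np.argmax(gains))
    if gains[best] < 0:
        return None
    return float(mids[best])


def discretize_feature(
    values: np.ndarray, labels: np.ndarray, max_depth: int = 2
) -> np.ndarray:
    """Supervised discretization: IG-maximizing binary split, recursing once
    (``max_depth=2`` gives at most four bins).  Returns integer bin codes."""
    codes = np.zeros(len(values), dtype=int)

    def recurse(mask: np.ndarray, depth: int, base: int) -> int:
        t = _best_threshold(values[mask], labels[mask])
        if t is None or depth == 0:
            codes[mask] = base
            return base + 1
        left = mask & (values <= t)
        right = mask & (values > t)
        nxt = recurse(left, depth - 1, base)
        return recurse(right, depth - 1, nxt)

    recurse(np.ones(len(values), dtype=bool), max_depth, 0)
    return codes


@dataclass
class InfoGainEntry:
    feature: str
    ig: float
    sign: str  # "+" or "-"
    rank: int = 0
    n_used: int = 0


_MAX_CATEGORICAL = 12


def information_gain(
    feature_column: Sequence,
    labels: Sequence[bool],
    discretize: bool | None = None,
    name: str = "",
) -> InfoGainEntry:
    """IG (bits) of one feature for a binary class indicator, with the sign
    of the feature/indicator correlation.

    Rows with a missing feature value are excluded.  Features with more
    distinct values than a small cap are discretized by the supervised
    split rule unless ``discretize`` overrides the heuristic.  A constant
    label column yields IG = 0 by convention.
    """
    values = pd.Series(list(feature_column), dtype=float)
    y = np.asarray(list(labels), dtype=bool)
    if len(values) != len(y):
        raise ValidationError("feature/label length mismatch")
    keep = values.notna().to_numpy()
    values = values[keep].to_numpy(dtype=float)
    y = y[keep]
    if len(y) == 0 or len(np.unique(y)) < 2:
        return InfoGainEntry(feature=name, ig=0.0, sign="+", n_used=len(y))
    if discretize is None:
        discretize = len(np.unique(values)) > _MAX_CATEGORICAL
    codes = discretize_feature(values, y) if discretize else values
    h = entropy_of_labels(y)
    cond = 0.0
    for v in np.unique(codes):
        mask = codes == v
        cond += mask.mean() * entropy_of_labels(y[mask])
    ig = max(0.0, h - cond)
    if np.std(values) == 0:
        sign = "+"
    else:
        corr = np.corrcoef(values, y.astype(float))[0, 1]
        sign = "-" if corr < 0 else "+"
    return InfoGainEntry(feature=name, ig=float(ig), sign=sign, n_used=len(y))


def rank_features(
    feature_table: pd.DataFrame,
    class_labels: Mapping[str, bool] | Sequence[bool],
    k: int = 10,
) -> list[InfoGainEntry]:
    """Top-k features by information gain against a binary class indicator,
    descending IG with deterministic name tie-break."""
    if isinstance(class_labels, Mapping):
        y = [bool(class_labels[pid]) for pid in feature_table.index]
    else:
        y = [bool(v) for v in class_labels]
    entries = []
    for col in feature_table.columns:
        if col.startswith("has_"):
            continue  # layer-presence flags are bookkeeping, not features
        entries.append(
            information_gain(feature_table[col], y, name=col)
        )
    entries.sort(key=lambda e: (-e.ig, e.feature))
    for i, e in enumerate(entries, start=1):
        e.rank = i
    return entries[: max(0, k)]


# ---------------------------------------------------------------------------
# difficulty-class prediction and interaction baselines


def _doc_of(pair_id: str) -> str:
    head, _, _ = pair_id.rpartition(".p")
    doc, _, _ = head.rpartition(".s")
    return doc


def _corpus_of(pair_id: str) -> str:
    return pair_id.split(".", 1)[0]


@dataclass
class EvalProtocol:
    """Evaluation protocol for feature-based classifiers."""

    mode: str = "cv"  # "cv" (document-level k-fold) or "resubstitution"
    folds: FoldAssignment | None = None
    n_folds: int = 10
    seed: int = 0

    def resolve_folds(self, doc_ids: Sequence[str]) -> FoldAssignment:
        if self.folds is not None:
            return self.folds
        docs = sorted(set(doc_ids))
        order = np.random.default_rng(self.seed).permutation(len(docs))
        return FoldAssignment(
            mapping={docs[j]: int(i % self.n_folds) for i, j in enumerate(order)},
            n_folds=self.n_folds,
        )


@dataclass
class DifficultyModel:
    estimator: DecisionTreeClassifier
    feature_names: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, feature_table: pd.DataFrame) -> dict[str, str]:
        X = feature_table[self.feature_names].fillna(-1.0).to_numpy(float)
        return dict(zip(feature_table.index, self.estimator.predict(X)))


def _design(feature_table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in feature_table.columns if not c.startswith("has_")]
    return feature_table[cols].fillna(-1.0).to_numpy(float), cols


def _make_tree(seed: int) -> DecisionTreeClassifier:
    # stability-oriented defaults: IG splitting, shallow-ish, sizable leaves
    return DecisionTreeClassifier(
        criterion="entropy",
        min_samples_leaf=25,
        max_depth=12,
        random_state=seed,
    )


def train_difficulty_model(
    feature_table: pd.DataFrame,
    classes: Mapping[str, str],
    protocol: EvalProtocol | None = None,
) -> DifficultyModel:
    """Fit the D/N/E decision tree on the full feature table."""
    protocol = protocol or EvalProtocol()
    X, cols = _design(feature_table)
    y = np.array([classes[pid] for pid in feature_table.index])
    if len(np.unique(y)) < 2:
        raise ValidationError("single-class training set")
    est = _make_tree(protocol.seed).fit(X, y)
    return DifficultyModel(
        estimator=est,
        feature_names=cols,
        metadata={
            "protocol": protocol.mode,
            "n_folds": protocol.n_folds,
            "seed": protocol.seed,
            "n_pairs": len(y),
        },
    )


def _check_leakage(train_docs: set[str], test_docs: set[str]) -> None:
    shared = train_docs & test_docs
    if shared:
        raise ValidationError(
            f"document-level fold leakage: {sorted(shared)[:3]} in both "
            "train and test"
        )


def evaluate_difficulty_model(
    feature_table: pd.DataFrame,
    classes: Mapping[str, str],
    protocol: EvalProtocol | None = None,
    labels: Sequence[str] = ("D", "N", "E"),
) -> MulticlassReport:
    """D/N/E prediction report (pooled confusion over document-level CV
    folds by default; ``mode="resubstitution"`` trains and scores on all)."""
    protocol = protocol or EvalProtocol()
    X, _ = _design(feature_table)
    pair_ids = list(feature_table.index)
    y = np.array([classes[pid] for pid in pair_ids])
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)

    if protocol.mode == "resubstitution":
        est = _make_tree(protocol.seed).fit(X, y)
        pred = est.predict(X)
        for a, p in zip(y, pred):
            mat[idx[a], idx[p]] += 1
        return multiclass_report_from_matrix(mat, labels)

    docs = np.array([_doc_of(pid) for pid in pair_ids])
    folds = protocol.resolve_folds(docs)
    fold_of = np.array([folds.mapping[d] for d in docs])
    for f in range(folds.n_folds):
        test = fold_of == f
        if not test.any():
            continue
        train = ~test
        _check_leakage(set(docs[train]), set(docs[test]))
        if len(np.unique(y[train])) < 2:
            raise ValidationError(f"single-class training set in fold {f}")
        est = _make_tree(protocol.seed).fit(X[train], y[train])
        pred = est.predict(X[test])
        for a, p in zip(y[test], pred):
            mat[idx[a], idx[p]] += 1
    return multiclass_report_from_matrix(mat, labels)


@dataclass
class BaselineSpec:
    """A non-kernel baseline learner over the surface feature space."""

    kind: str  # decision-tree | naive-bayes | logistic | rule | nearest-neighbor
    seed: int = 0

    def build(self):
        if self.kind == "decision-tree":
            return DecisionTreeClassifier(
                criterion="entropy", min_samples_leaf=5, random_state=self.seed
            )
        if self.kind == "naive-bayes":
            return GaussianNB()
        if self.kind == "logistic":
            from sklearn.pipeline import make_pipeline
            from sklearn.preprocessing import StandardScaler

            return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
        if self.kind == "rule":
            # one-rule-flavored: a depth-capped tree acts as a small rule list
            return DecisionTreeClassifier(
                criterion="entropy", max_depth=3, random_state=self.seed
            )
        if self.kind == "nearest-neighbor":
            return KNeighborsClassifier(n_neighbors=5)
        raise ValidationError(f"unknown baseline kind {self.kind!r}")


def majority_baseline(gold_train: np.ndarray) -> bool:
    """Label predicted by the majority-class baseline."""
    return bool(gold_train.mean() > 0.5)


def train_interaction_baselines(
    feature_table: pd.DataFrame,
    gold: Mapping[str, bool],
    specs: Sequence[BaselineSpec],
    folds: FoldAssignment,
    include_majority: bool = True,
) -> pd.DataFrame:
    """Per-learner per-corpus P/R/F for gold interaction prediction under
    document-level cross-validation (train/test always split by document)."""
    pair_ids = [pid for pid in feature_table.index if pid in gold]
    X_all, _ = _design(feature_table.loc[pair_ids])
    y_all = np.array([gold[pid] for pid in pair_ids])
    docs = np.array([_doc_of(pid) for pid in pair_ids])
    corpora = np.array([_corpus_of(pid) for pid in pair_ids])
    missing = sorted(set(docs) - set(folds.mapping))
    if missing:
        raise ValidationError(f"documents without fold assignment: {missing[:3]}")
    fold_of = np.array([folds.mapping[d] for d in docs])

    learners: list[tuple[str, BaselineSpec | None]] = [
        (s.kind, s) for s in specs
    ]
    if include_majority:
        learners.append(("majority", None))

    rows = []
    for corpus_name in sorted(set(corpora)):
        in_corpus = corpora == corpus_name
        for learner_name, spec in learners:
            counts = ConfusionCounts()
            for f in range(folds.n_folds):
                test = in_corpus & (fold_of == f)
                train = in_corpus & (fold_of != f)
                if not test.any() or not train.any():
                    continue
                _check_leakage(set(docs[train]), set(docs[test]))
                if spec is None:
                    pred = np.full(
                        int(test.sum()), majority_baseline(y_all[train])
                    )
                elif len(np.unique(y_all[train])) < 2:
                    pred = np.full(int(test.sum()), bool(y_all[train][0]))
                else:
                    est = spec.build().fit(X_all[train], y_all[train])
                    pred = est.predict(X_all[test]).astype(bool)
                for p, g in zip(pred, y_all[test]):
                    if g and p:
                        counts.TP += 1
                    elif g:
                        counts.FN += 1
                    elif p:
                        counts.FP += 1
                    else:
                        counts.TN += 1
            metrics = prf(counts)
            rows.append(
                [learner_name, corpus_name, *metrics.rounded()]
            )
    return pd.DataFrame(rows, columns=["learner", "corpus", "P", "R", "F"])
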