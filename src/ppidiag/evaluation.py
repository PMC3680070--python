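"""Confusion counts, P/R/F, stratum bookkeeping, rescoring and vote ensembles.

Conventions: metrics are percentages (one-decimal presentation); a metric
with zero denominator is defined as 0; the expected-correct count ``e`` on a
stratum rounds half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Corpus, PredictionSet, ValidationError

__all__ = [
    "ConfusionCounts",
    "PRF",
    "ClassifierProfile",
    "StratumReport",
    "MulticlassReport",
    "confusion",
    "prf",
    "positive_rate",
    "expected_correct",
    "stratum_report",
    "multiclass_eval",
    "relabel_and_rescore",
    "majority_vote",
    "ensemble_eval",
]


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class PRF:
    """Precision / recall / F1 as percentages in [0, 100]."""

    P: float
    R: float
    F: float

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round(self.P, ndigits),
            round(self.R, ndigits),
            round(self.F, ndigits),
        )


def confusion(
    predictions: Mapping[str, bool],
    gold: Mapping[str, bool],
    subset: Iterable[str] | None = None,
) -> ConfusionCounts:
    """Exact confusion counts of one predicted-label column over a pair subset."""
    ids = list(gold) if subset is None else list(subset)
    counts = ConfusionCounts()
    for pid in ids:
        if pid not in predictions:
            raise ValidationError(f"pair {pid} outside prediction coverage")
        pred, g = predictions[pid], gold[pid]
        if g:
            if pred:
                counts.TP += 1
            else:
                counts.FN += 1
        else:
            if pred:
                counts.FP += 1
            else:
                counts.TN += 1
    return counts


def prf(counts: ConfusionCounts) -> PRF:
    """P = 100 TP/(TP+FP), R = 100 TP/(TP+FN), F = harmonic mean; 0 on empty."""
    p = 100 * counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = 100 * counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return PRF(P=p, R=r, F=f)


@dataclass
class ClassifierProfile:
    """A classifier's positive-prediction rate r (%) over a pair population."""

    classifier_id: str
    r: float
    population_size: int
    population: str = "pooled"


def positive_rate(
    classifier_id: str,
    predictions: PredictionSet,
    population: Sequence[str] | None = None,
) -> ClassifierProfile:
    """r = 100 * (positive predictions) / |population|.

    Default population: all pairs the prediction set covers (pooled over
    corpora within the setting).
    """
    column = predictions.column(classifier_id)
    ids = list(column) if population is None else list(population)
    if not ids:
        raise ValidationError("empty population")
    pos = sum(column[pid] for pid in ids)
    return ClassifierProfile(
        classifier_id=classifier_id,
        r=100 * pos / len(ids),
        population_size=len(ids),
        population="pooled" if population is None else "custom",
    )


def expected_correct(stratum_size: int, r: float, polarity: str) -> int:
    """Correct labels expected on a single-gold-class stratum from rate r alone.

    For a negative stratum e = round((1 - r/100) * size); for a positive one
    e = round((r/100) * size); halves round away from zero.
    """
    if not 0 <= r <= 100:
        raise ValidationError(f"rate r={r} outside [0, 100]")
    if stratum_size < 0:
        raise ValidationError("negative stratum size")
    share = r / 100 if polarity == "positive" else 1 - r / 100
    x = share * stratum_size
    return int(math.floor(x + 0.5))  # x >= 0: floor(x+.5) = half away from zero


@dataclass
class StratumReport:
    classifier_id: str
    stratum_name: str
    stratum_size: int
    polarity: str
    r: float
    observed: int
    expected: int
    ratio_observed_expected: float | None
    ratio_observed_size: float

    def rounded(self) -> dict[str, float | None]:
        return {
            "r": round(self.r, 1),
            "observed": self.observed,
            "e": self.expected,
            "obs/e": (
                None
                if self.ratio_observed_expected is None
                else round(self.ratio_observed_expected, 2)
            ),
            "obs/size": round(self.ratio_observed_size, 2),
        }


def stratum_report(
    classifier_id: str,
    predictions: PredictionSet,
    gold: Mapping[str, bool],
    stratum: set[str],
    polarity: str,
    stratum_name: str = "",
    r: float | None = None,
) -> StratumReport:
    """Observed vs expected correct labels of one classifier on one stratum.

    The stratum must be gold-homogeneous and match ``polarity``; observed
    correct labels are TN on a negative stratum, TP on a positive one.  When
    ``r`` is not supplied it is computed over the full covered population.
    """
    if polarity not in ("positive", "negative"):
        raise ValidationError(f"polarity {polarity!r}")
    want = polarity == "positive"
    bad = [pid for pid in stratum if gold[pid] != want]
    if bad:
        raise ValidationError(
            f"stratum not gold-{polarity}: e.g. {sorted(bad)[:3]}"
        )
    if r is None:
        r = positive_rate(classifier_id, predictions).r
    counts = confusion(predictions.column(classifier_id), gold, stratum)
    observed = counts.TP if want else counts.TN
    e = expected_correct(len(stratum), r, polarity)
    return StratumReport(
        classifier_id=classifier_id,
        stratum_name=stratum_name,
        stratum_size=len(stratum),
        polarity=polarity,
        r=r,
        observed=observed,
        expected=e,
        ratio_observed_expected=observed / e if e else None,
        ratio_observed_size=observed / len(stratum) if stratum else 0.0,
    )


@dataclass
class MulticlassReport:
    """3-class report: per-class one-vs-rest PRF plus a support-weighted total."""

    labels: list[str]
    matrix: np.ndarray  # actual rows x predicted columns
    per_class: dict[str, PRF]
    supports: dict[str, int]
    total: PRF

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.labels):
            m = self.per_class[lab]
            rows.append(
                [lab, *m.rounded(), *self.matrix[i].tolist(), self.supports[lab]]
            )
        rows.append(["Total", *self.total.rounded(), None, None, None, None])
        return pd.DataFrame(
            rows, columns=["class", "P", "R", "F", *self.labels, "support"]
        )


def multiclass_eval(
    predicted: Mapping[str, str] | Sequence[str],
    actual: Mapping[str, str] | Sequence[str],
    labels: Sequence[str] = ("D", "N", "E"),
) -> MulticlassReport:
    """Difficulty-class prediction report from parallel label assignments."""
    if isinstance(predicted, Mapping):
        keys = list(actual)
        pred_seq = [predicted[k] for k in keys]
        act_seq = [actual[k] for k in keys]
    else:
        pred_seq, act_seq = list(predicted), list(actual)
        if len(pred_seq) != len(act_seq):
            raise ValidationError("predicted/actual length mismatch")
    bad = (set(pred_seq) | set(act_seq)) - set(labels)
    if bad:
        raise ValidationError(f"labels outside {list(labels)}: {sorted(bad)}")
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for a, p in zip(act_seq, pred_seq):
        mat[idx[a], idx[p]] += 1
    return multiclass_report_from_matrix(mat, labels)


def multiclass_report_from_matrix(
    matrix: np.ndarray, labels: Sequence[str] = ("D", "N", "E")
) -> MulticlassReport:
    """Per-class and support-weighted PRF from an actual-by-predicted matrix.

    The total row is the support-weighted average of the unrounded per-class
    P, R and F (not a micro-average).
    """
    mat = np.asarray(matrix, dtype=int)
    per_class = {}
    supports = {}
    for i, lab in enumerate(labels):
        tp = int(mat[i, i])
        fp = int(mat[:, i].sum() - tp)
        fn = int(mat[i, :].sum() - tp)
        per_class[lab] = prf(ConfusionCounts(TP=tp, FP=fp, FN=fn))
        supports[lab] = int(mat[i, :].sum())
    n = sum(supports.values())
    total = PRF(
        P=sum(per_class[l].P * supports[l] for l in labels) / n,
        R=sum(per_class[l].R * supports[l] for l in labels) / n,
        F=sum(per_class[l].F * supports[l] for l in labels) / n,
    )
    return MulticlassReport(
        labels=list(labels),
        matrix=mat,
        per_class=per_class,
        supports=supports,
        total=total,
    )


def relabel_and_rescore(
    predictions: Mapping[str, bool],
    gold: Mapping[str, bool],
    flip_ids: Iterable[str],
) -> dict:
    """Invert the gold labels of ``flip_ids`` and re-score fixed predictions.

    Models are not retrained; only the ground truth moves.  Returns before/
    after confusion counts and P/R/F plus the fraction of labels changed.
    """
    flips = list(flip_ids)
    unknown = [pid for pid in flips if pid not in gold]
    if unknown:
        raise ValidationError(f"unknown pair id(s) {unknown[:3]}")
    new_gold = dict(gold)
    for pid in flips:
        new_gold[pid] = not new_gold[pid]
    before = confusion(predictions, gold)
    after = confusion(predictions, new_gold)
    return {
        "before": before,
        "after": after,
        "before_prf": prf(before),
        "after_prf": prf(after),
        "n_flipped": len(set(flips)),
        "changed_fraction": len(set(flips)) / len(gold) if gold else 0.0,
    }


def majority_vote(
    predictions: PredictionSet,
    committee: Sequence[str],
    tie_rule: str = "error",
    ensemble_id: str | None = None,
) -> PredictionSet:
    """Label each pair with the strict majority vote of the committee.

    Ties (possible only for even committees) are handled per ``tie_rule``:
    ``error`` raises, ``positive``/``negative`` break toward that label.
    """
    if tie_rule not in ("error", "positive", "negative"):
        raise ValidationError(f"tie_rule {tie_rule!r}")
    missing = [c for c in committee if c not in predictions.roster]
    if missing:
        raise ValidationError(f"committee members outside roster: {missing}")
    if not committee:
        raise ValidationError("empty committee")
    name = ensemble_id or "+".join(committee)
    table = {}
    for pid in predictions.pair_ids():
        votes = sum(predictions.table[(pid, c)] for c in committee)
        against = len(committee) - votes
        if votes > against:
            label = True
        elif votes < against:
            label = False
        elif tie_rule == "error":
            raise ValidationError(f"tied vote on pair {pid}")
        else:
            label = tie_rule == "positive"
        table[(pid, name)] = label
    return PredictionSet(
        setting=predictions.setting, roster=[name], table=table
    )


def ensemble_eval(
    ensemble: PredictionSet,
    corpora: Sequence[Corpus],
) -> pd.DataFrame:
    """Per-corpus P/R/F of an ensemble (or any single-column prediction set)."""
    [name] = ensemble.roster
    column = ensemble.column(name)
    rows = []
    for corpus in corpora:
        gold = corpus.gold()
        metrics = prf(confusion(column, gold))
        rows.append([name, corpus.name, *metrics.rounded()])
    return pd.DataFrame(rows, columns=["combination", "corpus", "P", "R", "F"])
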