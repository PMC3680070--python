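"""Difficulty stratification of candidate pairs from multi-classifier predictions.

The *success level* of a pair is the number of roster classifiers that
predict its gold label correctly.  Per corpus and evaluation setting, the
most difficult ~10% of pairs (a downward-closed success-level prefix) and
the easiest ~10% (an upward-closed suffix) are extracted from the
success-level histogram; intersecting the per-setting extremes across the
CV and CL settings yields the setting-independent classes D (difficult),
E (easy) and N (neutral), which split by gold label into the subclasses
PD/ND/PE/NE.

Two cutoff rules are provided.  ``closest``: the non-empty prefix/suffix
whose size is closest to the target fraction of the corpus (ties toward
the smaller, more stringent set).  ``at_least``: the smallest non-empty
prefix/suffix whose size reaches at least the target fraction.  The default
pairing is asymmetric — ``closest`` on the difficult side, ``at_least`` on
the easy side — which is the pairing that reproduces every published
per-corpus set size; when the two rules disagree the report flags it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import Corpus, PredictionSet, ValidationError

__all__ = [
    "SuccessTable",
    "DifficultySets",
    "CombinedClasses",
    "OverlapTest",
    "compute_success_levels",
    "cut_difficult",
    "cut_easy",
    "extract_difficulty_sets",
    "combine_settings",
    "overlap_chi2",
    "crosstab_cv_cl",
]


@dataclass
class SuccessTable:
    """Per-pair success levels for one corpus under one setting's roster."""

    setting: str
    roster: list[str]
    levels: dict[str, int]
    corpus_name: str = ""

    @property
    def max_level(self) -> int:
        return len(self.roster)

    def histogram(self) -> np.ndarray:
        """Pair counts per success level 0..len(roster)."""
        hist = np.zeros(self.max_level + 1, dtype=int)
        for s in self.levels.values():
            hist[s] += 1
        return hist


def compute_success_levels(
    corpus: Corpus, predictions: PredictionSet
) -> SuccessTable:
    """s(pair) = number of roster classifiers whose prediction equals gold."""
    gold = corpus.gold()
    predictions.validate_against(gold)
    levels = {
        pid: sum(
            predictions.table[(pid, cid)] == g for cid in predictions.roster
        )
        for pid, g in gold.items()
    }
    return SuccessTable(
        setting=predictions.setting,
        roster=list(predictions.roster),
        levels=levels,
        corpus_name=corpus.name,
    )


def _check_histogram(histogram: Sequence[int], corpus_size: int) -> np.ndarray:
    hist = np.asarray(histogram, dtype=int)
    if corpus_size <= 0:
        raise ValidationError("corpus_size must be positive")
    if hist.sum() != corpus_size:
        raise ValidationError(
            f"histogram totals {hist.sum()} != corpus size {corpus_size}"
        )
    return hist


def cut_difficult(
    histogram: Sequence[int],
    corpus_size: int,
    fraction: float = 0.10,
    rule: str = "closest",
) -> tuple[int, int]:
    """Select the difficult-side success-level prefix {s <= t}.

    Returns ``(threshold_level, set_size)``.  Under the default ``closest``
    rule the non-empty prefix closest in size to ``fraction * corpus_size``
    is chosen, ties broken toward the smaller set; under ``at_least`` the
    smallest non-empty prefix reaching the target size.
    """
    hist = _check_histogram(histogram, corpus_size)
    target = fraction * corpus_size
    cum = np.cumsum(hist)
    candidates = [(t, int(c)) for t, c in enumerate(cum) if c > 0]
    if rule == "closest":
        return min(candidates, key=lambda tc: (abs(tc[1] - target), tc[1]))
    if rule == "at_least":
        for t, c in candidates:
            if c >= target:
                return t, c
        return candidates[-1]
    raise ValueError(f"unknown cutoff rule {rule!r}")


def cut_easy(
    histogram: Sequence[int],
    corpus_size: int,
    fraction: float = 0.10,
    rule: str = "at_least",
) -> tuple[int, int]:
    """Select the easy-side success-level suffix {s >= t}.

    Returns ``(threshold_level, set_size)``.  Default rule: the smallest
    non-empty suffix whose size is at least ``fraction * corpus_size``.
    """
    hist = _check_histogram(histogram, corpus_size)
    t_rev, size = cut_difficult(hist[::-1], corpus_size, fraction, rule=rule)
    return len(hist) - 1 - t_rev, size


@dataclass
class DifficultySets:
    """The ~10% difficult and easy pair sets of one corpus in one setting."""

    corpus_name: str
    setting: str
    difficult: set[str]
    difficult_threshold: int
    easy: set[str]
    easy_threshold: int
    fraction: float = 0.10
    #: set when the two candidate cutoff rules select different sets
    rule_disagreement: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.difficult & self.easy:
            raise ValidationError(
                f"{self.corpus_name}/{self.setting}: difficult and easy "
                "sets overlap"
            )


def extract_difficulty_sets(
    table: SuccessTable,
    fraction: float = 0.10,
    difficult_rule: str = "closest",
    easy_rule: str = "at_least",
) -> DifficultySets:
    """Apply both cutoffs to a success table and materialize the pair sets."""
    hist = table.histogram()
    n = int(hist.sum())
    t_d, _ = cut_difficult(hist, n, fraction, rule=difficult_rule)
    t_e, _ = cut_easy(hist, n, fraction, rule=easy_rule)
    if t_e <= t_d:
        raise ValidationError(
            f"{table.corpus_name}/{table.setting}: difficult and easy "
            f"cutoffs overlap (levels <= {t_d} vs >= {t_e})"
        )
    disagreement = {}
    for side, fn, chosen, default_rule in (
        ("difficult", cut_difficult, t_d, difficult_rule),
        ("easy", cut_easy, t_e, easy_rule),
    ):
        alt_rule = "at_least" if default_rule == "closest" else "closest"
        alt_t, _ = fn(hist, n, fraction, rule=alt_rule)
        if alt_t != chosen:
            disagreement[side] = (
                f"{default_rule} -> level {chosen}, {alt_rule} -> level {alt_t}"
            )
    return DifficultySets(
        corpus_name=table.corpus_name,
        setting=table.setting,
        difficult={p for p, s in table.levels.items() if s <= t_d},
        difficult_threshold=t_d,
        easy={p for p, s in table.levels.items() if s >= t_e},
        easy_threshold=t_e,
        fraction=fraction,
        rule_disagreement=disagreement,
    )


@dataclass
class CombinedClasses:
    """Setting-independent difficulty classes D/N/E with gold-signed subclasses."""

    classes: dict[str, str]  # pair id -> D | N | E
    subclasses: dict[str, str]  # pair id -> PD | ND | PE | NE | neutral

    def members(self, label: str) -> set[str]:
        """Pairs in a class (D/N/E) or subclass (PD/ND/PE/NE/neutral)."""
        if label in ("D", "N", "E"):
            return {p for p, c in self.classes.items() if c == label}
        return {p for p, c in self.subclasses.items() if c == label}

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in ("D", "N", "E", "PD", "ND", "PE", "NE")}
        for c in self.classes.values():
            out[c] += 1
        for c in self.subclasses.values():
            if c != "neutral":
                out[c] += 1
        return out


def combine_settings(
    sets_cv: DifficultySets,
    sets_cl: DifficultySets,
    gold: Mapping[str, bool],
) -> CombinedClasses:
    """Intersect per-setting extremes: D = D_CV & D_CL, E = E_CV & E_CL.

    Remaining pairs are neutral (N).  With gold labels, D splits into
    PD (gold positive) and ND, E into PE and NE.
    """
    universe = set(gold)
    for ds in (sets_cv, sets_cl):
        stray = (ds.difficult | ds.easy) - universe
        if stray:
            raise ValidationError(
                f"{ds.corpus_name}/{ds.setting}: pairs outside gold universe, "
                f"e.g. {sorted(stray)[:3]}"
            )
    difficult = sets_cv.difficult & sets_cl.difficult
    easy = sets_cv.easy & sets_cl.easy
    classes = {}
    subclasses = {}
    for pid, g in gold.items():
        if pid in difficult:
            classes[pid] = "D"
            subclasses[pid] = "PD" if g else "ND"
        elif pid in easy:
            classes[pid] = "E"
            subclasses[pid] = "PE" if g else "NE"
        else:
            classes[pid] = "N"
            subclasses[pid] = "neutral"
    return CombinedClasses(classes=classes, subclasses=subclasses)


@dataclass
class OverlapTest:
    """chi-squared enrichment test of the overlap of two sets in a universe."""

    size_a: int
    size_b: int
    overlap: int
    universe: int
    expected: float
    chi2: float
    p_value: float
    significant: bool

    ALPHA = 0.001


def overlap_chi2(
    A: set[str], B: set[str], N: int, correction: bool = False
) -> OverlapTest:
    """Pearson chi-squared test on the 2x2 membership table of A and B.

    ``significant`` means p < 0.001 *and* the observed overlap exceeds the
    expected |A||B|/N (one-sided enrichment).  By default no continuity
    correction is applied; ``correction=True`` switches to the Yates-
    corrected statistic, whose one-sided p closely tracks the exact
    hypergeometric tail in small universes.
    """
    if N <= 0:
        raise ValidationError("empty universe")
    a, b, k = len(A), len(B), len(A & B)
    if a == 0 or b == 0 or a == N or b == N:
        raise ValidationError(
            "degenerate 2x2 table: A and B must be non-empty proper subsets"
        )
    table = np.array([[k, a - k], [b - k, N - a - b + k]])
    if (table < 0).any():
        raise ValidationError("A and B are not subsets of the universe")
    chi2_stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    expected = a * b / N
    return OverlapTest(
        size_a=a,
        size_b=b,
        overlap=k,
        universe=N,
        expected=expected,
        chi2=float(chi2_stat),
        p_value=float(p),
        significant=bool(p < OverlapTest.ALPHA and k > expected),
    )


def crosstab_cv_cl(
    success_cv: SuccessTable, success_cl: SuccessTable
) -> np.ndarray:
    """Joint distribution of CV and CL success levels.

    Cell (i, j) counts pairs with CV level i and CL level j; shape is
    (|roster_CV|+1, |roster_CL|+1), i.e. 14 x 13 for the full rosters.
    """
    if set(success_cv.levels) != set(success_cl.levels):
        raise ValidationError("CV and CL success tables cover different pairs")
    mat = np.zeros((success_cv.max_level + 1, success_cl.max_level + 1), dtype=int)
    for pid, s_cv in success_cv.levels.items():
        mat[s_cv, success_cl.levels[pid]] += 1
    return mat
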