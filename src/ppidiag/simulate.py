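"""Synthetic PPI corpora and prediction matrices with realistic structure.

The generator emulates the statistical couplings that drive the downstream
analyses rather than fluent English.  Its model:

* Each sentence draws a protein count k and a latent *sentence type*
  (positive-bearing vs negative-only).  Type odds decay with k; the
  per-stratum number of positive-type sentences is assigned by quota, so
  realized corpus positive ratios concentrate tightly around the target.
* Sentence length in words is class-conditioned: positive-type sentences
  draw from N(27.6, sd), negative-type from N(37.2, sd) — the published
  per-class averages of the benchmark corpora.
* All C(k,2) entity pairs are enumerated; within a positive-type sentence
  each pair is positive with high probability (0.95 by default), within a
  negative-type sentence with a small floor (0.02).
* Entities are placed with class-conditioned spacing so the mean token
  distance between pair entities recovers the published per-class values
  (7.15 positive / 9.67 negative); interaction, negation and hedge clue
  words are inserted with class-conditioned rates.
* Every sentence carries a token layer, a chain dependency graph whose
  edge labels are drawn from the standard Stanford-style alphabet, and a
  shallow constituency tree.  A per-sentence *clarity* variable controls
  how often the fallback labels (``dep`` / ``X``) replace specific ones,
  giving each sentence a recoverable label-entropy signal.

Predictions are generated from per-pair latent difficulty δ blended from
Beta noise and the sentence's realized parse clarity, per-family random
effects that induce representation-level error correlation, and a fixed
correctness penalty for the cross-learning setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .features import Lexicons
from .model import (
    CandidatePair,
    Corpus,
    Document,
    Entity,
    FoldAssignment,
    PredictionSet,
    SentenceRecord,
    Token,
    TreeNode,
    ValidationError,
)
from .refdata import BENCHMARK_SIZES

__all__ = [
    "SimCorpusConfig",
    "SimClassifierProfile",
    "SimPredictionConfig",
    "generate_corpus",
    "generate_predictions",
    "generate_benchmark_suite",
    "default_roster",
    "random_folds",
    "positive_bias_for_rate",
    "BenchmarkSuite",
]

_DEP_LABELS = [
    "nsubj", "dobj", "nn", "appos", "conj_and",
    "det", "amod", "prep_with", "prep_in", "nsubjpass",
]
_DEP_WEIGHTS = [0.16, 0.14, 0.12, 0.06, 0.10, 0.14, 0.10, 0.06, 0.08, 0.04]
_CONST_LABELS = ["NP", "VP", "PP", "ADJP", "ADVP", "SBAR"]
_CONST_WEIGHTS = [0.34, 0.22, 0.18, 0.08, 0.08, 0.10]
_FILLERS = [
    "the", "a", "of", "in", "by", "with", "cells", "protein", "expression",
    "analysis", "results", "levels", "human", "gene", "kinase", "domain",
    "signal", "pathway", "membrane", "two", "specific", "assay", "role",
    "function", "observed", "using", "between", "and", "or", "also",
]


@dataclass
class SimCorpusConfig:
    """Study conditions for one synthetic corpus."""

    name: str = "synthetic"
    n_documents: int = 100
    sentences_per_document: tuple[int, int] = (1, 3)
    protein_count_weights: dict[int, float] = field(
        default_factory=lambda: {2: 0.55, 3: 0.25, 4: 0.12, 5: 0.08}
    )
    pos_length_mean: float = 27.6
    pos_length_sd: float = 6.0
    neg_length_mean: float = 37.2
    neg_length_sd: float = 8.0
    pos_entity_distance: float = 7.15
    neg_entity_distance: float = 9.67
    #: per-pair positive probability inside positive-/negative-type sentences
    pos_within: float = 0.95
    neg_within: float = 0.02
    #: per-extra-protein decay of positive-type sentence odds
    count_decay: float = 0.35
    target_positive_ratio: float = 0.25
    lexicons: Lexicons = field(default_factory=Lexicons)
    seed: int = 0

    def validate(self) -> None:
        if self.pos_length_mean <= 0 or self.neg_length_mean <= 0:
            raise ValidationError("length means must be positive")
        if not 0 < self.target_positive_ratio <= 1:
            raise ValidationError("target ratio must be in (0, 1]")
        weights = self.protein_count_weights
        if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValidationError("protein count distribution must be proper")
        if any(k < 2 for k in weights):
            raise ValidationError("sentences need at least two proteins")


@dataclass
class SimClassifierProfile:
    """Behavioral profile of one simulated classifier."""

    classifier_id: str
    family: str  # syntax-tree | dependency | shallow
    base_correctness: float = 0.8
    difficulty_sensitivity: float = 0.6  # λ: correctness drop per unit δ
    family_coupling: float = 1.0  # ρ: weight of the shared family effect
    positive_bias: float = 0.0  # shifts error asymmetry, drives rate r


@dataclass
class SimPredictionConfig:
    """Latent-difficulty and error-correlation model for prediction matrices."""

    difficulty_alpha: float = 2.0
    difficulty_beta: float = 2.0
    #: blend weight of the sentence parse-clarity signal into δ (0 = pure Beta)
    feature_coupling: float = 0.5
    family_sd: float = 0.15  # τ of the per-pair per-family effect
    cl_penalty: float = 0.12  # correctness drop in the CL setting
    clamp: tuple[float, float] = (0.02, 0.98)
    seed: int = 0


def positive_bias_for_rate(
    target_r: float, positive_ratio: float, base_correctness: float
) -> float:
    """Bias value for which a classifier's expected positive-prediction rate
    is ``target_r`` percent, given the gold ratio and its mean correctness
    (closed form, exact for difficulty-insensitive classifiers)."""
    rho, b = positive_ratio, base_correctness
    neutral = rho * b + (1 - rho) * (1 - b)
    return 2 * (target_r / 100 - neutral)


def _draw_protein_counts(rng, weights: dict[int, float], n: int) -> np.ndarray:
    ks = np.array(sorted(weights))
    p = np.array([weights[k] for k in ks], dtype=float)
    p /= p.sum()
    return rng.choice(ks, size=n, p=p)


def _positive_type_quota(
    config: SimCorpusConfig, counts: np.ndarray
) -> dict[int, int]:
    """Per-protein-count-stratum number of positive-type sentences.

    Solves q0 in  target = π_lo + q0 * span * Σ N_k C_k d(k) / Σ N_k C_k
    with d(k) = 1 / (1 + decay (k-2)), then applies per-stratum rounding.
    Raises when the target ratio is outside the achievable range.
    """
    span = config.pos_within - config.neg_within
    ks, n_k = np.unique(counts, return_counts=True)
    pair_k = np.array([k * (k - 1) // 2 for k in ks])
    d_k = 1.0 / (1.0 + config.count_decay * (ks - 2))
    mass = (n_k * pair_k).sum()
    d_bar = (n_k * pair_k * d_k).sum() / mass
    lo = config.neg_within
    hi = config.neg_within + span * d_bar
    target = config.target_positive_ratio
    if not lo <= target <= hi:
        raise ValidationError(
            f"target positive ratio {target:.3f} infeasible; achievable "
            f"range is [{lo:.3f}, {hi:.3f}] under this configuration"
        )
    q0 = (target - lo) / (span * d_bar)
    return {
        int(k): int(round(q0 * d * n))
        for k, d, n in zip(ks, d_k, n_k)
    }


def _chunk_tree(rng, pos_tags: list[str], clarity: float) -> TreeNode:
    """Shallow constituency tree: S over contiguous chunks of 3-5 leaves."""
    n = len(pos_tags)
    chunks: list[TreeNode] = []
    i = 0
    while i < n:
        size = min(int(rng.integers(3, 6)), n - i)
        if clarity < rng.random() * 0.75:
            label = "X"  # fallback constituent, frequent in opaque parses
        else:
            label = _CONST_LABELS[
                rng.choice(len(_CONST_LABELS), p=_CONST_WEIGHTS)
            ]
        leaves = [
            TreeNode(pos_tags[j], token_index=j) for j in range(i, i + size)
        ]
        chunks.append(TreeNode(label, leaves))
        i += size
    return TreeNode("S", chunks)


def _build_sentence(
    rng,
    sid: str,
    k: int,
    positive_type: bool,
    config: SimCorpusConfig,
    entity_counter: list[int],
) -> SentenceRecord:
    interaction = sorted(config.lexicons.interaction)
    negation = sorted(config.lexicons.negation)
    hedge = sorted(config.lexicons.hedge)

    if positive_type:
        length_mean, length_sd = config.pos_length_mean, config.pos_length_sd
        dist_target = config.pos_entity_distance
        p_inter, p_neg, p_hedge, p_comma = 0.9, 0.10, 0.15, 0.15
    else:
        length_mean, length_sd = config.neg_length_mean, config.neg_length_sd
        dist_target = config.neg_entity_distance
        p_inter, p_neg, p_hedge, p_comma = 0.2, 0.45, 0.40, 0.45

    # entity spacing g reproduces the class-mean pair distance: the average
    # index gap over all pairs of k equally spaced entities is g (k+1)/3
    g = 3.0 * (dist_target + 1.0) / (k + 1)
    gaps = [max(2, int(round(g + rng.normal(0, 0.6)))) for _ in range(k - 1)]
    span = sum(gaps)
    length = int(round(rng.normal(length_mean, length_sd)))
    length = max(length, span + 4, 6)
    start = int(rng.integers(1, max(2, length - span - 2)))
    positions = [start]
    for gap in gaps:
        positions.append(positions[-1] + gap)

    words = [""] * length
    pos_tags = ["NN"] * length
    entity_names = []
    for pos in positions:
        entity_counter[0] += 1
        name = f"PROT{entity_counter[0]}"
        words[pos] = name
        pos_tags[pos] = "NN"
        entity_names.append((pos, name))

    def place(word: str, tag: str, lo: int, hi: int) -> None:
        free = [i for i in range(max(0, lo), min(length, hi)) if not words[i]]
        if free:
            i = free[int(rng.integers(0, len(free)))]
            words[i] = word
            pos_tags[i] = tag

    for a, b in zip(positions, positions[1:]):
        if rng.random() < p_inter:
            place(interaction[int(rng.integers(0, len(interaction)))], "VBZ", a + 1, b)
        if rng.random() < p_comma:
            place(",", ",", a + 1, b)
    if rng.random() < p_neg:
        place(negation[int(rng.integers(0, len(negation)))], "RB", 0, positions[0])
    if rng.random() < p_hedge:
        place(hedge[int(rng.integers(0, len(hedge)))], "MD", positions[-1] + 1, length)
    filler_tags = ["NN", "JJ", "DT", "IN", "VBN", "CC"]
    for i in range(length):
        if not words[i]:
            words[i] = _FILLERS[int(rng.integers(0, len(_FILLERS)))]
            pos_tags[i] = filler_tags[int(rng.integers(0, len(filler_tags)))]
    words[-1] = "."
    pos_tags[-1] = "."

    text = " ".join(words)
    tokens = []
    cursor = 0
    for i, w in enumerate(words):
        tokens.append(Token(i, w, pos_tags[i], (cursor, cursor + len(w))))
        cursor += len(w) + 1

    entities = []
    for j, (pos, name) in enumerate(entity_names):
        tok = tokens[pos]
        entities.append(
            Entity(
                id=f"{sid}.e{j}",
                char_span=tok.char_span,
                surface_text=name,
            )
        )

    clarity = float(rng.uniform(0, 1))
    import networkx as nx

    dep = nx.DiGraph()
    dep.add_nodes_from(range(length))
    for i in range(length - 1):
        if rng.random() < 0.8 - 0.62 * clarity:
            label = "dep"
        else:
            label = _DEP_LABELS[rng.choice(len(_DEP_LABELS), p=_DEP_WEIGHTS)]
        dep.add_edge(i, i + 1, label=label)

    tree = _chunk_tree(rng, pos_tags, clarity)

    pairs = []
    pidx = 0
    p_pos = config.pos_within if positive_type else config.neg_within
    for a in range(k):
        for b in range(a + 1, k):
            pairs.append(
                CandidatePair(
                    id=f"{sid}.p{pidx}",
                    e1=entities[a].id,
                    e2=entities[b].id,
                    gold=bool(rng.random() < p_pos),
                )
            )
            pidx += 1

    return SentenceRecord(
        id=sid,
        text=text,
        entities=entities,
        pairs=pairs,
        tokens=tokens,
        dep_graph=dep,
        syntax_tree=tree,
    )


def generate_corpus(
    config: SimCorpusConfig, pair_budget: int | None = None
) -> Corpus:
    """Generate a corpus under the configured study conditions.

    Every sentence enumerates all C(k,2) candidate pairs and carries token,
    dependency and constituency layers.  With ``pair_budget`` the document
    loop runs until exactly that many pairs exist (final sentences are
    forced to two proteins); otherwise ``n_documents`` documents are drawn.
    Identical config and seed yield an identical corpus.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # skeleton: per-document protein counts
    skeleton: list[list[int]] = []
    if pair_budget is None:
        lo, hi = config.sentences_per_document
        for _ in range(config.n_documents):
            n_sent = int(rng.integers(lo, hi + 1))
            skeleton.append(
                list(_draw_protein_counts(rng, config.protein_count_weights, n_sent))
            )
    else:
        remaining = pair_budget
        lo, hi = config.sentences_per_document
        while remaining > 0:
            n_sent = int(rng.integers(lo, hi + 1))
            doc: list[int] = []
            for _ in range(n_sent):
                if remaining <= 0:
                    break
                k = int(_draw_protein_counts(rng, config.protein_count_weights, 1)[0])
                while k > 2 and k * (k - 1) // 2 > remaining:
                    k -= 1
                doc.append(k)
                remaining -= k * (k - 1) // 2
            if doc:
                skeleton.append(doc)

    counts = np.array([k for doc in skeleton for k in doc], dtype=int)
    corpus = Corpus(name=config.name)
    if counts.size == 0:
        return corpus

    quota = _positive_type_quota(config, counts)
    # assign positive-type slots uniformly at random within each k stratum
    positive_type = np.zeros(counts.size, dtype=bool)
    for k, n_pos in quota.items():
        idx = np.flatnonzero(counts == k)
        chosen = rng.permutation(idx)[:n_pos]
        positive_type[chosen] = True

    entity_counter = [0]
    flat = 0
    for di, doc_ks in enumerate(skeleton):
        doc = Document(id=f"{config.name}.d{di}")
        for si, k in enumerate(doc_ks):
            sid = f"{doc.id}.s{si}"
            doc.sentences.append(
                _build_sentence(
                    rng, sid, int(k), bool(positive_type[flat]), config,
                    entity_counter,
                )
            )
            flat += 1
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


def _sentence_clarity(sentence: SentenceRecord) -> float:
    """Realized parse clarity in [0, 1]: normalized dependency-label entropy."""
    if sentence.dep_graph is None or sentence.dep_graph.number_of_edges() == 0:
        return 0.5
    from collections import Counter

    counts = Counter(
        d.get("label", "dep") for _, _, d in sentence.dep_graph.edges(data=True)
    )
    h = _stats.entropy(list(counts.values()), base=2)
    h_max = math.log2(len(_DEP_LABELS) + 1)
    return float(min(1.0, h / h_max))


def generate_predictions(
    corpus: Corpus,
    profiles: Sequence[SimClassifierProfile],
    pconfig: SimPredictionConfig,
    setting: str = "CV",
    return_difficulty: bool = False,
):
    """Simulate a prediction matrix over the corpus pairs.

    For each pair p and classifier c the correctness probability is

        clamp(b_c - λ_c δ_p + ρ_c u_{family(c)}(p) - [CL] cl_penalty ± bias/2)

    where δ_p blends Beta(a, b) noise with the pair's sentence parse
    opacity (1 - clarity), u is a per-pair per-family Normal(0, τ) effect
    shared between settings, and the bias term is +bias/2 on gold-positive
    pairs and -bias/2 on gold-negative ones.  The prediction equals gold
    with that probability and the flipped label otherwise.  δ and u depend
    only on (pconfig.seed, corpus); the correctness coin flips additionally
    depend on the setting.
    """
    if not profiles:
        raise ValidationError("profiles must be non-empty")
    if setting not in ("CV", "CL"):
        raise ValidationError(f"unknown setting {setting!r}")
    families = sorted({p.family for p in profiles})
    fam_index = {f: i for i, f in enumerate(families)}
    pair_rng = np.random.default_rng([pconfig.seed, 1013])
    flip_rng = np.random.default_rng(
        [pconfig.seed, 2027 if setting == "CL" else 3041]
    )
    lo, hi = pconfig.clamp
    w = pconfig.feature_coupling
    penalty = pconfig.cl_penalty if setting == "CL" else 0.0

    table = {}
    difficulty = {}
    for sentence, pair in corpus.pairs():
        noise = pair_rng.beta(pconfig.difficulty_alpha, pconfig.difficulty_beta)
        delta = (1 - w) * noise + w * (1.0 - _sentence_clarity(sentence))
        difficulty[pair.id] = float(delta)
        u = pair_rng.normal(0.0, pconfig.family_sd, size=len(families))
        for prof in profiles:
            p_correct = (
                prof.base_correctness
                - prof.difficulty_sensitivity * delta
                + prof.family_coupling * u[fam_index[prof.family]]
                - penalty
                + (0.5 if pair.gold else -0.5) * prof.positive_bias
            )
            p_correct = min(hi, max(lo, p_correct))
            correct = bool(flip_rng.random() < p_correct)
            table[(pair.id, prof.classifier_id)] = (
                pair.gold if correct else not pair.gold
            )
    pset = PredictionSet(
        setting=setting,
        roster=sorted(p.classifier_id for p in profiles),
        table=table,
    )
    if return_difficulty:
        return pset, difficulty
    return pset


def default_roster(include_pt: bool = True) -> list[SimClassifierProfile]:
    """Thirteen classifier profiles in three representation families,
    mirroring the benchmark rosters (the slow PT member is dropped from the
    cross-learning roster)."""
    rows = [
        # (id, family, base correctness, λ, bias)
        ("ST", "syntax-tree", 0.80, 0.62, 0.04),
        ("SST", "syntax-tree", 0.81, 0.60, 0.02),
        ("PT", "syntax-tree", 0.78, 0.64, 0.04),
        ("SpT", "syntax-tree", 0.74, 0.70, 0.22),
        ("APG", "dependency", 0.86, 0.55, 0.00),
        ("kBSPS", "dependency", 0.83, 0.62, 0.12),
        ("edit", "dependency", 0.79, 0.58, -0.08),
        ("cosine", "dependency", 0.78, 0.60, 0.00),
        ("syntactic", "dependency", 0.78, 0.60, -0.01),
        ("SL", "shallow", 0.85, 0.56, 0.05),
        ("shallow", "shallow", 0.77, 0.62, 0.00),
        ("lexical", "shallow", 0.78, 0.61, 0.00),
        ("combined", "shallow", 0.80, 0.58, -0.01),
    ]
    out = [
        SimClassifierProfile(
            classifier_id=cid,
            family=fam,
            base_correctness=b,
            difficulty_sensitivity=lam,
            positive_bias=bias,
        )
        for cid, fam, b, lam, bias in rows
    ]
    if not include_pt:
        out = [p for p in out if p.classifier_id != "PT"]
    return out


@dataclass
class BenchmarkSuite:
    """Five synthetic corpora with pooled CV and CL prediction matrices."""

    corpora: list[Corpus]
    cv: PredictionSet
    cl: PredictionSet
    difficulty: dict[str, float]

    def corpus(self, name: str) -> Corpus:
        for c in self.corpora:
            if c.name == name:
                return c
        raise KeyError(name)


def generate_benchmark_suite(
    seed: int, size_factor: float = 1.0
) -> BenchmarkSuite:
    """Emulate the five-corpus benchmark: corpus sizes and positive ratios
    follow the published benchmarks scaled by ``size_factor``; the CV
    roster has 13 classifiers, the CL roster 12 (PT omitted)."""
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(BENCHMARK_SIZES) + 1)
    corpora = []
    cv_table: dict = {}
    cl_table: dict = {}
    difficulty: dict[str, float] = {}
    roster_cv = roster_cl = None
    for i, (name, (size, ratio)) in enumerate(sorted(BENCHMARK_SIZES.items())):
        budget = max(3, int(round(size * size_factor)))
        config = SimCorpusConfig(
            name=name,
            target_positive_ratio=ratio,
            seed=int(seeds[2 * i] % (2**31)),
        )
        corpus = generate_corpus(config, pair_budget=budget)
        corpora.append(corpus)
        pconfig = SimPredictionConfig(seed=int(seeds[2 * i + 1] % (2**31)))
        cv, delta = generate_predictions(
            corpus, default_roster(True), pconfig, "CV", return_difficulty=True
        )
        cl = generate_predictions(corpus, default_roster(False), pconfig, "CL")
        cv_table.update(cv.table)
        cl_table.update(cl.table)
        difficulty.update(delta)
        roster_cv, roster_cl = cv.roster, cl.roster
    return BenchmarkSuite(
        corpora=corpora,
        cv=PredictionSet(setting="CV", roster=roster_cv, table=cv_table),
        cl=PredictionSet(setting="CL", roster=roster_cl, table=cl_table),
        difficulty=difficulty,
    )


def random_folds(corpus: Corpus, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Document-level fold partition, balanced by round-robin over a shuffle."""
    rng = np.random.default_rng(seed)
    docs = [d.id for d in corpus.documents]
    order = rng.permutation(len(docs))
    mapping = {docs[j]: int(i % n_folds) for i, j in enumerate(order)}
    return FoldAssignment(mapping=mapping, n_folds=n_folds)
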