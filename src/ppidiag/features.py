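"""Surface and parse feature extraction per candidate pair.

Surface features are computed on an entity-blinded tokenization: the two
pair entities become ``ENT1``/``ENT2`` and other protein mentions become
``PROT``.  Lexicon clue flags are evaluated in four scopes — the whole
sentence (s), before the earlier entity (b), strictly between the entities
(w), and after the later entity (a).

Parse features cover the labeled dependency graph (DG) and the constituency
tree (ST): shortest-path lengths between the two entities, per-label
occurrence counts and relative frequencies over the whole structure and
along the shortest path, and Shannon entropies of those label
distributions (a Kullback-Leibler mode against the corpus background is
available).  Missing layers yield absent (NaN) features, never zeros.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from importlib import resources
from scipy import stats

from .difficulty import CombinedClasses
from .model import CandidatePair, Corpus, Entity, SentenceRecord, Token, TreeNode, ValidationError

__all__ = [
    "Lexicons",
    "tokenize",
    "surface_features",
    "dg_features",
    "st_features",
    "pair_features",
    "feature_table",
    "six_way_classes",
    "aggregate_by_difficulty",
    "positive_rate_by_length",
    "class_dist_by_protein_count",
]

_SCOPES = ("s", "b", "w", "a")
_CLUE_KINDS = ("negation", "hedge", "interaction")

#: Core always-present feature columns.
SURFACE_COLUMNS = (
    ["sentence_length_char", "sentence_length_word", "entity_word_distance", "n_proteins"]
    + [f"{kind}_{scope}" for kind in _CLUE_KINDS for scope in _SCOPES]
    + ["comma_between", "ing_after_e1"]
)


def _load_wordlist(name: str) -> frozenset[str]:
    text = resources.files("ppidiag.data").joinpath(name).read_text()
    return frozenset(
        w.strip().lower()
        for w in text.splitlines()
        if w.strip() and not w.startswith("#")
    )


@dataclass(frozen=True)
class Lexicons:
    """Clue word lists; defaults ship with the package and are overridable."""

    interaction: frozenset[str] = field(default_factory=lambda: _load_wordlist("interaction_words.txt"))
    negation: frozenset[str] = field(default_factory=lambda: _load_wordlist("negation_words.txt"))
    hedge: frozenset[str] = field(default_factory=lambda: _load_wordlist("hedge_words.txt"))

    def words(self, kind: str) -> frozenset[str]:
        return getattr(self, kind)


_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(
    sentence: SentenceRecord, pair: CandidatePair | None = None
) -> list[Token]:
    """Deterministic whitespace/punctuation tokenization with entity blinding.

    Each entity span collapses to one token: ``ENT1``/``ENT2`` for the pair's
    entities (in sentence order of mention ids as given), ``PROT`` otherwise.
    Token spans partition the non-space characters of the sentence.
    """
    spans = sorted((e.char_span, e.id) for e in sentence.entities)
    for (a, b), (c, d) in zip(spans, spans[1:]):
        if a[1] > c[0]:
            raise ValidationError(
                f"sentence {sentence.id}: overlapping entity spans {a} and {c}"
            )
    blind = {}
    if pair is not None:
        blind[pair.e1] = "ENT1"
        blind[pair.e2] = "ENT2"
    out: list[Token] = []
    cursor = 0
    for (start, end), eid in spans:
        for m in _TOKEN_RE.finditer(sentence.text, cursor, start):
            out.append(Token(len(out), m.group(), char_span=(m.start(), m.end())))
        out.append(
            Token(len(out), blind.get(eid, "PROT"), char_span=(start, end))
        )
        cursor = end
    for m in _TOKEN_RE.finditer(sentence.text, cursor):
        out.append(Token(len(out), m.group(), char_span=(m.start(), m.end())))
    return out


def _entity_positions(tokens: list[Token]) -> tuple[int, int]:
    idx = {t.text: t.index for t in tokens if t.text in ("ENT1", "ENT2")}
    if len(idx) != 2:
        raise ValidationError("pair entities not found in blinded tokens")
    first, second = sorted(idx.values())
    return first, second


def surface_features(
    sentence: SentenceRecord, pair: CandidatePair, lexicons: Lexicons
) -> dict[str, float]:
    """Length, distance, count and clue-flag features for one pair."""
    tokens = tokenize(sentence, pair)
    first, second = _entity_positions(tokens)
    scopes = {
        "s": tokens,
        "b": tokens[:first],
        "w": tokens[first + 1 : second],
        "a": tokens[second + 1 :],
    }
    feats: dict[str, float] = {
        "sentence_length_char": float(len(sentence.text)),
        "sentence_length_word": float(len(tokens)),
        "entity_word_distance": float(second - first - 1),
        "n_proteins": float(len(sentence.entities)),
    }
    for kind in _CLUE_KINDS:
        words = lexicons.words(kind)
        for scope, toks in scopes.items():
            feats[f"{kind}_{scope}"] = float(
                any(t.text.lower() in words for t in toks)
            )
    feats["comma_between"] = float(any(t.text == "," for t in scopes["w"]))
    nxt = tokens[first + 1] if first + 1 < len(tokens) else None
    feats["ing_after_e1"] = float(
        nxt is not None
        and nxt.text.lower().endswith("ing")
        and nxt.text not in ("ENT1", "ENT2", "PROT")
    )
    return feats


def _entity_head_index(sentence: SentenceRecord, entity: Entity) -> int:
    """Head token of an entity = its last overlapping token in the sentence layer."""
    if sentence.tokens is None:
        raise ValidationError(f"sentence {sentence.id}: no token layer")
    start, end = entity.char_span
    hits = [
        t.index
        for t in sentence.tokens
        if t.char_span[0] < end and t.char_span[1] > start
    ]
    if not hits:
        raise ValidationError(
            f"entity {entity.id}: no token overlaps span {entity.char_span}"
        )
    return max(hits)


def _bfs_shortest_path(adj: Mapping[int, Sequence[int]], src: int, dst: int) -> list[int] | None:
    """BFS shortest path, neighbors explored in ascending index order so the
    returned path is the lexicographically smallest among the shortest."""
    if src == dst:
        return [src]
    parent = {src: -1}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(adj.get(u, ())):
                if v not in parent:
                    parent[v] = u
                    if v == dst:
                        path = [v]
                        while path[-1] != src:
                            path.append(parent[path[-1]])
                        return path[::-1]
                    nxt.append(v)
        frontier = nxt
    return None


def _distribution_features(
    prefix: str, labels: Sequence[str]
) -> dict[str, float]:
    counts = Counter(labels)
    total = sum(counts.values())
    feats: dict[str, float] = {}
    for lab, c in counts.items():
        feats[f"{prefix}_{lab}_count"] = float(c)
        feats[f"{prefix}_{lab}_freq"] = c / total
    feats[f"{prefix}_label_entropy"] = (
        float(stats.entropy(list(counts.values()), base=2)) if counts else 0.0
    )
    return feats


def label_divergence(
    labels: Sequence[str], reference: Mapping[str, float]
) -> float:
    """KL divergence (bits) of the empirical label distribution from a
    background distribution; labels missing from the reference get a small
    floor mass so the divergence stays finite."""
    counts = Counter(labels)
    total = sum(counts.values())
    if not total:
        return 0.0
    floor = 1e-9
    div = 0.0
    for lab, c in counts.items():
        p = c / total
        q = max(reference.get(lab, 0.0), floor)
        div += p * math.log2(p / q)
    return div


def dg_features(
    sentence: SentenceRecord, pair: CandidatePair
) -> dict[str, float]:
    """Dependency-graph features: shortest path between the entity head
    tokens on the undirected view (unit weights), label counts/frequencies
    and entropy over the whole graph and the path.  Disconnected entities
    yield absent path features."""
    if sentence.dep_graph is None:
        raise ValidationError(f"sentence {sentence.id}: no dependency layer")
    g = sentence.dep_graph
    head1 = _entity_head_index(sentence, sentence.entity_by_id(pair.e1))
    head2 = _entity_head_index(sentence, sentence.entity_by_id(pair.e2))
    all_labels = [d.get("label", "dep") for _, _, d in g.edges(data=True)]
    feats = _distribution_features("dg", all_labels)
    adj: dict[int, set[int]] = {}
    for u, v in g.edges():
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    path = _bfs_shortest_path(adj, head1, head2)
    if path is None or len(path) < 2:
        return feats  # path features flagged absent at table level
    labels = []
    for u, v in zip(path, path[1:]):
        data = g.get_edge_data(u, v) or g.get_edge_data(v, u)
        labels.append(data.get("label", "dep"))
    feats["dg_path_length"] = float(len(path) - 1)
    feats.update(_distribution_features("dgp", labels))
    return feats


def _tree_parents(root: TreeNode) -> dict[int, TreeNode | None]:
    parents: dict[int, TreeNode | None] = {id(root): None}
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in node.children:
            parents[id(ch)] = node
            stack.append(ch)
    return parents


def st_features(
    sentence: SentenceRecord, pair: CandidatePair
) -> dict[str, float]:
    """Constituency-tree features: leaf-to-leaf path through the lowest
    common ancestor, plus constituent-label statistics for the whole tree
    and the path."""
    if sentence.syntax_tree is None:
        raise ValidationError(f"sentence {sentence.id}: no syntax-tree layer")
    root = sentence.syntax_tree
    head1 = _entity_head_index(sentence, sentence.entity_by_id(pair.e1))
    head2 = _entity_head_index(sentence, sentence.entity_by_id(pair.e2))
    by_index = {leaf.token_index: leaf for leaf in root.leaves()}
    try:
        leaf1, leaf2 = by_index[head1], by_index[head2]
    except KeyError as exc:
        raise ValidationError(
            f"sentence {sentence.id}: entity leaf {exc} not found in tree"
        ) from None
    parents = _tree_parents(root)

    def chain(leaf: TreeNode) -> list[TreeNode]:
        out = [leaf]
        while parents[id(out[-1])] is not None:
            out.append(parents[id(out[-1])])
        return out

    up1, up2 = chain(leaf1), chain(leaf2)
    anc2 = {id(n): i for i, n in enumerate(up2)}
    for i, node in enumerate(up1):
        if id(node) in anc2:
            j = anc2[id(node)]
            break
    path_nodes = up1[: i + 1] + up2[:j][::-1]
    feats = _distribution_features("st", root.internal_labels())
    feats["st_path_length"] = float(i + j)
    feats.update(
        _distribution_features(
            "stp", [n.label for n in path_nodes if not n.is_leaf]
        )
    )
    return feats


def pair_features(
    sentence: SentenceRecord,
    pair: CandidatePair,
    lexicons: Lexicons,
) -> dict[str, float]:
    """Full feature vector for one pair (absent layers simply contribute
    no keys; the table assembler distinguishes absent from zero)."""
    feats = surface_features(sentence, pair, lexicons)
    if sentence.dep_graph is not None and sentence.tokens is not None:
        feats["has_dg"] = 1.0
        feats.update(dg_features(sentence, pair))
    else:
        feats["has_dg"] = 0.0
    if sentence.syntax_tree is not None and sentence.tokens is not None:
        feats["has_st"] = 1.0
        feats.update(st_features(sentence, pair))
    else:
        feats["has_st"] = 0.0
    return feats


def feature_table(
    corpus: Corpus,
    lexicons: Lexicons | None = None,
    entropy_mode: str = "shannon",
) -> pd.DataFrame:
    """One feature vector per candidate pair, registry closed over observed
    labels.

    Count/frequency columns for labels a structure merely does not contain
    are backfilled with 0 for pairs whose layer exists; pairs without the
    layer keep NaN (absent).  ``entropy_mode="kl"`` adds Kullback-Leibler
    divergences of each pair's label distributions against the corpus-wide
    background distribution.
    """
    if entropy_mode not in ("shannon", "kl"):
        raise ValidationError(f"entropy_mode {entropy_mode!r}")
    lexicons = lexicons or Lexicons()
    rows = {}
    for sentence, pair in corpus.pairs():
        rows[pair.id] = pair_features(sentence, pair, lexicons)
    df = pd.DataFrame.from_dict(rows, orient="index")
    # close the registry: observed-label columns become 0 where the structure
    # exists (a connected path for dgp_/stp_ columns), stay NaN where absent
    def _present(prefix: str) -> pd.Series:
        if prefix == "dg_":
            return df.get("has_dg", pd.Series(0.0, index=df.index)) == 1.0
        if prefix == "st_":
            return df.get("has_st", pd.Series(0.0, index=df.index)) == 1.0
        key = "dg_path_length" if prefix == "dgp_" else "st_path_length"
        if key not in df.columns:
            return pd.Series(False, index=df.index)
        return df[key].notna()

    for prefix in ("dg_", "dgp_", "st_", "stp_"):
        cols = [
            c
            for c in df.columns
            if c.startswith(prefix) and (c.endswith("_count") or c.endswith("_freq"))
        ]
        if cols:
            mask = _present(prefix)
            df.loc[mask, cols] = df.loc[mask, cols].fillna(0.0)
    if entropy_mode == "kl":
        df = _add_kl_columns(df, corpus, lexicons)
    return df.sort_index(axis=1)


def _add_kl_columns(
    df: pd.DataFrame, corpus: Corpus, lexicons: Lexicons
) -> pd.DataFrame:
    backgrounds: dict[str, Counter] = {
        "dg": Counter(),
        "st": Counter(),
    }
    for sentence in corpus.sentences():
        if sentence.dep_graph is not None:
            backgrounds["dg"].update(
                d.get("label", "dep")
                for _, _, d in sentence.dep_graph.edges(data=True)
            )
        if sentence.syntax_tree is not None:
            backgrounds["st"].update(sentence.syntax_tree.internal_labels())
    refs = {
        key: {lab: c / total for lab, c in cnt.items()}
        for key, cnt in backgrounds.items()
        if (total := sum(cnt.values()))
    }
    for sentence, pair in corpus.pairs():
        for key, ref in refs.items():
            if key == "dg" and sentence.dep_graph is not None:
                labels = [
                    d.get("label", "dep")
                    for _, _, d in sentence.dep_graph.edges(data=True)
                ]
            elif key == "st" and sentence.syntax_tree is not None:
                labels = sentence.syntax_tree.internal_labels()
            else:
                continue
            df.loc[pair.id, f"{key}_label_kl"] = label_divergence(labels, ref)
    return df


SIX_WAY = ("ND", "NN", "NE", "PD", "PN", "PE")


def six_way_classes(
    combined: CombinedClasses, gold: Mapping[str, bool]
) -> dict[str, str]:
    """Gold-signed six-way difficulty classes ND/NN/NE/PD/PN/PE."""
    out = {}
    for pid, cls in combined.classes.items():
        sign = "P" if gold[pid] else "N"
        out[pid] = sign + {"D": "D", "N": "N", "E": "E"}[cls]
    return out


def aggregate_by_difficulty(
    table: pd.DataFrame, classes: Mapping[str, str]
) -> pd.DataFrame:
    """Per-difficulty-class means of sentence length, entity distance and
    the two shortest-path lengths (NaN for empty classes / absent layers)."""
    cols = [
        "sentence_length_word",
        "entity_word_distance",
        "dg_path_length",
        "st_path_length",
    ]
    cols = [c for c in cols if c in table.columns]
    cls = pd.Series(classes).reindex(table.index)
    out = table[cols].groupby(cls).mean()
    return out.reindex([c for c in SIX_WAY if c in out.index])


def _sentence_word_length(sentence: SentenceRecord) -> int:
    if sentence.tokens is not None:
        return len(sentence.tokens)
    return len(tokenize(sentence))


def positive_rate_by_length(
    corpus: Corpus, binning: Sequence[float] | int = 8
) -> pd.DataFrame:
    """Gold positive rate per sentence-length bin; bin totals conserve pairs."""
    records = [
        (_sentence_word_length(s), p.gold) for s, p in corpus.pairs()
    ]
    if not records:
        raise ValidationError("empty corpus")
    lengths = np.array([r[0] for r in records])
    gold = np.array([r[1] for r in records])
    if isinstance(binning, int):
        edges = np.unique(
            np.quantile(lengths, np.linspace(0, 1, binning + 1))
        ).astype(float)
        edges[-1] += 1
    else:
        edges = np.asarray(binning, dtype=float)
    idx = np.clip(np.digitize(lengths, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        pos = int(gold[mask].sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "pairs": n,
                "positives": pos,
                "positive_rate": pos / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def class_dist_by_protein_count(corpus: Corpus) -> pd.DataFrame:
    """Gold class distribution of pairs by the number of proteins in the
    sentence (rows conserve per-count pair totals)."""
    rows: dict[int, list[int]] = {}
    for s, p in corpus.pairs():
        k = len(s.entities)
        rows.setdefault(k, [0, 0])
        rows[k][0] += 1
        rows[k][1] += int(p.gold)
    if not rows:
        raise ValidationError("empty corpus")
    out = pd.DataFrame(
        [
            {
                "n_proteins": k,
                "pairs": n,
                "positives": pos,
                "negatives": n - pos,
                "positive_rate": pos / n,
            }
            for k, (n, pos) in sorted(rows.items())
        ]
    )
    return out
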