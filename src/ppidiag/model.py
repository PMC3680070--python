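"""Canonical in-memory model for PPI corpora, predictions and fold assignments.

A corpus is a named, ordered collection of documents; each document is an
ordered list of sentences; each sentence carries character-offset entity
mentions and labeled candidate pairs, plus optional linguistic layers
(tokens with POS tags, a labeled dependency graph over token indices, and a
constituency tree whose leaves align with the tokens).

All character coordinates are 0-based half-open internally.  The unified
XML interchange dialect uses inclusive offsets; conversion happens at the
I/O boundary (see :mod:`ppidiag.io`).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Entity",
    "CandidatePair",
    "Token",
    "TreeNode",
    "SentenceRecord",
    "Document",
    "Corpus",
    "PredictionSet",
    "FoldAssignment",
    "ValidationError",
    "CORPUS_PREFIXES",
    "normalize_pair_id",
    "corpus_stats",
]

#: Short-prefix <-> corpus-name map for the five PPI benchmark corpora.
CORPUS_PREFIXES = {
    "A": "AIMed",
    "B": "BioInfer",
    "H": "HPRD50",
    "I": "IEPA",
    "L": "LLL",
}
_NAME_TO_PREFIX = {v: k for k, v in CORPUS_PREFIXES.items()}


class ValidationError(ValueError):
    """A structural invariant of the data model is violated."""


@dataclass
class Entity:
    """A protein mention anchored to a sentence by a half-open char span."""

    id: str
    char_span: tuple[int, int]
    surface_text: str
    entity_type: str = "protein"

    def validate(self, sentence_text: str) -> None:
        start, end = self.char_span
        if not (0 <= start < end <= len(sentence_text)):
            raise ValidationError(
                f"entity {self.id}: span {self.char_span} outside sentence "
                f"of length {len(sentence_text)}"
            )
        sub = sentence_text[start:end]
        if sub != self.surface_text:
            raise ValidationError(
                f"entity {self.id}: surface text {self.surface_text!r} does "
                f"not match sentence substring {sub!r}"
            )


@dataclass
class CandidatePair:
    """An unordered candidate entity pair with a gold interaction label."""

    id: str
    e1: str
    e2: str
    gold: bool

    def __post_init__(self) -> None:
        if self.e1 == self.e2:
            raise ValidationError(f"pair {self.id}: self-interaction (e1 == e2)")


@dataclass
class Token:
    index: int
    text: str
    pos: str = ""
    char_span: tuple[int, int] = (0, 0)


@dataclass
class TreeNode:
    """Minimal ordered labeled constituency-tree node.

    Leaves carry ``token_index`` (>= 0) aligning them with the token layer.
    """

    label: str
    children: list["TreeNode"] = field(default_factory=list)
    token_index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def internal_labels(self) -> list[str]:
        """Labels of all non-leaf nodes, pre-order."""
        if self.is_leaf:
            return []
        out = [self.label]
        for ch in self.children:
            out.extend(ch.internal_labels())
        return out

    def to_bracketed(self) -> str:
        if self.is_leaf:
            return f"{self.label}~{self.token_index}"
        inner = " ".join(ch.to_bracketed() for ch in self.children)
        return f"({self.label} {inner})"

    @classmethod
    def from_bracketed(cls, text: str) -> "TreeNode":
        tokens = re.findall(r"\(|\)|[^()\s]+", text)
        pos = 0

        def parse() -> TreeNode:
            nonlocal pos
            if tokens[pos] == "(":
                pos += 1
                label = tokens[pos]
                pos += 1
                children = []
                while tokens[pos] != ")":
                    children.append(parse())
                pos += 1
                return cls(label, children)
            tok = tokens[pos]
            pos += 1
            label, _, idx = tok.rpartition("~")
            return cls(label, token_index=int(idx))

        node = parse()
        if pos != len(tokens):
            raise ValidationError("trailing content in bracketed tree")
        return node


@dataclass
class SentenceRecord:
    id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    pairs: list[CandidatePair] = field(default_factory=list)
    tokens: list[Token] | None = None
    dep_graph: nx.DiGraph | None = None
    syntax_tree: TreeNode | None = None
    #: unknown XML child elements preserved verbatim for round-tripping
    extra_xml: list[str] = field(default_factory=list)

    def entity_by_id(self, entity_id: str) -> Entity:
        for e in self.entities:
            if e.id == entity_id:
                return e
        raise KeyError(entity_id)

    def validate(self) -> None:
        for e in self.entities:
            e.validate(self.text)
        ids = {e.id for e in self.entities}
        n = len(self.entities)
        if len(self.pairs) > n * (n - 1) // 2:
            raise ValidationError(
                f"sentence {self.id}: {len(self.pairs)} pairs exceed C({n},2)"
            )
        for p in self.pairs:
            for end in (p.e1, p.e2):
                if end not in ids:
                    raise ValidationError(
                        f"pair {p.id}: dangling entity reference {end}"
                    )
        if self.dep_graph is not None and self.tokens is not None:
            n_tok = len(self.tokens)
            for u, v in self.dep_graph.edges():
                if not (0 <= u < n_tok and 0 <= v < n_tok):
                    raise ValidationError(
                        f"sentence {self.id}: dependency endpoint ({u},{v}) "
                        f"outside token range 0..{n_tok - 1}"
                    )
        if self.syntax_tree is not None and self.tokens is not None:
            if len(self.syntax_tree.leaves()) != len(self.tokens):
                raise ValidationError(
                    f"sentence {self.id}: tree leaf count differs from token count"
                )


@dataclass
class Document:
    id: str
    sentences: list[SentenceRecord] = field(default_factory=list)


@dataclass
class Corpus:
    name: str
    documents: list[Document] = field(default_factory=list)

    def sentences(self) -> Iterator[SentenceRecord]:
        for doc in self.documents:
            yield from doc.sentences

    def pairs(self) -> Iterator[tuple[SentenceRecord, CandidatePair]]:
        for s in self.sentences():
            for p in s.pairs:
                yield s, p

    def pair_ids(self) -> list[str]:
        return [p.id for _, p in self.pairs()]

    def gold(self) -> dict[str, bool]:
        return {p.id: p.gold for _, p in self.pairs()}

    def validate(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            for item_id in itertools.chain(
                [doc.id],
                (s.id for s in doc.sentences),
                (e.id for s in doc.sentences for e in s.entities),
                (p.id for s in doc.sentences for p in s.pairs),
            ):
                if item_id in seen:
                    raise ValidationError(f"duplicate id {item_id}")
                seen.add(item_id)
            for s in doc.sentences:
                s.validate()


def merge_gold(corpora: Iterable[Corpus]) -> dict[str, bool]:
    """Pooled pair-id -> gold-label map over several corpora."""
    out: dict[str, bool] = {}
    for c in corpora:
        out.update(c.gold())
    return out


@dataclass
class PredictionSet:
    """Predicted labels of a roster of classifiers in one evaluation setting.

    ``setting`` is ``"CV"`` (document-level cross-validation) or ``"CL"``
    (cross-learning: train on four corpora, test on the fifth).  The two
    settings have separate rosters and are never mixed.
    """

    setting: str
    roster: list[str]
    table: dict[tuple[str, str], bool]

    def __post_init__(self) -> None:
        if self.setting not in ("CV", "CL"):
            raise ValidationError(f"unknown setting {self.setting!r}")

    def pair_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.table:
            seen.setdefault(pid)
        return list(seen)

    def get(self, pair_id: str, classifier_id: str) -> bool:
        try:
            return self.table[(pair_id, classifier_id)]
        except KeyError:
            raise KeyError(
                f"no prediction for pair {pair_id!r} by classifier "
                f"{classifier_id!r} in {self.setting}"
            ) from None

    def column(self, classifier_id: str) -> dict[str, bool]:
        if classifier_id not in self.roster:
            raise KeyError(classifier_id)
        return {
            pid: lab
            for (pid, cid), lab in self.table.items()
            if cid == classifier_id
        }

    def validate_against(self, gold: Mapping[str, bool]) -> None:
        """Check completeness: every gold pair has a label from every roster member."""
        for pid in gold:
            for cid in self.roster:
                if (pid, cid) not in self.table:
                    raise ValidationError(
                        f"missing prediction for pair {pid} / classifier {cid}"
                    )


@dataclass
class FoldAssignment:
    """Document-level fold partition for cross-validation."""

    mapping: dict[str, int]
    n_folds: int = 10

    def __post_init__(self) -> None:
        for doc, fold in self.mapping.items():
            if not (0 <= fold < self.n_folds):
                raise ValidationError(
                    f"document {doc}: fold {fold} outside 0..{self.n_folds - 1}"
                )

    def documents_in_fold(self, fold: int) -> list[str]:
        return [d for d, f in self.mapping.items() if f == fold]


_PAIR_ID_RE = re.compile(r"^([A-Za-z0-9]+)\.(d\w+)\.(s\w+)\.(p\w+)$")


def normalize_pair_id(id_string: str) -> str:
    """Canonicalize a pair id to long form, e.g. ``B.d267.s0.p14`` ->
    ``BioInfer.d267.s0.p14``.  Long-form ids pass through unchanged."""
    m = _PAIR_ID_RE.match(id_string)
    if not m:
        raise ValidationError(f"malformed pair id {id_string!r}")
    prefix, d, s, p = m.groups()
    if prefix in CORPUS_PREFIXES:
        prefix = CORPUS_PREFIXES[prefix]
    elif prefix not in _NAME_TO_PREFIX:
        raise ValidationError(f"unknown corpus prefix {prefix!r} in {id_string!r}")
    return f"{prefix}.{d}.{s}.{p}"


def shorten_pair_id(id_string: str) -> str:
    """Inverse of :func:`normalize_pair_id` (long form -> one-letter prefix)."""
    m = _PAIR_ID_RE.match(id_string)
    if not m:
        raise ValidationError(f"malformed pair id {id_string!r}")
    prefix, d, s, p = m.groups()
    if prefix in _NAME_TO_PREFIX:
        prefix = _NAME_TO_PREFIX[prefix]
    elif prefix not in CORPUS_PREFIXES:
        raise ValidationError(f"unknown corpus prefix {prefix!r} in {id_string!r}")
    return f"{prefix}.{d}.{s}.{p}"


def corpus_stats(corpus: Corpus) -> dict[str, float]:
    """Pair/sentence/document counts and the positive-class ratio."""
    pairs = [p for _, p in corpus.pairs()]
    positives = sum(p.gold for p in pairs)
    n = len(pairs)
    return {
        "documents": len(corpus.documents),
        "sentences": sum(len(d.sentences) for d in corpus.documents),
        "pairs": n,
        "positives": positives,
        "negatives": n - positives,
        "positive_ratio": positives / n if n else 0.0,
    }
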