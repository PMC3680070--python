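"""Readers/writers for the unified PPI corpus XML dialect and flat tables.

The XML layout follows the standardized interchange format of the five PPI
benchmark corpora: ``corpus > document > sentence > entity/pair`` with
inclusive ``charOffset="a-b"`` entity spans and ``interaction="True|False"``
pair labels.  Optional linguistic layers are carried in self-defined
sub-elements (``tokenization``, ``dependencies``, ``bracketing``); the
original resources do not publish a parse-layer schema, so this dialect is
documented here rather than claimed to match any particular one.

Internal coordinates are 0-based half-open; inclusive offsets are converted
at this boundary in both directions.
"""

from __future__ import annotations

import os
from typing import IO

import pandas as pd
from lxml import etree

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

import networkx as nx

__all__ = [
    "parse_unified_corpus",
    "write_unified_corpus",
    "read_predictions",
    "write_predictions",
    "read_folds",
    "write_folds",
    "read_flip_list",
]


def _inclusive_to_half_open(offset: str, entity_id: str) -> tuple[int, int]:
    try:
        a, b = offset.split("-")
        start, last = int(a), int(b)
    except Exception:
        raise ValidationError(
            f"entity {entity_id}: malformed charOffset {offset!r}"
        ) from None
    if last < start:
        raise ValidationError(f"entity {entity_id}: empty charOffset {offset!r}")
    return start, last + 1


def _half_open_to_inclusive(span: tuple[int, int]) -> str:
    start, end = span
    return f"{start}-{end - 1}"


def _parse_sentence(elem: etree._Element) -> SentenceRecord:
    sent = SentenceRecord(id=elem.get("id"), text=elem.get("text", ""))
    for child in elem:
        tag = etree.QName(child).localname if isinstance(child.tag, str) else None
        if tag == "entity":
            span = _inclusive_to_half_open(child.get("charOffset"), child.get("id"))
            sent.entities.append(
                Entity(
                    id=child.get("id"),
                    char_span=span,
                    surface_text=sent.text[span[0] : span[1]],
                    entity_type=child.get("type", "protein"),
                )
            )
        elif tag == "pair":
            label = child.get("interaction")
            if label not in ("True", "False"):
                raise ValidationError(
                    f"pair {child.get('id')}: interaction must be True/False, "
                    f"got {label!r}"
                )
            sent.pairs.append(
                CandidatePair(
                    id=child.get("id"),
                    e1=child.get("e1"),
                    e2=child.get("e2"),
                    gold=(label == "True"),
                )
            )
        elif tag == "tokenization":
            sent.tokens = []
            for tok in child:
                span = _inclusive_to_half_open(tok.get("charOffset"), tok.get("id"))
                sent.tokens.append(
                    Token(
                        index=int(tok.get("index")),
                        text=tok.get("text"),
                        pos=tok.get("POS", ""),
                        char_span=span,
                    )
                )
        elif tag == "dependencies":
            g = nx.DiGraph()
            if sent.tokens is not None:
                g.add_nodes_from(t.index for t in sent.tokens)
            for dep in child:
                g.add_edge(
                    int(dep.get("t1")),
                    int(dep.get("t2")),
                    label=dep.get("type", "dep"),
                )
            sent.dep_graph = g
        elif tag == "bracketing":
            sent.syntax_tree = TreeNode.from_bracketed(child.get("tree"))
        else:
            # opaque payload: preserved verbatim on round-trip
            sent.extra_xml.append(
                etree.tostring(child, encoding="unicode").strip()
            )
    return sent


def parse_unified_corpus(xml_source: str | os.PathLike | IO[bytes]) -> Corpus:
    """Parse unified-format XML into a validated :class:`Corpus`.

    Entity offsets are converted from inclusive ``a-b`` to half-open spans;
    optional token / dependency / bracketed-tree layers are attached when
    present; document and sentence order is preserved.
    """
    try:
        tree = etree.parse(xml_source)
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "corpus":
        raise ValidationError(
            f"expected root element <corpus>, found <{root.tag}>"
        )
    corpus = Corpus(name=root.get("source", root.get("id", "corpus")))
    for doc_elem in root.iterchildren(tag=etree.Element):
        if etree.QName(doc_elem).localname != "document":
            raise ValidationError(
                f"unexpected element <{doc_elem.tag}> under <corpus>"
            )
        doc = Document(id=doc_elem.get("id"))
        for sent_elem in doc_elem.iterchildren(tag=etree.Element):
            if etree.QName(sent_elem).localname != "sentence":
                raise ValidationError(
                    f"unexpected element <{sent_elem.tag}> under <document>"
                )
            doc.sentences.append(_parse_sentence(sent_elem))
        corpus.documents.append(doc)
    corpus.validate()
    return corpus


def write_unified_corpus(
    corpus: Corpus, destination: str | os.PathLike | IO[bytes]
) -> None:
    """Emit unified XML; ``parse_unified_corpus`` maps it back to an equal corpus."""
    root = etree.Element("corpus", source=corpus.name)
    for doc in corpus.documents:
        doc_elem = etree.SubElement(root, "document", id=doc.id)
        for sent in doc.sentences:
            s = etree.SubElement(doc_elem, "sentence", id=sent.id, text=sent.text)
            for ent in sent.entities:
                etree.SubElement(
                    s,
                    "entity",
                    id=ent.id,
                    charOffset=_half_open_to_inclusive(ent.char_span),
                    text=ent.surface_text,
                    type=ent.entity_type,
                )
            for pair in sent.pairs:
                etree.SubElement(
                    s,
                    "pair",
                    id=pair.id,
                    e1=pair.e1,
                    e2=pair.e2,
                    interaction=str(pair.gold),
                )
            if sent.tokens is not None:
                tk = etree.SubElement(s, "tokenization")
                for tok in sent.tokens:
                    etree.SubElement(
                        tk,
                        "token",
                        id=f"{sent.id}.t{tok.index}",
                        index=str(tok.index),
                        text=tok.text,
                        POS=tok.pos,
                        charOffset=_half_open_to_inclusive(tok.char_span),
                    )
            if sent.dep_graph is not None:
                dp = etree.SubElement(s, "dependencies")
                for i, (u, v, data) in enumerate(
                    sorted(sent.dep_graph.edges(data=True))
                ):
                    etree.SubElement(
                        dp,
                        "dependency",
                        id=f"{sent.id}.dep{i}",
                        t1=str(u),
                        t2=str(v),
                        type=data.get("label", "dep"),
                    )
            if sent.syntax_tree is not None:
                etree.SubElement(
                    s, "bracketing", tree=sent.syntax_tree.to_bracketed()
                )
            for raw in sent.extra_xml:
                s.append(etree.fromstring(raw))
    payload = etree.tostring(
        etree.ElementTree(root),
        pretty_print=True,
        xml_declaration=True,
        encoding="UTF-8",
    )
    if hasattr(destination, "write"):
        destination.write(payload)
    else:
        with open(destination, "wb") as fh:
            fh.write(payload)


def read_predictions(
    tsv_source: str | os.PathLike | IO[str], setting: str | None = None
) -> PredictionSet:
    """Read a prediction table (TSV: pair_id, classifier_id, setting, label).

    The file must contain a single evaluation setting unless ``setting`` is
    given as a filter.  Duplicate (pair, classifier) cells and non-binary
    labels are rejected.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype=str)
    required = ["pair_id", "classifier_id", "setting", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"prediction table missing columns {missing}")
    bad_setting = set(df["setting"]) - {"CV", "CL"}
    if bad_setting:
        raise ValidationError(f"unknown setting token(s) {sorted(bad_setting)}")
    if setting is not None:
        df = df[df["setting"] == setting]
    settings = set(df["setting"])
    if len(settings) != 1:
        raise ValidationError(
            f"prediction table holds settings {sorted(settings)}; "
            "pass setting= to select one"
        )
    bad_label = set(df["label"]) - {"0", "1"}
    if bad_label:
        raise ValidationError(f"non-binary label(s) {sorted(bad_label)}")
    dup = df.duplicated(subset=["pair_id", "classifier_id"], keep=False)
    if dup.any():
        cell = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate prediction cell (pair {cell['pair_id']!r}, "
            f"classifier {cell['classifier_id']!r})"
        )
    table = {
        (row.pair_id, row.classifier_id): row.label == "1"
        for row in df.itertuples()
    }
    roster = sorted(df["classifier_id"].unique())
    return PredictionSet(setting=settings.pop(), roster=roster, table=table)


def write_predictions(
    predictions: PredictionSet, destination: str | os.PathLike | IO[str]
) -> None:
    rows = [
        {
            "pair_id": pid,
            "classifier_id": cid,
            "setting": predictions.setting,
            "label": int(label),
        }
        for (pid, cid), label in predictions.table.items()
    ]
    df = pd.DataFrame(rows, columns=["pair_id", "classifier_id", "setting", "label"])
    df = df.sort_values(["pair_id", "classifier_id"], kind="stable")
    df.to_csv(destination, sep="\t", index=False)


def read_folds(tsv_source: str | os.PathLike | IO[str], n_folds: int = 10) -> FoldAssignment:
    df = pd.read_csv(tsv_source, sep="\t", dtype={"document_id": str, "fold": int})
    missing = [c for c in ("document_id", "fold") if c not in df.columns]
    if missing:
        raise ValidationError(f"fold table missing columns {missing}")
    if df["document_id"].duplicated().any():
        dup = df[df["document_id"].duplicated()].iloc[0]["document_id"]
        raise ValidationError(f"document {dup} assigned to more than one fold")
    return FoldAssignment(
        mapping=dict(zip(df["document_id"], df["fold"])), n_folds=n_folds
    )


def write_folds(folds: FoldAssignment, destination: str | os.PathLike | IO[str]) -> None:
    df = pd.DataFrame(
        sorted(folds.mapping.items()), columns=["document_id", "fold"]
    )
    df.to_csv(destination, sep="\t", index=False)


def read_flip_list(source: str | os.PathLike | IO[str]) -> list[str]:
    """Plain-text list of pair ids (one per line; '#' comments allowed)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line.split("\t")[0])
    return out
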