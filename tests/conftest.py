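"""Shared fixtures: hand-built miniature corpora and seeded synthetic suites."""

from __future__ import annotations

import networkx as nx
import pytest

from ppidiag.model import (
    CandidatePair,
    Corpus,
    Document,
    Entity,
    PredictionSet,
    SentenceRecord,
    Token,
    TreeNode,
)
from ppidiag.simulate import (
    SimCorpusConfig,
    SimPredictionConfig,
    default_roster,
    generate_benchmark_suite,
    generate_corpus,
    generate_predictions,
)


def make_sentence(sid: str, text: str, entity_spans, pair_specs, with_layers=False):
    """Sentence from raw text, (start, end) entity spans and (i, j, gold) pairs."""
    entities = [
        Entity(id=f"{sid}.e{k}", char_span=(a, b), surface_text=text[a:b])
        for k, (a, b) in enumerate(entity_spans)
    ]
    pairs = [
        CandidatePair(
            id=f"{sid}.p{k}",
            e1=entities[i].id,
            e2=entities[j].id,
            gold=gold,
        )
        for k, (i, j, gold) in enumerate(pair_specs)
    ]
    sent = SentenceRecord(id=sid, text=text, entities=entities, pairs=pairs)
    if with_layers:
        words = text.split(" ")
        tokens, cursor = [], 0
        for i, w in enumerate(words):
            tokens.append(Token(i, w, "NN", (cursor, cursor + len(w))))
            cursor += len(w) + 1
        sent.tokens = tokens
        g = nx.DiGraph()
        g.add_nodes_from(range(len(tokens)))
        for i in range(len(tokens) - 1):
            g.add_edge(i, i + 1, label="dep")
        sent.dep_graph = g
        sent.syntax_tree = TreeNode(
            "S",
            [
                TreeNode(
                    "NP", [TreeNode("NN", token_index=i) for i in range(len(tokens))]
                )
            ],
        )
    return sent


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two documents, three sentences, five pairs, no parse layers."""
    s1 = make_sentence(
        "AIMed.d0.s0",
        "ProtA binds ProtB strongly .",
        [(0, 5), (12, 17)],
        [(0, 1, True)],
    )
    s2 = make_sentence(
        "AIMed.d0.s1",
        "ProtC and ProtD and ProtE were assayed .",
        [(0, 5), (10, 15), (20, 25)],
        [(0, 1, False), (0, 2, False), (1, 2, True)],
    )
    s3 = make_sentence(
        "AIMed.d1.s0",
        "No interaction of ProtF with ProtG .",
        [(18, 23), (29, 34)],
        [(0, 1, False)],
    )
    return Corpus(
        name="AIMed",
        documents=[
            Document(id="AIMed.d0", sentences=[s1, s2]),
            Document(id="AIMed.d1", sentences=[s3]),
        ],
    )


def constant_predictions(corpus: Corpus, roster, setting="CV", correct=True):
    """Every classifier right (or wrong) on every pair."""
    gold = corpus.gold()
    table = {
        (pid, cid): (g if correct else not g)
        for pid, g in gold.items()
        for cid in roster
    }
    return PredictionSet(setting=setting, roster=list(roster), table=table)


@pytest.fixture(scope="session")
def mid_corpus() -> Corpus:
    """~2200-pair synthetic corpus at the default study conditions."""
    return generate_corpus(SimCorpusConfig(n_documents=400, seed=7))


@pytest.fixture(scope="session")
def mid_predictions(mid_corpus):
    """CV + CL prediction matrices with latent difficulties for mid_corpus."""
    pconfig = SimPredictionConfig(seed=3)
    cv, delta = generate_predictions(
        mid_corpus, default_roster(True), pconfig, "CV", return_difficulty=True
    )
    cl = generate_predictions(mid_corpus, default_roster(False), pconfig, "CL")
    return {"CV": cv, "CL": cl, "delta": delta}


@pytest.fixture(scope="session")
def small_suite():
    """Five-corpus benchmark emulation at 5% scale (854 pairs total)."""
    return generate_benchmark_suite(11, size_factor=0.05)


@pytest.fixture(scope="session")
def mid_feature_table(mid_corpus):
    from ppidiag.features import Lexicons, feature_table

    return feature_table(mid_corpus, Lexicons())
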