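"""Tokenization, surface/parse feature extraction and aggregate statistics."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from ppidiag.difficulty import (
    combine_settings,
    compute_success_levels,
    extract_difficulty_sets,
)
from ppidiag.features import (
    Lexicons,
    aggregate_by_difficulty,
    class_dist_by_protein_count,
    dg_features,
    feature_table,
    pair_features,
    positive_rate_by_length,
    six_way_classes,
    st_features,
    surface_features,
    tokenize,
)
from ppidiag.model import (
    CandidatePair,
    Entity,
    SentenceRecord,
    Token,
    TreeNode,
    ValidationError,
)
from tests.conftest import make_sentence


class TestTokenize:
    def test_pair_entities_are_blinded(self):
        sent = make_sentence(
            "s0", "ProtA binds ProtB.", [(0, 5), (12, 17)], [(0, 1, True)]
        )
        tokens = tokenize(sent, sent.pairs[0])
        assert [t.text for t in tokens] == ["ENT1", "binds", "ENT2", "."]

    def test_entity_free_sentence_is_plain(self):
        sent = SentenceRecord(id="s", text="No entities here.")
        assert [t.text for t in tokenize(sent)] == ["No", "entities", "here", "."]

    def test_third_entity_becomes_prot(self):
        sent = make_sentence(
            "s0",
            "ProtC and ProtD bind ProtE",
            [(0, 5), (10, 15), (21, 26)],
            [(0, 1, True)],
        )
        texts = [t.text for t in tokenize(sent, sent.pairs[0])]
        assert texts == ["ENT1", "and", "ENT2", "bind", "PROT"]

    def test_token_spans_partition_non_space_characters(self):
        sent = make_sentence(
            "s0",
            "A complex (p53/MDM2) forms, binding ProtX.",
            [(36, 41)],
            [],
        )
        tokens = tokenize(sent)
        covered = set()
        for t in tokens:
            span = set(range(*t.char_span))
            assert not span & covered  # no overlap
            covered |= span
        non_space = {i for i, ch in enumerate(sent.text) if not ch.isspace()}
        assert covered == non_space

    def test_overlapping_entities_are_rejected(self):
        sent = SentenceRecord(
            id="s",
            text="ABCDEF",
            entities=[
                Entity("e0", (0, 4), "ABCD"),
                Entity("e1", (2, 6), "CDEF"),
            ],
        )
        with pytest.raises(ValidationError, match="overlap"):
            tokenize(sent)


class TestSurfaceFeatures:
    def _feats(self, text, spans, lexicons=None):
        sent = make_sentence("s0", text, spans, [(0, 1, True)])
        return surface_features(sent, sent.pairs[0], lexicons or Lexicons())

    def test_interaction_word_between_entities(self):
        f = self._feats("ProtA binds ProtB", [(0, 5), (12, 17)])
        assert f["interaction_w"] == 1.0
        assert f["interaction_s"] == 1.0
        assert f["entity_word_distance"] == 1.0
        assert f["n_proteins"] == 2.0

    def test_no_lexicon_hits_leaves_flags_clear(self):
        f = self._feats("ProtA near ProtB", [(0, 5), (11, 16)])
        clue_cols = [k for k in f if k.split("_")[0] in ("negation", "hedge", "interaction")]
        assert all(f[k] == 0.0 for k in clue_cols)

    def test_comma_must_be_strictly_between(self):
        # commas flank the pair but none sits strictly between the entities
        f = self._feats("X , ProtA ProtB ,", [(4, 9), (10, 15)])
        assert f["comma_between"] == 0.0
        g = self._feats("ProtA , ProtB", [(0, 5), (8, 13)])
        assert g["comma_between"] == 1.0

    def test_scopes_before_and_after(self):
        f = self._feats("not ProtA binds ProtB possibly", [(4, 9), (16, 21)])
        assert f["negation_b"] == 1.0
        assert f["negation_w"] == 0.0
        assert f["hedge_a"] == 1.0
        assert f["hedge_b"] == 0.0

    def test_ing_word_right_after_first_entity(self):
        f = self._feats("ProtA binding ProtB", [(0, 5), (14, 19)])
        assert f["ing_after_e1"] == 1.0
        g = self._feats("ProtA strongly binding ProtB", [(0, 5), (23, 28)])
        assert g["ing_after_e1"] == 0.0

    def test_extraction_is_pure(self):
        args = ("ProtA binds ProtB .", [(0, 5), (12, 17)])
        assert self._feats(*args) == self._feats(*args)


def _layered_sentence(labels):
    """Chain sentence ENT1 -> v -> ENT2 with given dependency edge labels."""
    sent = make_sentence(
        "s0", "ProtA binds ProtB", [(0, 5), (12, 17)], [(0, 1, True)], with_layers=True
    )
    g = nx.DiGraph()
    g.add_nodes_from(range(3))
    g.add_edge(0, 1, label=labels[0])
    g.add_edge(1, 2, label=labels[1])
    sent.dep_graph = g
    return sent


class TestDependencyFeatures:
    def test_two_label_chain_path(self):
        sent = _layered_sentence(["nsubj", "dobj"])
        f = dg_features(sent, sent.pairs[0])
        assert f["dg_path_length"] == 2.0
        assert f["dgp_nsubj_freq"] == 0.5
        assert f["dgp_dobj_freq"] == 0.5
        assert f["dgp_label_entropy"] == pytest.approx(1.0)  # two equiprobable

    def test_single_label_graph_has_zero_entropy(self):
        sent = _layered_sentence(["dep", "dep"])
        f = dg_features(sent, sent.pairs[0])
        assert f["dg_label_entropy"] == 0.0

    def test_path_matches_exhaustive_search_on_random_graph(self):
        # oracle: enumerate all simple paths of a 12-node labeled graph
        rng = np.random.default_rng(5)
        sent = make_sentence(
            "s0",
            " ".join(["w"] * 10 + ["ProtA", "ProtB"]),
            [(20, 25), (26, 31)],
            [(0, 1, False)],
            with_layers=True,
        )
        g = nx.DiGraph()
        g.add_nodes_from(range(12))
        edges = set()
        while len(edges) < 16:
            u, v = rng.integers(0, 12, 2)
            if u != v and (u, v) not in edges and (v, u) not in edges:
                edges.add((int(u), int(v)))
        for u, v in sorted(edges):
            g.add_edge(u, v, label="dep")
        sent.dep_graph = g
        ug = g.to_undirected()
        f = dg_features(sent, sent.pairs[0])
        if nx.has_path(ug, 10, 11):
            oracle = min(
                len(p) - 1 for p in nx.all_simple_paths(ug, 10, 11, cutoff=12)
            )
            assert f["dg_path_length"] == oracle
        else:
            assert "dg_path_length" not in f

    def test_disconnected_entities_have_absent_path_features(self):
        sent = _layered_sentence(["nsubj", "dobj"])
        sent.dep_graph.remove_edge(1, 2)
        f = dg_features(sent, sent.pairs[0])
        assert "dg_path_length" not in f
        assert "dg_nsubj_count" in f  # whole-graph stats survive


class TestSyntaxTreeFeatures:
    def _with_tree(self, tree):
        sent = make_sentence(
            "s0", "ProtA binds ProtB", [(0, 5), (12, 17)], [(0, 1, True)],
            with_layers=True,
        )
        sent.syntax_tree = tree
        return sent

    def test_siblings_under_one_parent_have_path_two(self):
        tree = TreeNode(
            "NP",
            [
                TreeNode("NN", token_index=0),
                TreeNode("VB", token_index=1),
                TreeNode("NN", token_index=2),
            ],
        )
        sent = self._with_tree(tree)
        f = st_features(sent, sent.pairs[0])
        assert f["st_path_length"] == 2.0

    def test_balanced_depth_three_opposite_leaves_have_path_six(self):
        sent = make_sentence(
            "s0",
            "ProtA w w w w w w ProtB",
            [(0, 5), (18, 23)],
            [(0, 1, True)],
            with_layers=True,
        )
        leaves = [TreeNode("T", token_index=i) for i in range(8)]
        lvl1 = [TreeNode("L1", leaves[i : i + 2]) for i in range(0, 8, 2)]
        lvl2 = [TreeNode("L2", lvl1[i : i + 2]) for i in range(0, 4, 2)]
        sent.syntax_tree = TreeNode("S", lvl2)
        f = st_features(sent, sent.pairs[0])
        assert f["st_path_length"] == 6.0

    def test_single_label_tree_has_zero_entropy(self):
        tree = TreeNode(
            "NP",
            [TreeNode("NN", token_index=i) for i in range(3)],
        )
        sent = self._with_tree(tree)
        f = st_features(sent, sent.pairs[0])
        assert f["st_label_entropy"] == 0.0


class TestFeatureTable:
    def test_row_count_equals_pair_count(self, mid_corpus, mid_feature_table):
        assert len(mid_feature_table) == len(mid_corpus.pair_ids())

    def test_sentence_char_length_matches_independent_count(self, mid_corpus):
        sentence, pair = next(mid_corpus.pairs())
        lex = Lexicons()
        f = pair_features(sentence, pair, lex)
        assert f["sentence_length_char"] == len(sentence.text)

    def test_removing_dependency_layer_flags_absence(self, tiny_corpus):
        ft_plain = feature_table(tiny_corpus)
        assert not any(c.startswith("dg_") for c in ft_plain.columns)
        assert ft_plain["sentence_length_word"].notna().all()

    def test_frequency_distributions_sum_to_one(self, mid_feature_table):
        for prefix in ("dgp_", "stp_"):
            cols = [
                c
                for c in mid_feature_table.columns
                if c.startswith(prefix) and c.endswith("_freq")
            ]
            sums = mid_feature_table[cols].sum(axis=1, skipna=True)
            present = mid_feature_table[cols].notna().any(axis=1)
            assert np.allclose(sums[present], 1.0, atol=1e-9)

    def test_kl_mode_adds_divergence_columns(self):
        from ppidiag.simulate import SimCorpusConfig, generate_corpus

        small = generate_corpus(SimCorpusConfig(n_documents=10, seed=2))
        ft = feature_table(small, entropy_mode="kl")
        assert "dg_label_kl" in ft.columns
        assert (ft["dg_label_kl"].dropna() >= -1e-9).all()


class TestAggregates:
    def test_identical_pairs_have_equal_class_means(self, tiny_corpus):
        ft = feature_table(tiny_corpus)
        classes = {pid: "NN" for pid in ft.index}
        out = aggregate_by_difficulty(ft, classes)
        assert list(out.index) == ["NN"]

    def test_class_conditioned_parameter_recovery(self, mid_corpus, mid_feature_table):
        # the configured per-class sentence-length means (27.6 / 37.2 words)
        # and entity distances (7.15 / 9.67) must be recoverable from the
        # extracted features at n >= 2000 pairs
        gold = mid_corpus.gold()
        ft = mid_feature_table
        pos = [p for p, g in gold.items() if g]
        neg = [p for p, g in gold.items() if not g]
        assert abs(ft.loc[pos, "sentence_length_word"].mean() - 27.6) < 1.0
        assert abs(ft.loc[neg, "sentence_length_word"].mean() - 37.2) < 1.0
        assert abs(ft.loc[pos, "entity_word_distance"].mean() - 7.15) < 0.5
        assert abs(ft.loc[neg, "entity_word_distance"].mean() - 9.67) < 0.5

    def test_six_way_aggregate_table_shape(
        self, mid_corpus, mid_predictions, mid_feature_table
    ):
        cv = extract_difficulty_sets(
            compute_success_levels(mid_corpus, mid_predictions["CV"])
        )
        cl = extract_difficulty_sets(
            compute_success_levels(mid_corpus, mid_predictions["CL"])
        )
        gold = mid_corpus.gold()
        combined = combine_settings(cv, cl, gold)
        classes = six_way_classes(combined, gold)
        out = aggregate_by_difficulty(mid_feature_table, classes)
        assert set(out.columns) == {
            "sentence_length_word",
            "entity_word_distance",
            "dg_path_length",
            "st_path_length",
        }
        assert out["sentence_length_word"].notna().all()

    def test_positive_rate_decreases_with_sentence_length(self, mid_corpus):
        table = positive_rate_by_length(mid_corpus, binning=6)
        assert table["pairs"].sum() == len(mid_corpus.pair_ids())
        rates = table["positive_rate"].dropna().to_numpy()
        rho, _ = stats.spearmanr(np.arange(len(rates)), rates)
        assert rho < 0
        assert rates[0] > rates[-1]

    def test_class_distribution_by_protein_count(self, mid_corpus):
        table = class_dist_by_protein_count(mid_corpus)
        assert (table["positives"] + table["negatives"] == table["pairs"]).all()
        assert table["pairs"].sum() == len(mid_corpus.pair_ids())
        # positive-type odds decay with protein count
        assert table["positive_rate"].iloc[0] > table["positive_rate"].iloc[-1]
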