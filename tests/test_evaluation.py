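"""Metrics, stratum bookkeeping, relabeling and majority-vote ensembles."""

import numpy as np
import pytest

from ppidiag.evaluation import (
    ConfusionCounts,
    confusion,
    ensemble_eval,
    expected_correct,
    majority_vote,
    multiclass_report_from_matrix,
    positive_rate,
    prf,
    relabel_and_rescore,
    stratum_report,
)
from ppidiag.model import PredictionSet, ValidationError
from ppidiag.refdata import (
    DIFFICULTY_PREDICTION_CONFUSION,
    ND_CV_STRATUM,
    ND_SIZE,
    PD_CV_STRATUM,
    PD_SIZE,
    load_flagged_pairs,
)


class TestConfusionAndPrf:
    def test_perfect_predictions_have_no_errors(self):
        gold = {f"p{i}": i % 2 == 0 for i in range(10)}
        c = confusion(gold, gold)
        assert (c.FP, c.FN) == (0, 0)
        assert c.total == 10

    def test_all_positive_predictor_on_negative_subset(self):
        gold = {f"p{i}": False for i in range(7)}
        pred = {pid: True for pid in gold}
        c = confusion(pred, gold)
        assert (c.TP, c.TN, c.FN, c.FP) == (0, 0, 0, 7)

    def test_counts_match_independent_recount_on_random_subset(self):
        rng = np.random.default_rng(4)
        gold = {f"p{i}": bool(rng.integers(2)) for i in range(300)}
        pred = {pid: bool(rng.integers(2)) for pid in gold}
        subset = [pid for pid in gold if rng.random() < 0.5]
        c = confusion(pred, gold, subset)
        # independent oracle: tuple-count over the subset
        tallies = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for pid in subset:
            key = ("T" if pred[pid] == gold[pid] else "F") + (
                "P" if pred[pid] else "N"
            )
            tallies[key] += 1
        assert (c.TP, c.FP, c.TN, c.FN) == tuple(
            tallies[k] for k in ("TP", "FP", "TN", "FN")
        )

    def test_published_difficult_class_row(self):
        # D row of the difficulty-prediction table: TP=148, FP=192, FN=563
        m = prf(ConfusionCounts(TP=148, FP=192, FN=563))
        assert m.rounded() == (43.5, 20.8, 28.2)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(), (0.0, 0.0, 0.0)),  # all-zero convention
            (ConfusionCounts(TP=1), (100.0, 100.0, 100.0)),
        ],
    )
    def test_degenerate_conventions(self, counts, expected):
        assert prf(counts).rounded() == expected

    def test_metrics_never_exceed_100(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = ConfusionCounts(*(int(x) for x in rng.integers(0, 40, 4)))
            m = prf(c)
            assert 0 <= m.P <= 100 and 0 <= m.R <= 100 and 0 <= m.F <= 100


class TestPositiveRateAndExpectedCorrect:
    def _pset(self, labels):
        return PredictionSet(
            "CV", ["k"], {(f"p{i}", "k"): bool(v) for i, v in enumerate(labels)}
        )

    def test_all_negative_predictor_has_rate_zero(self):
        assert positive_rate("k", self._pset([0] * 8)).r == 0.0

    def test_all_positive_predictor_has_rate_100(self):
        assert positive_rate("k", self._pset([1] * 8)).r == 100.0

    def test_empty_population_is_rejected(self):
        with pytest.raises(ValidationError):
            positive_rate("k", self._pset([1]), population=[])

    @pytest.mark.parametrize(
        "size,r,polarity,e",
        [
            (521, 18.1, "negative", 427),  # published ND bookkeeping
            (190, 46.4, "positive", 88),  # published PD bookkeeping
            (190, 0.0, "positive", 0),
            (100, 50.0, "positive", 50),
        ],
    )
    def test_expected_correct_reproduces_published_values(
        self, size, r, polarity, e
    ):
        assert expected_correct(size, r, polarity) == e

    def test_expected_correct_monotone_in_rate(self):
        pos = [expected_correct(400, r, "positive") for r in range(0, 101, 5)]
        neg = [expected_correct(400, r, "negative") for r in range(0, 101, 5)]
        assert pos == sorted(pos)
        assert neg == sorted(neg, reverse=True)


class TestStratumReport:
    def _single(self, observed, size, r, polarity):
        gold = {f"p{i}": polarity == "positive" for i in range(size)}
        want = polarity == "positive"
        pred = {
            pid: (want if i < observed else not want)
            for i, pid in enumerate(gold)
        }
        pset = PredictionSet("CV", ["k"], {(pid, "k"): v for pid, v in pred.items()})
        return stratum_report(
            "k", pset, gold, set(gold), polarity, r=r, stratum_name="S"
        )

    def test_published_nd_edit_row(self):
        rep = self._single(305, 521, 18.1, "negative")
        r = rep.rounded()
        assert (r["e"], r["obs/e"], r["obs/size"]) == (427, 0.71, 0.59)

    def test_published_pd_spt_row(self):
        rep = self._single(71, 190, 46.4, "positive")
        assert rep.rounded()["obs/e"] == 0.81

    def test_perfect_classifier_saturates_the_stratum(self):
        rep = self._single(30, 30, 50.0, "positive")
        assert rep.observed == 30
        assert rep.ratio_observed_size == 1.0

    def test_polarity_mismatch_is_rejected(self):
        gold = {"p0": True}
        pset = PredictionSet("CV", ["k"], {("p0", "k"): True})
        with pytest.raises(ValidationError, match="gold-negative"):
            stratum_report("k", pset, gold, {"p0"}, "negative", r=10.0)

    @pytest.mark.parametrize("row", ND_CV_STRATUM, ids=[r[0] for r in ND_CV_STRATUM])
    def test_published_nd_table_ratios(self, row):
        name, r, observed, e_printed, ratio_e, ratio_size = row
        rep = self._single(observed, ND_SIZE, r, "negative")
        assert rep.expected == e_printed
        rounded = rep.rounded()
        assert rounded["obs/e"] == ratio_e
        # one printed cell (ST) is internally inconsistent at two decimals
        assert abs(rounded["obs/size"] - ratio_size) <= 0.01 + 1e-9

    @pytest.mark.parametrize("row", PD_CV_STRATUM, ids=[r[0] for r in PD_CV_STRATUM])
    def test_published_pd_table_ratios(self, row):
        name, r, observed, e_printed, ratio_e, ratio_size = row
        rep = self._single(observed, PD_SIZE, r, "positive")
        # the lexical row prints e from an unrounded rate (47 vs 47.5)
        assert abs(rep.expected - e_printed) <= 1
        rounded = rep.rounded()
        assert rounded["obs/e"] == ratio_e
        assert rounded["obs/size"] == ratio_size


class TestMulticlassReport:
    def test_published_difficulty_prediction_metrics(self):
        report = multiclass_report_from_matrix(DIFFICULTY_PREDICTION_CONFUSION)
        assert report.per_class["D"].rounded() == (43.5, 20.8, 28.2)
        assert report.per_class["N"].rounded() == (92.0, 96.2, 94.1)
        assert report.per_class["E"].rounded() == (72.6, 60.0, 65.7)
        assert report.total.rounded() == (88.0, 89.4, 88.5)
        assert report.supports == {"D": 711, "N": 14640, "E": 1729}

    def test_identity_matrix_is_perfect(self):
        report = multiclass_report_from_matrix(np.eye(3, dtype=int) * 7)
        assert report.total.rounded() == (100.0, 100.0, 100.0)

    def test_row_sums_equal_supports(self):
        mat = np.array([[5, 1, 0], [2, 9, 1], [0, 3, 4]])
        report = multiclass_report_from_matrix(mat)
        assert [report.supports[c] for c in "DNE"] == [6, 12, 7]


class TestRelabelAndRescore:
    def _setup(self, n=20):
        rng = np.random.default_rng(1)
        gold = {f"p{i}": bool(rng.integers(2)) for i in range(n)}
        pred = {pid: bool(rng.integers(2)) for pid in gold}
        return pred, gold

    def test_empty_flip_list_changes_nothing(self):
        pred, gold = self._setup()
        rep = relabel_and_rescore(pred, gold, [])
        assert rep["before"] == rep["after"]

    def test_flipping_a_positive_prediction_to_true_moves_fp_to_tp(self):
        gold = {"p0": False, "p1": True}
        pred = {"p0": True, "p1": True}
        rep = relabel_and_rescore(pred, gold, ["p0"])
        assert rep["after"].TP == rep["before"].TP + 1
        assert rep["after"].FP == rep["before"].FP - 1
        assert rep["after_prf"].P >= rep["before_prf"].P

    def test_total_count_is_conserved(self):
        pred, gold = self._setup(50)
        flips = [f"p{i}" for i in range(0, 50, 7)]
        rep = relabel_and_rescore(pred, gold, flips)
        assert rep["before"].total == rep["after"].total == 50

    def test_unknown_pair_id_is_rejected(self):
        pred, gold = self._setup()
        with pytest.raises(ValidationError):
            relabel_and_rescore(pred, gold, ["nope"])

    def test_curated_flip_list_is_03_percent_of_the_benchmark(self):
        flagged = load_flagged_pairs()
        assert len(flagged) == 51
        assert sum(g for _, g in flagged) == 23  # positives flagged
        assert round(100 * len(flagged) / 17080, 1) == 0.3


class TestMajorityVote:
    def _pset(self, columns):
        table = {}
        n = len(next(iter(columns.values())))
        for cid, labels in columns.items():
            for i, v in enumerate(labels):
                table[(f"p{i}", cid)] = bool(v)
        return PredictionSet("CV", sorted(columns), table)

    def test_two_to_one_vote(self):
        pset = self._pset({"A": [1], "B": [1], "C": [0]})
        ens = majority_vote(pset, ["A", "B", "C"])
        assert ens.table[("p0", "A+B+C")] is True

    def test_unanimous_vote(self):
        pset = self._pset({"A": [0], "B": [0], "C": [0]})
        assert majority_vote(pset, ["A", "B", "C"]).table[("p0", "A+B+C")] is False

    def test_odd_committee_of_clones_is_identity(self):
        labels = [1, 0, 1, 1, 0]
        pset = self._pset({"A": labels, "B": labels, "C": labels})
        ens = majority_vote(pset, ["A", "B", "C"], ensemble_id="E")
        assert [ens.table[(f"p{i}", "E")] for i in range(5)] == [
            bool(v) for v in labels
        ]

    def test_even_tie_honors_tie_rule(self):
        pset = self._pset({"A": [1], "B": [0]})
        with pytest.raises(ValidationError, match="tie"):
            majority_vote(pset, ["A", "B"])
        assert majority_vote(pset, ["A", "B"], "positive").table[("p0", "A+B")]
        assert not majority_vote(pset, ["A", "B"], "negative").table[("p0", "A+B")]

    def test_three_independent_members_match_closed_form_error(self):
        # members err independently with p = 0.2; the majority errs with
        # probability 3 p^2 (1-p) + p^3 = 0.104
        rng = np.random.default_rng(42)
        n = 10_000
        gold = {f"p{i}": bool(rng.integers(2)) for i in range(n)}
        columns = {
            cid: [gold[f"p{i}"] ^ (rng.random() < 0.2) for i in range(n)]
            for cid in "ABC"
        }
        pset = self._pset(columns)
        ens = majority_vote(pset, ["A", "B", "C"], ensemble_id="E")
        err = np.mean(
            [ens.table[(f"p{i}", "E")] != gold[f"p{i}"] for i in range(n)]
        )
        closed_form = 3 * 0.2**2 * 0.8 + 0.2**3
        assert abs(err - closed_form) < 3 * np.sqrt(closed_form * (1 - closed_form) / n)


class TestEnsembleEval:
    def test_single_member_matches_that_member(self, tiny_corpus):
        from tests.conftest import constant_predictions

        pset = constant_predictions(tiny_corpus, ["A", "B", "C"])
        single = majority_vote(pset, ["A"], ensemble_id="A")
        df = ensemble_eval(single, [tiny_corpus])
        assert df.loc[0, "F"] == 100.0

    def test_all_correct_members_score_100_everywhere(self, small_suite):
        from ppidiag.model import PredictionSet as PS

        gold = {}
        for c in small_suite.corpora:
            gold.update(c.gold())
        table = {(pid, cid): g for pid, g in gold.items() for cid in "XYZ"}
        pset = PS("CV", ["X", "Y", "Z"], table)
        ens = majority_vote(pset, ["X", "Y", "Z"])
        df = ensemble_eval(ens, small_suite.corpora)
        assert set(df["F"]) == {100.0}

    def test_dissimilar_members_beat_the_best_member(self):
        # three members with independent 15% errors: the committee's F should
        # exceed the best single member's in most replicates
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            gold = {f"p{i}": bool(rng.random() < 0.3) for i in range(n)}
            table = {}
            for cid in "ABC":
                for pid, g in gold.items():
                    table[(pid, cid)] = g ^ (rng.random() < 0.15)
            pset = PredictionSet("CV", ["A", "B", "C"], table)
            from ppidiag.evaluation import confusion as _conf, prf as _prf

            best = max(
                _prf(_conf(pset.column(c), gold)).F for c in "ABC"
            )
            ens = majority_vote(pset, ["A", "B", "C"], ensemble_id="E")
            ens_f = _prf(_conf(ens.column("E"), gold)).F
            wins += ens_f > best
        assert wins >= 8
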