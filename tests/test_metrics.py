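import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protlabel.alphabets import AMINO_ACIDS
from protlabel.exceptions import ConfigError, DataError
from protlabel.metrics import (
    BLOSUM62,
    cc_percent_correct,
    evaluate_task,
    extract_segments,
    knn_overlap,
    per_class_prf,
    q_score,
    sp_protein_accuracy,
    tm_segment_metrics,
    z_test,
)
from protlabel.network import EmbeddingTable


class TestQScore:
    @pytest.mark.parametrize(
        "pred, true, expected",
        [
            ("HHEC", "HHEC", 1.0),
            ("HHEC", "HHCC", 0.75),
            ("HHHC", "H.EC", 2 / 3),  # unlabeled position excluded
        ],
    )
    def test_hand_counts(self, pred, true, expected):
        assert q_score(pred, true) == pytest.approx(expected)

    def test_no_labeled_positions_is_error(self):
        with pytest.raises(DataError):
            q_score("HH", "..")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equals_support_weighted_mean_recall(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = "HEC"
        n = int(rng.integers(5, 60))
        true = "".join(rng.choice(list(alphabet), size=n))
        pred = "".join(rng.choice(list(alphabet), size=n))
        total = 0.0
        for cls in alphabet:
            support = true.count(cls)
            _, recall, _ = per_class_prf(pred, true, cls)
            total += support * recall
        assert q_score(pred, true) == pytest.approx(total / n)


class TestPerClassPrf:
    def test_perfect_prediction(self):
        assert per_class_prf("HEHC", "HEHC", "H") == (1.0, 1.0, 1.0)

    def test_hand_count(self):
        precision, recall, f1 = per_class_prf("HHHH", "HHEE", "H")
        assert (precision, recall) == (0.5, 1.0)
        assert f1 == pytest.approx(2 / 3)

    def test_absent_class_flagged_zero(self):
        assert per_class_prf("HH", "HH", "E") == (0.0, 0.0, 0.0)

    def test_class_outside_alphabet_rejected(self):
        with pytest.raises(DataError):
            per_class_prf("HH", "HH", "Z", alphabet=("H", "E", "C"))


class TestExtractSegments:
    def test_maximal_runs(self):
        spans = extract_segments("MMMOO")
        assert [(s.label, s.start, s.end) for s in spans] == [("M", 1, 3), ("O", 4, 5)]

    def test_unlabeled_breaks_runs(self):
        spans = extract_segments("M.M")
        assert [(s.label, s.start, s.end) for s in spans] == [("M", 1, 1), ("M", 3, 3)]

    def test_empty_labeling(self):
        assert extract_segments("") == []


def brute_force_match_count(pred, true):
    """Oracle: maximum one-to-one matching by trying all assignments."""
    from protlabel.metrics import _min_overlap

    ps = extract_segments(pred)
    ts = extract_segments(true)
    admissible = [
        (i, j)
        for i, p in enumerate(ps)
        for j, t in enumerate(ts)
        if p.label == t.label and p.overlap(t) >= _min_overlap(p.label)
    ]
    best = 0
    for r in range(min(len(ps), len(ts)), 0, -1):
        for combo in itertools.combinations(admissible, r):
            if len({i for i, _ in combo}) == r and len({j for _, j in combo}) == r:
                best = r
                break
        if best:
            break
    return best, len(ts), len(ps)


class TestTmSegmentMetrics:
    def _labeling(self, length, spans):
        out = ["O"] * length
        for label, start, end in spans:
            out[start - 1:end] = label * (end - start + 1)
        return "".join(out)

    def test_five_residue_overlap_rule(self):
        true = self._labeling(30, [("M", 10, 25)])
        pred5 = self._labeling(30, [("M", 8, 14)])   # overlap 5 -> matched
        pred4 = self._labeling(30, [("M", 10, 13)])  # overlap 4 -> unmatched
        sens5, _ = tm_segment_metrics(pred5, true)
        sens4, _ = tm_segment_metrics(pred4, true)
        m_true5 = [s for s in extract_segments(true) if s.label == "M"]
        assert sens5 > sens4
        # the membrane segment itself: matched under pred5, not under pred4
        assert tm_segment_metrics("M" * 10 + "O" * 5, "M" * 14 + "O")[0] == 1.0

    def test_single_residue_rule_for_loops(self):
        true = "O" * 9 + "M" * 21
        pred = "M" * 8 + "O" + "M" * 21  # O-segment overlap of exactly 1
        sens, prec = tm_segment_metrics(pred, true)
        assert sens == 1.0  # both true segments matched

    def test_symmetry_swaps_sensitivity_and_precision(self, rng):
        for _ in range(30):
            a = "".join(rng.choice(list("MOIS"), size=25))
            b = "".join(rng.choice(list("MOIS"), size=25))
            assert tm_segment_metrics(a, b) == tm_segment_metrics(b, a)[::-1]

    def test_matches_brute_force_matching_oracle(self, rng):
        for _ in range(40):
            a = "".join(rng.choice(list("MO"), size=20))
            b = "".join(rng.choice(list("MO"), size=20))
            sens, prec = tm_segment_metrics(a, b)
            best, n_true, n_pred = brute_force_match_count(a, b)
            assert sens == pytest.approx(best / n_true)
            assert prec == pytest.approx(best / n_pred)


class TestSpProteinAccuracy:
    def test_any_s_counts_as_signal_peptide(self):
        assert sp_protein_accuracy(["NNSNN"], ["SSNNN"]) == 1.0

    def test_absent_on_both_sides_is_correct(self):
        assert sp_protein_accuracy(["NNNN"], ["NNNN"]) == 1.0

    def test_hand_count_two_of_three(self):
        preds = ["SNN", "NNN", "NNN"]
        trues = ["SNN", "SNN", "NNN"]
        assert sp_protein_accuracy(preds, trues) == pytest.approx(2 / 3)


class TestCcPercentCorrect:
    def test_any_heptad_letter_matches_any_other(self):
        assert cc_percent_correct("a", "c") == 1.0

    def test_heptad_never_matches_n(self):
        assert cc_percent_correct("a", "N") == 0.0

    def test_positionwise_hand_count(self):
        # a/c, b/d, c/e and N/N match; N/a does not
        assert cc_percent_correct("abcNN", "cdeNa") == pytest.approx(4 / 5)


class TestZTest:
    def test_equal_accuracies_give_p_one(self):
        assert z_test(0.8, 0.8, 500) == pytest.approx(1.0)

    def test_large_n_significant(self):
        # pooled two-proportion Z = 5.164 -> two-sided p = 2.418e-7
        # (cross-checked against statsmodels proportions_ztest)
        assert z_test(0.80, 0.70, 1000) == pytest.approx(2.4175638811e-07, rel=1e-6)

    def test_small_n_not_significant(self):
        assert z_test(0.8, 0.7, 10) > 0.05

    def test_degenerate_pooled_rate(self):
        assert z_test(1.0, 1.0, 100) == 1.0


class TestKnnOverlap:
    def test_consistent_neighborhoods_give_perfect_overlap(self, rng):
        # score matrix = negative squared distances of the embedding itself:
        # top-k by score and nearest-k by distance pick identical sets
        emb = EmbeddingTable.random(5, rng)
        cols = [emb.symbols.index(a) for a in AMINO_ACIDS]
        V = emb.weights[:, cols].T
        sq = ((V[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
        assert knn_overlap(emb, -sq, 3) == 1.0

    def test_isometry_invariance(self, rng):
        emb = EmbeddingTable.random(6, rng)
        rate = knn_overlap(emb, BLOSUM62, 3)
        # random rotation + translation preserves all pairwise distances
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        moved = EmbeddingTable(emb.symbols, 6, q @ emb.weights + 0.37)
        assert knn_overlap(moved, BLOSUM62, 3) == pytest.approx(rate)

    def test_random_embedding_near_chance(self):
        rates = [
            knn_overlap(
                EmbeddingTable.random(8, np.random.default_rng(s)), BLOSUM62, 3
            )
            for s in range(30)
        ]
        chance = 3 / 19  # k neighbors drawn blind from the 19 others
        assert abs(np.mean(rates) - chance) < 0.05

    def test_k_bounds(self, rng):
        emb = EmbeddingTable.random(4, rng)
        with pytest.raises(ConfigError):
            knn_overlap(emb, BLOSUM62, 20)
        with pytest.raises(ConfigError):
            knn_overlap(emb, BLOSUM62, 0)


class TestEvaluateTask:
    def test_perfect_prediction_report(self):
        report = evaluate_task([("HEC", "HEC")], ("H", "E", "C"))
        assert report.q_score == 1.0
        assert all(v["f1"] == 1.0 for v in report.per_class.values())
        support = sum(v["support"] for v in report.per_class.values())
        assert support == 3

    def test_protein_order_invariance(self, rng):
        pairs = [("HHE", "HEE"), ("CCC", "CHC"), ("EEH", "EEH")]
        fwd = evaluate_task(pairs, ("H", "E", "C"))
        rev = evaluate_task(pairs[::-1], ("H", "E", "C"))
        assert fwd.q_score == rev.q_score
        assert fwd.per_class == rev.per_class

    def test_tsv_rendering_carries_all_fields(self):
        report = evaluate_task([("SNN", "SON")], ("S", "O", "N"), "sp")
        tsv = report.to_tsv()
        assert tsv.startswith("q_score\t")
        assert "protein_accuracy" in tsv
        assert tsv.count("\n") == 1 + 3 * 5 + 1  # q + 3 classes x 5 stats + extra

    def test_task_specific_extras(self):
        sp = evaluate_task([("SNN", "SNN")], ("S", "O", "N"), "sp")
        assert sp.extras["protein_accuracy"] == 1.0
        tm = evaluate_task([("M" * 10 + "O" * 5, "M" * 14 + "O")], tuple("SOIMRN"), "tm")
        assert "segment_sensitivity_pooled" in tm.extras
        cc = evaluate_task([("abcNN", "cdeNa")], tuple("Nabcdefg"), "cc")
        assert cc.extras["percent_correct"] == pytest.approx(4 / 5)
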