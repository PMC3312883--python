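import itertools

import numpy as np
import pytest

from protlabel.decode import (
    NEG_INF,
    TransitionModel,
    estimate_transitions,
    path_score,
    predict_labels,
    viterbi_decode,
)
from protlabel.exceptions import DataError
from protlabel.io_formats import LabelSequence


def brute_force_best_path(posteriors, tm):
    """Exhaustive search over all K^L label paths (oracle)."""
    L, K = posteriors.shape
    best, best_score = None, -np.inf
    for path in itertools.product(range(K), repeat=L):
        labels = "".join(tm.alphabet[i] for i in path)
        s = path_score(labels, posteriors, tm)
        if s > best_score:  # strict: first (lexicographically lowest) wins ties
            best, best_score = labels, s
    return best, best_score


def random_instance(rng, max_L=8, max_K=4, forbid_prob=0.2):
    L = int(rng.integers(1, max_L + 1))
    K = int(rng.integers(2, max_K + 1))
    post = rng.random((L, K)) + 1e-3
    post /= post.sum(axis=1, keepdims=True)
    trans = rng.random((K, K))
    trans[rng.random((K, K)) < forbid_prob] = 0.0
    trans += (trans.sum(axis=1, keepdims=True) == 0)  # keep rows stochastic
    trans /= trans.sum(axis=1, keepdims=True)
    init = rng.random(K)
    init /= init.sum()
    with np.errstate(divide="ignore"):
        tm = TransitionModel(
            tuple("abcd"[:K]),
            np.where(init > 0, np.log(init), NEG_INF),
            np.where(trans > 0, np.log(trans), NEG_INF),
        )
    return post, tm


class TestEstimateTransitions:
    def test_hand_counted_bigrams_without_pseudocount(self):
        tm = estimate_transitions(["aab"], ("a", "b"), pseudocount=0)
        assert np.exp(tm.log_trans[0]) == pytest.approx([0.5, 0.5])
        # 'b' row has no outgoing data: uniform
        assert np.exp(tm.log_trans[1]) == pytest.approx([0.5, 0.5])
        assert np.exp(tm.log_init) == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_pseudocount_only_gives_uniform(self):
        tm = estimate_transitions(["a"], ("a", "b", "c"), pseudocount=1)
        assert np.exp(tm.log_trans).sum(axis=1) == pytest.approx([1, 1, 1])
        assert np.exp(tm.log_trans[1]) == pytest.approx([1 / 3] * 3)

    def test_unlabeled_positions_break_bigrams(self):
        with_dot = estimate_transitions(["a.b"], ("a", "b"), pseudocount=0)
        # no a->b bigram was observed across the gap
        assert np.exp(with_dot.log_trans[0]) == pytest.approx([0.5, 0.5])

    def test_heptad_grammar_recovered(self):
        from protlabel.synthetic import generate_heptad_task

        task = generate_heptad_task(n_proteins=20, seed=1)
        tm = estimate_transitions(
            [d.labels for d in task.dataset], task.alphabet, pseudocount=0
        )
        a, b = task.alphabet.index("a"), task.alphabet.index("b")
        trans = np.exp(tm.log_trans)
        assert trans[a, b] > 0.99
        assert trans[a, a] < 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            estimate_transitions([], ("a", "b"))


class TestViterbi:
    def test_uniform_transitions_reduce_to_argmax(self, rng):
        post = rng.random((10, 3))
        post /= post.sum(axis=1, keepdims=True)
        tm = TransitionModel.uniform(("a", "b", "c"))
        decoded = viterbi_decode(post, tm)
        argmax = "".join("abc"[i] for i in post.argmax(axis=1))
        assert decoded.labels == argmax

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            post, tm = random_instance(rng)
            decoded = viterbi_decode(post, tm).labels
            oracle, oracle_score = brute_force_best_path(post, tm)
            assert decoded == oracle
            assert path_score(decoded, post, tm) == pytest.approx(oracle_score)

    def test_heptad_phase_repair(self):
        # posteriors favor 'aacdefg' but strict heptad transitions force the
        # register 'abcdefg'; verified against the exhaustive oracle
        alphabet = tuple("abcdefg")
        K = 7
        trans = np.full((K, K), 0.0)
        for i in range(K):
            trans[i, (i + 1) % K] = 1.0
        with np.errstate(divide="ignore"):
            tm = TransitionModel(
                alphabet, np.log(np.full(K, 1 / K)),
                np.where(trans > 0, np.log(trans), NEG_INF),
            )
        post = np.full((7, K), 0.01)
        for t, c in enumerate("aacdefg"):
            post[t, alphabet.index(c)] = 0.9
        post /= post.sum(axis=1, keepdims=True)
        decoded = viterbi_decode(post, tm)
        assert decoded.labels == "abcdefg"
        oracle, _ = brute_force_best_path(post, tm)
        assert decoded.labels == oracle

    def test_monotone_invariance_per_position_scaling(self, rng):
        post, tm = random_instance(rng, forbid_prob=0.0)
        decoded = viterbi_decode(post, tm).labels
        scaled = post.copy()
        scaled[0] *= 7.3  # constant added to all log scores at one position
        assert viterbi_decode(scaled, tm).labels == decoded

    def test_decoded_score_at_least_argmax_path(self, rng):
        for _ in range(20):
            post, tm = random_instance(rng)
            decoded = viterbi_decode(post, tm).labels
            greedy = "".join(tm.alphabet[i] for i in post.argmax(axis=1))
            assert path_score(decoded, post, tm) >= path_score(greedy, post, tm)

    def test_all_paths_forbidden_falls_back_to_argmax(self):
        tm = TransitionModel(("a", "b"), np.array([NEG_INF, NEG_INF]),
                             np.full((2, 2), NEG_INF))
        post = np.array([[0.9, 0.1], [0.2, 0.8]])
        decoded = viterbi_decode(post, tm)
        assert decoded.labels == "ab"


class TestPredictLabels:
    def test_single_residue_protein(self, small_fixture_tasks, fast_hyper):
        from protlabel.io_formats import ProteinRecord
        from protlabel.model import ProteinLabelingModel

        task = small_fixture_tasks[0]
        res = ProteinLabelingModel(task, fast_hyper).fit()
        rec = ProteinRecord("one", "A")
        labels, post = res.predict(rec, None, task.name)
        assert post.shape == (1, task.n_classes)
        assert labels.labels == task.alphabet[post[0].argmax()]

    def test_viterbi_with_uniform_transitions_is_argmax(
        self, small_fixture_tasks, fast_hyper
    ):
        task = small_fixture_tasks[0]
        item = task.dataset[0]
        from protlabel.model import ProteinLabelingModel

        res = ProteinLabelingModel(task, fast_hyper).fit()
        res.transitions[task.name] = TransitionModel.uniform(task.alphabet)
        plain, _ = res.predict(item.record, item.profile, task.name, viterbi=False)
        vit, _ = res.predict(item.record, item.profile, task.name, viterbi=True)
        assert plain.labels == vit.labels

    def test_binary_task_uses_half_cutoff(self, rng):
        # posterior 0.6/0.4 labels the first class: argmax == 0.5 cutoff
        post = np.array([[0.6, 0.4], [0.4, 0.6]])
        tm = TransitionModel.uniform(("N", "B"))
        assert viterbi_decode(post, tm).labels == "NB"
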