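"""Transition estimation, top-k Viterbi smoothing, bout statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import electosleep as es
from electosleep.hypnogram import find_bouts

W, N, R, U = es.WAKE, es.NREM, es.REM, es.UNKNOWN


def _enumerate_paths(probs, tm, k):
    """Brute-force oracle: score all 3^T sequences, return top k."""
    T = len(probs)
    pi = tm.stationary()
    scored = []
    with np.errstate(divide="ignore"):
        lp, lt, lpi = np.log(probs), np.log(tm.probs), np.log(pi)
    for seq in itertools.product(range(3), repeat=T):
        s = lpi[seq[0]] + sum(lp[t, seq[t]] for t in range(T))
        s += sum(lt[seq[t], seq[t + 1]] for t in range(T - 1))
        scored.append((s, seq))
    scored.sort(key=lambda x: (-x[0], x[1]))
    return scored[:k]


class TestEstimateTransitions:
    def test_hand_counted_example(self):
        tm = es.estimate_transitions(np.array([W, W, N, N, R]), smoothing=0.0)
        assert np.allclose(tm.probs[W], [0.5, 0.5, 0.0])
        assert np.allclose(tm.probs[N], [0.0, 0.5, 0.5])

    def test_constant_sequence_identity_row(self):
        tm = es.estimate_transitions(np.full(10, N), smoothing=0.0)
        assert np.allclose(tm.probs[N], [0.0, 1.0, 0.0])

    def test_add_one_smoothing_strictly_positive(self):
        tm = es.estimate_transitions(np.array([W, W, W, W]), smoothing=1.0)
        assert (tm.probs > 0).all()
        assert np.allclose(tm.probs.sum(axis=1), 1.0)

    def test_unknown_breaks_adjacency(self):
        # W,U,N contributes no W->N transition
        tm = es.estimate_transitions(np.array([W, U, N, N]), smoothing=0.0)
        assert tm.probs[W, N] == 0.0

    def test_multiple_sequences_pooled(self):
        tm = es.estimate_transitions(
            [np.array([W, N]), np.array([W, R])], smoothing=0.0
        )
        assert np.allclose(tm.probs[W], [0.0, 0.5, 0.5])

    def test_no_pairs_error(self):
        with pytest.raises(ValueError, match="consecutive"):
            es.estimate_transitions(np.array([W, U, N]), smoothing=0.0)


class TestViterbiTopK:
    def test_uniform_transitions_top1_is_argmax(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=30)
        tm = es.TransitionMatrix(np.full((3, 3), 1 / 3))
        paths, _ = es.viterbi_topk(p, tm, k=1)
        assert np.array_equal(paths[0], p.argmax(axis=1))

    def test_matches_enumeration_on_fixed_instance(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(3), size=4)
        tm = es.TransitionMatrix(rng.dirichlet(2 * np.ones(3), size=3))
        paths, scores = es.viterbi_topk(p, tm, k=3)
        oracle = _enumerate_paths(p, tm, 3)
        assert np.allclose(scores, [s for s, _ in oracle])
        assert tuple(paths[0]) == oracle[0][1]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 8))
    def test_top1_matches_exhaustive_optimum(self, seed, T):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3), size=T)
        tm = es.TransitionMatrix(rng.dirichlet(2 * np.ones(3), size=3))
        paths, scores = es.viterbi_topk(p, tm, k=4)
        oracle = _enumerate_paths(p, tm, 4)
        assert np.isclose(scores[0], oracle[0][0])
        assert np.allclose(scores, [s for s, _ in oracle], atol=1e-9)

    def test_scores_nonincreasing(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(3), size=20)
        tm = es.TransitionMatrix(rng.dirichlet(np.ones(3) * 3, size=3))
        _, scores = es.viterbi_topk(p, tm, k=10)
        assert (np.diff(scores) <= 1e-12).all()

    def test_k1_equals_standard_viterbi(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(3), size=50)
        tm = es.TransitionMatrix(rng.dirichlet(np.ones(3) * 2, size=3))
        p1, s1 = es.viterbi_topk(p, tm, k=1)
        p10, s10 = es.viterbi_topk(p, tm, k=10)
        assert np.array_equal(p1[0], p10[0])
        assert np.isclose(s1[0], s10[0])

    def test_zero_probability_deadlock_error(self):
        p = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        tm = es.TransitionMatrix(np.eye(3))  # wake can never become NREM
        with pytest.raises(ValueError, match="window 1"):
            es.viterbi_topk(p, tm, k=2)

    def test_k_capped_by_number_of_sequences(self):
        p = np.full((2, 3), 1 / 3)
        tm = es.TransitionMatrix(np.full((3, 3), 1 / 3))
        paths, _ = es.viterbi_topk(p, tm, k=50)
        assert len(paths) == 9  # 3^2 sequences exist


class TestSmooth:
    def _diagonal_tm(self, stay=0.98):
        off = (1 - stay) / 2
        return es.TransitionMatrix(
            np.full((3, 3), off) + np.eye(3) * (stay - off)
        )

    def test_isolated_blip_removed(self):
        tm = self._diagonal_tm()
        probs = np.full((9, 3), 0.1)
        probs[:, N] = 0.8
        probs[4] = [0.15, 0.35, 0.5]  # weak REM blip inside the NREM run
        hyp = es.Hypnogram(labels=probs.argmax(axis=1), probabilities=probs)
        sm = es.smooth(hyp, tm, k=10)
        assert hyp.labels[4] == R
        assert (sm.smoothed == N).all()
        # agree with the enumeration oracle's best path
        oracle = _enumerate_paths(probs, tm, 1)
        assert tuple(sm.smoothed) == oracle[0][1]

    def test_onehot_consistent_probs_unchanged(self):
        tm = self._diagonal_tm(0.9)
        labels = np.array([W, W, W, N, N, N, R, R])
        probs = np.eye(3)[labels] * 0.99994 + 2e-5
        hyp = es.Hypnogram(labels=labels, probabilities=probs)
        sm = es.smooth(hyp, tm, k=5)
        assert np.array_equal(sm.smoothed, labels)

    def test_confidence_bounds(self):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet(np.ones(3), size=40)
        hyp = es.Hypnogram(labels=probs.argmax(axis=1), probabilities=probs)
        sm = es.smooth(hyp, self._diagonal_tm(0.8), k=10)
        assert (sm.confidence >= 1 / 10 - 1e-12).all()
        assert (sm.confidence <= 1.0).all()

    def test_smoothed_score_no_worse_than_argmax_sequence(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(3), size=30)
        tm = self._diagonal_tm(0.9)
        hyp = es.Hypnogram(labels=probs.argmax(axis=1), probabilities=probs)
        sm = es.smooth(hyp, tm, k=3)

        def score(seq):
            s = np.log(tm.stationary()[seq[0]])
            s += sum(np.log(probs[t, seq[t]]) for t in range(len(seq)))
            s += sum(np.log(tm.probs[seq[t], seq[t + 1]]) for t in range(len(seq) - 1))
            return s

        assert score(sm.smoothed) >= score(probs.argmax(axis=1)) - 1e-12

    def test_unknown_gap_bridged_uniformly(self):
        labels = np.array([N, U, N])
        probs = np.array([[0.05, 0.9, 0.05], [np.nan] * 3, [0.05, 0.9, 0.05]])
        hyp = es.Hypnogram(labels=labels, probabilities=probs)
        sm = es.smooth(hyp, self._diagonal_tm(), k=3)
        assert sm.smoothed[1] == N

    def test_requires_probabilities(self):
        hyp = es.Hypnogram(labels=np.array([W, N]))
        with pytest.raises(ValueError, match="probabilities"):
            es.smooth(hyp, self._diagonal_tm())


class TestArchitectureStats:
    def test_hand_decomposed_example(self):
        hyp = es.Hypnogram(labels=np.array([W, W, W, N, N, R]))
        stats = es.architecture_stats(hyp)
        assert stats["wake"]["n_bouts"] == 1
        assert stats["nrem"]["n_bouts"] == 1
        assert stats["rem"]["n_bouts"] == 1
        assert np.isclose(stats["wake"]["percent_time"], 50.0)
        assert np.isclose(stats["nrem"]["percent_time"], 100 / 3)
        assert np.isclose(stats["rem"]["percent_time"], 100 / 6)
        assert stats["wake"]["mean_bout_s"] == 6.0
        assert stats["rem"]["mean_bout_s"] == 2.0

    def test_bout_lengths_sum_to_state_window_counts(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 3, 10_000)
        bouts = find_bouts(labels)
        for s in es.STATES:
            total = sum(b.length for b in bouts if b.state == s)
            assert total == (labels == s).sum()
        assert sum(b.length for b in bouts) == len(labels)

    def test_all_unknown_zero_stats_with_warning(self):
        hyp = es.Hypnogram(labels=np.full(5, U))
        with pytest.warns(UserWarning, match="no labeled"):
            stats = es.architecture_stats(hyp)
        assert all(stats[nm]["n_bouts"] == 0 for nm in ("wake", "nrem", "rem"))

    def test_invariant_to_unknown_padding(self):
        core = np.array([W, W, N, R, R, R])
        padded = np.concatenate([[U, U], core, [U]])
        s1 = es.architecture_stats(es.Hypnogram(labels=core))
        s2 = es.architecture_stats(es.Hypnogram(labels=padded))
        assert s1 == s2

    def test_interval_restriction(self):
        hyp = es.Hypnogram(labels=np.array([W, W, N, N, R, R]))
        stats = es.architecture_stats(hyp, interval=(4.0, 12.0))
        assert stats["wake"]["n_bouts"] == 0
        assert stats["nrem"]["n_bouts"] == 1
        assert stats["rem"]["n_bouts"] == 1

    def test_prefers_smoothed_track(self):
        hyp = es.Hypnogram(
            labels=np.array([W, R, W]), smoothed=np.array([W, W, W])
        )
        stats = es.architecture_stats(hyp)
        assert stats["wake"]["n_bouts"] == 1
        assert stats["rem"]["n_bouts"] == 0


class TestRoundTrips:
    def test_transition_roundtrip_with_generator(self):
        spec = es.SyntheticCohortSpec(n_mice=1, seed=0)
        gt = es.sample_state_sequence(spec, 50_000, seed=17)
        tm = es.estimate_transitions(gt.state_sequence, smoothing=0.0)
        assert np.abs(tm.probs - spec.transition_matrix).max() < 0.02

    def test_hypnogram_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        probs = rng.dirichlet(np.ones(3), size=20)
        labels = probs.argmax(axis=1)
        labels[3] = U
        probs[3] = np.nan
        hyp = es.Hypnogram(labels=labels, probabilities=probs)
        tm = es.TransitionMatrix(np.full((3, 3), 1 / 3))
        sm = es.smooth(hyp, tm, k=5)
        sm.to_csv(tmp_path / "h.csv")
        back = es.Hypnogram.from_csv(tmp_path / "h.csv")
        assert np.array_equal(back.labels, sm.labels)
        assert np.array_equal(back.smoothed, sm.smoothed)
        assert np.allclose(back.confidence, sm.confidence)
        ok = ~np.isnan(probs).any(axis=1)
        assert np.allclose(back.probabilities[ok], probs[ok])
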