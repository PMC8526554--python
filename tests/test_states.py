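"""Clustering, model selection, state medians, temporal statistics."""

import numpy as np
import pytest

from dynstates.dynamic_fc import WindowSpec, WindowedSeries
from dynstates.errors import ComputationError, InputError
from dynstates.states import (bic_for_k, cluster_states, silhouette_mean,
                              state_medians, temporal_stats)

SPEC = WindowSpec(22, 3.0, 1, 2.7)


def make_windowed(subject_id, matrices):
    return WindowedSeries(subject_id, [np.asarray(m, float) for m in matrices],
                          np.arange(len(matrices)), 0.1, SPEC)


def two_regime_windows(rng, n_per_state=40, r=6, spread=0.02):
    """Windows drawn around two well-separated connectivity patterns."""
    hi = np.full((r, r), 0.6)
    lo = np.full((r, r), 0.05)
    for m in (hi, lo):
        np.fill_diagonal(m, 0)
    mats, labels = [], []
    for state, base in ((1, hi), (2, lo)):
        for _ in range(n_per_state):
            noise = rng.normal(0, spread, (r, r))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            mats.append(np.clip(base + noise, -0.99, 0.99))
            labels.append(state)
    return mats, np.array(labels)


class TestClusterStates:
    def test_planted_two_state_recovery(self, rng):
        mats, truth = two_regime_windows(rng)
        order = rng.permutation(len(mats))
        ws = make_windowed("s1", [mats[i] for i in order])
        d = cluster_states([ws], range(2, 6), reps=10, seed=0)
        assert d.k == 2
        assert np.array_equal(d.labels["s1"], truth[order])

    def test_state1_is_most_connected(self, rng):
        mats, _ = two_regime_windows(rng)
        d = cluster_states([make_windowed("s", mats)], [2], reps=5, seed=1)
        m1 = np.tanh(d.centroids[0]).mean()
        m2 = np.tanh(d.centroids[1]).mean()
        assert m1 > m2

    def test_identical_windows_rejected(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 0)
        with pytest.raises(InputError, match="distinct"):
            cluster_states([make_windowed("s", [m] * 30)], [2], reps=3, seed=0)

    def test_pooled_order_permutation_equivariance(self, rng):
        mats, _ = two_regime_windows(rng, n_per_state=25)
        d1 = cluster_states([make_windowed("a", mats[:25]),
                             make_windowed("b", mats[25:])],
                            [2], reps=10, seed=3)
        # swap which subject owns which windows: labels must follow windows
        d2 = cluster_states([make_windowed("a", mats[25:]),
                             make_windowed("b", mats[:25])],
                            [2], reps=10, seed=3)
        assert np.array_equal(d1.labels["a"], d2.labels["b"])
        assert np.array_equal(d1.labels["b"], d2.labels["a"])

    def test_deterministic_given_seed(self, rng):
        mats, _ = two_regime_windows(rng, n_per_state=20)
        ws = [make_windowed("s", mats)]
        d1 = cluster_states(ws, range(2, 5), reps=5, seed=9)
        d2 = cluster_states(ws, range(2, 5), reps=5, seed=9)
        assert d1.k == d2.k
        assert np.array_equal(d1.labels["s"], d2.labels["s"])
        assert d1.silhouette_by_k == d2.silhouette_by_k


class TestSilhouette:
    def test_hand_evaluated_two_blobs(self):
        feats = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        # a = 0.1 for every point; b = mean distance to the other blob
        a = 0.1
        svals = []
        for i, x in enumerate(feats[:, 0]):
            other = feats[labels != labels[i], 0]
            b = np.mean(np.abs(other - x))
            svals.append((b - a) / max(a, b))
        assert silhouette_mean(feats, labels) == pytest.approx(
            np.mean(svals), abs=0.005)
        assert silhouette_mean(feats, labels) > 0.98

    def test_swapped_labels_negative(self):
        feats = np.array([[0.0], [0.1], [10.0], [10.1]])
        assert silhouette_mean(feats, np.array([1, 0, 0, 1])) < 0

    def test_single_cluster_rejected(self):
        with pytest.raises(InputError):
            silhouette_mean(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestBic:
    def test_separation_beats_single_cluster(self, rng):
        a = rng.normal(0, 0.1, (30, 3))
        b = rng.normal(8, 0.1, (30, 3))
        feats = np.vstack([a, b])
        labels2 = np.array([0] * 30 + [1] * 30)
        cents2 = np.array([a.mean(0), b.mean(0)])
        bic2 = bic_for_k(feats, labels2, cents2)
        bic1 = bic_for_k(feats, np.zeros(60, dtype=int),
                         feats.mean(0, keepdims=True))
        assert bic2 < bic1

    def test_duplication_preserves_argmin(self, rng):
        feats = np.vstack([rng.normal(0, 0.5, (20, 2)),
                           rng.normal(5, 0.5, (20, 2))])
        labels = np.array([0] * 20 + [1] * 20)
        cents = np.array([feats[:20].mean(0), feats[20:].mean(0)])

        def argmin_k(f, l, c):
            one = bic_for_k(f, np.zeros(len(f), dtype=int),
                            f.mean(0, keepdims=True))
            two = bic_for_k(f, l, c)
            return 1 if one < two else 2

        doubled = np.vstack([feats, feats])
        dlabels = np.concatenate([labels, labels])
        assert argmin_k(feats, labels, cents) == argmin_k(doubled, dlabels, cents)

    def test_zero_dispersion_rejected(self):
        feats = np.zeros((5, 2))
        with pytest.raises(ComputationError):
            bic_for_k(feats, np.zeros(5, dtype=int), np.zeros((1, 2)))


class TestStateMedians:
    def test_identical_windows(self, rng):
        m = rng.uniform(-0.5, 0.5, (4, 4))
        m = (m + m.T) / 2
        meds = state_medians([m, m, m], np.array([1, 1, 1]), 2)
        assert np.array_equal(meds[0], m)
        assert meds[1] is None

    def test_odd_count_median(self):
        mats = []
        for v in (0.1, 0.5, 0.9):
            m = np.zeros((3, 3))
            m[0, 1] = m[1, 0] = v
            mats.append(m)
        meds = state_medians(mats, np.array([2, 2, 2]), 2)
        assert meds[1][0, 1] == pytest.approx(0.5)


class TestTemporalStats:
    def test_run_length_enumeration(self):
        t = temporal_stats(np.array([1, 1, 2, 2, 2, 1]), SPEC, 2)
        assert t.n_transitions == 2
        assert t.fraction_time[0] == pytest.approx(0.5)
        assert t.mean_dwell_minutes[0] == pytest.approx(1.5 * 2.7 / 60)
        assert t.mean_dwell_minutes[1] == pytest.approx(3 * 2.7 / 60)

    def test_constant_sequence(self):
        t = temporal_stats(np.ones(231, dtype=int), SPEC, 2)
        assert t.n_transitions == 0
        assert t.fraction_time[0] == 1.0
        assert t.mean_dwell_minutes[0] == pytest.approx(231 * 2.7 / 60)
        assert np.isnan(t.mean_dwell_minutes[1])

    def test_alternating_sequence(self):
        t = temporal_stats(np.array([1, 2, 1, 2, 1, 2]), SPEC, 2)
        assert t.n_transitions == 5

    def test_fractions_sum_to_one(self, rng):
        labels = rng.integers(1, 3, size=100)
        t = temporal_stats(labels, SPEC, 2)
        assert t.fraction_time.sum() == pytest.approx(1.0)

    def test_empty_labels_rejected(self):
        with pytest.raises(InputError):
            temporal_stats(np.array([]), SPEC, 2)
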