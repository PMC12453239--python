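import numpy as np
import pytest

from fridisc.bootstrap import (
    PooledMetrics,
    SessionResult,
    auroc,
    pool_sessions,
    rank_features,
    run_session,
    run_sessions,
    sens_spec,
)
from fridisc.config import BootstrapConfig, FitConfig


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_pair_enumeration_with_tie(self):
        # positives {0.9, 0.8}, negatives {0.7, 0.8}: 3 wins + 1 tie of 4 pairs
        scores = np.array([0.9, 0.8, 0.7, 0.8])
        labels = np.array([1, 1, 0, 0])
        assert auroc(scores, labels) == pytest.approx(0.875)

    def test_negation_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert auroc(-scores, labels) == pytest.approx(1 - auroc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestSensSpec:
    def test_perfect_split(self):
        s, p = sens_spec([1, 1, 0, 0], [1, 1, 0, 0])
        assert (s, p) == (1.0, 1.0)

    def test_constant_low_score_all_negative(self):
        s, p = sens_spec([0.4] * 6, [1, 1, 1, 0, 0, 0])
        assert (s, p) == (0.0, 1.0)

    def test_hand_tally_six_samples(self):
        scores = np.array([0.9, 0.3, 0.6, 0.2, 0.8, 0.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        # predictions: + - + - + -  => TP=2 FN=1 TN=2 FP=1
        s, p = sens_spec(scores, labels, 0.5)
        assert s == pytest.approx(2 / 3)
        assert p == pytest.approx(2 / 3)


def _paired_data(rng, n_pairs=10, d=6, separation=0.0):
    n = 2 * n_pairs
    X = rng.normal(size=(n, d))
    y = np.array([1, 0] * n_pairs)
    X[y == 1, 0] += separation
    pairs = np.repeat([f"p{i}" for i in range(n_pairs)], 2)
    return X, y, pairs


class TestRunSession:
    def test_separable_data_high_auroc(self, rng):
        X, y, pairs = _paired_data(rng, n_pairs=10, separation=6.0)
        s = run_session(X, y, pairs, FitConfig(alpha=0.5), n_resamples=20, seed=1)
        assert s.mean("auroc") > 0.95

    def test_same_seed_identical(self, rng):
        X, y, pairs = _paired_data(rng, separation=1.0)
        s1 = run_session(X, y, pairs, FitConfig(), n_resamples=15, seed=9)
        s2 = run_session(X, y, pairs, FitConfig(), n_resamples=15, seed=9)
        for m in s1.metrics:
            np.testing.assert_array_equal(s1.metrics[m], s2.metrics[m])
        assert s1.selected == s2.selected

    def test_null_features_auroc_near_half(self, rng):
        """With unscreened pure-noise features the OOB AUROC mean stays
        within 3 resample-SDs of 0.5."""
        X, y, pairs = _paired_data(rng, n_pairs=13, d=10, separation=0.0)
        s = run_session(X, y, pairs, FitConfig(), n_resamples=50, seed=3)
        sd = np.std(s.metrics["auroc"], ddof=1)
        assert abs(s.mean("auroc") - 0.5) < 3 * sd

    def test_oob_always_contains_both_classes(self, rng):
        """Pair-level resampling guarantees paired OOB sets; no redraws
        should ever be needed for class balance."""
        X, y, pairs = _paired_data(rng)
        s = run_session(X, y, pairs, FitConfig(), n_resamples=30, seed=5)
        assert s.n_redraws < 30  # redraws only for the rare all-pairs-drawn case

    def test_single_pair_rejected(self, rng):
        X = rng.normal(size=(2, 3))
        with pytest.raises(ValueError):
            run_session(X, np.array([1, 0]), np.array(["p0", "p0"]), FitConfig())


def _session(seed, means, var_scale=1.0, rng=None):
    rng = rng or np.random.default_rng(seed)
    B = 40
    metrics = {
        "auroc": means[0] + var_scale * rng.normal(0, 0.05, B),
        "sensitivity": means[1] + var_scale * rng.normal(0, 0.05, B),
        "specificity": means[2] + var_scale * rng.normal(0, 0.05, B),
    }
    return SessionResult(seed=seed, metrics=metrics, selected=[["f0"]] * B)


class TestPoolSessions:
    def test_identical_sessions_pool_to_their_mean(self):
        s1 = _session(1, (0.8, 0.7, 0.6))
        s2 = SessionResult(seed=2, metrics={k: v.copy() for k, v in s1.metrics.items()},
                           selected=s1.selected)
        pooled = pool_sessions([s1, s2])
        assert pooled.pooled["auroc"] == pytest.approx(s1.mean("auroc"))

    def test_equal_variance_two_sessions_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.05, 40)
        m1 = {k: 0.7 + base for k in ("auroc", "sensitivity", "specificity")}
        m2 = {k: 0.8 + base for k in ("auroc", "sensitivity", "specificity")}
        s1 = SessionResult(1, m1, [["a"]] * 40)
        s2 = SessionResult(2, m2, [["a"]] * 40)
        pooled = pool_sessions([s1, s2])
        want = 0.5 * (s1.mean("auroc") + s2.mean("auroc"))
        assert pooled.pooled["auroc"] == pytest.approx(want, abs=1e-12)

    def test_unequal_variance_hand_computation(self):
        rng = np.random.default_rng(1)
        sessions = [_session(1, (0.7, 0.7, 0.7), 1.0), _session(2, (0.8, 0.8, 0.8), 3.0),
                    _session(3, (0.9, 0.9, 0.9), 0.5)]
        pooled = pool_sessions(sessions)
        m = np.array([s.mean("auroc") for s in sessions])
        v = np.array([s.var("auroc") for s in sessions])
        w = 1 / v
        want = np.sum(w * m) / np.sum(w)
        half = 1.96 / np.sqrt(np.sum(w))
        assert pooled.pooled["auroc"] == pytest.approx(want, abs=1e-12)
        assert pooled.ci_hi["auroc"] - pooled.pooled["auroc"] == pytest.approx(half, abs=1e-12)
        assert pooled.ci_lo["auroc"] <= pooled.pooled["auroc"] <= pooled.ci_hi["auroc"]

    def test_zero_variance_session_rejected(self):
        s1 = _session(1, (0.7, 0.7, 0.7))
        s2 = _session(2, (0.8, 0.8, 0.8))
        s2.metrics["auroc"][:] = 0.8  # degenerate
        with pytest.raises(ValueError):
            pool_sessions([s1, s2])

    def test_ci_width_shrinks_with_more_sessions(self):
        sessions = [_session(i, (0.75, 0.7, 0.7)) for i in range(12)]
        w4 = pool_sessions(sessions[:4])
        w12 = pool_sessions(sessions)
        width4 = w4.ci_hi["auroc"] - w4.ci_lo["auroc"]
        width12 = w12.ci_hi["auroc"] - w12.ci_lo["auroc"]
        assert width12 < width4

    def test_mean_pooling_option(self):
        sessions = [_session(i, (0.7 + 0.01 * i, 0.7, 0.7)) for i in range(5)]
        pooled = pool_sessions(sessions, pooling="mean")
        assert pooled.pooled["auroc"] == pytest.approx(
            np.mean([s.mean("auroc") for s in sessions])
        )


class TestRankFeatures:
    def test_always_selected_feature_has_frequency_one(self):
        sessions = [_session(i, (0.7, 0.7, 0.7)) for i in range(3)]
        ranking = rank_features(sessions)
        assert ranking.frequencies["f0"] == 1.0

    def test_never_selected_absent_from_top(self):
        sessions = [_session(i, (0.7, 0.7, 0.7)) for i in range(3)]
        ranking = rank_features(sessions)
        assert "ghost" not in ranking.top(40)

    def test_tie_break_deterministic_by_id(self):
        s = SessionResult(1, {k: np.array([0.5, 0.6]) for k in
                              ("auroc", "sensitivity", "specificity")},
                          selected=[["b", "a"], ["a", "b"]])
        ranking = rank_features([s])
        assert ranking.top(2) == ["a", "b"]


def test_run_sessions_deterministic_and_seed_varied(rng):
    X, y, pairs = _paired_data(rng, n_pairs=8, separation=1.5)
    bc = BootstrapConfig(n_resamples=10, n_sessions=3)
    s1 = run_sessions(X, y, pairs, FitConfig(), bc, seed=11)
    s2 = run_sessions(X, y, pairs, FitConfig(), bc, seed=11)
    assert [s.seed for s in s1] == [s.seed for s in s2]
    assert len({s.seed for s in s1}) == 3  # sessions use distinct seeds
    for a, b in zip(s1, s2):
        np.testing.assert_array_equal(a.metrics["auroc"], b.metrics["auroc"])
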