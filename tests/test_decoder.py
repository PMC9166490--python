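"""LDA -> 2-state HMM -> logistic regression decoder chain."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modbci.decoder import (
    DecodeState,
    MotorImageryDecoder,
    TrainingError,
    evaluate,
)
from modbci.simulator import MOVE, REST


# ---------------------------------------------------------------------------
# helpers: minimal hand-built models and synthetic feature generators

def _make_model(
    startprob=(0.5, 0.5),
    transmat=((0.9, 0.1), (0.2, 0.8)),
    means=(-1.0, 1.0),
    sigmas=(1.0, 1.0),
    lr=(6.0, -3.0),
    threshold=0.5,
    n_features=4,
):
    """Assemble a decoder with known parameters, bypassing fit."""
    m = MotorImageryDecoder(threshold=threshold, log_features=False)
    m.keep_mask_ = np.ones(n_features, bool)
    m.mean_ = np.zeros(n_features)
    m.scale_ = np.ones(n_features)
    # LDA score = first feature
    m.lda_coef_ = np.eye(1, n_features).ravel()
    m.lda_intercept_ = 0.0
    m.startprob_ = np.array(startprob, float)
    m.transmat_ = np.array(transmat, float)
    m.emission_means_ = np.array(means, float)
    m.emission_sigmas_ = np.array(sigmas, float)
    m.lr_coef_, m.lr_intercept_ = lr
    m.classes_ = np.array([REST, MOVE])
    m.n_features_in_ = n_features
    m.metadata_ = {"schema": "modbci-decoder-v1"}
    return m


def _gauss(x, mu, sig):
    return np.exp(-0.5 * ((x - mu) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))


def _enumeration_posteriors(scores, pi, A, means, sigmas):
    """Filtered posteriors by brute-force marginalization over all paths."""
    T = len(scores)
    post = np.zeros((T, 2))
    for t in range(T):
        weights = np.zeros(2)
        for path in itertools.product((0, 1), repeat=t + 1):
            w = pi[path[0]] * _gauss(scores[0], means[path[0]], sigmas[path[0]])
            for u in range(1, t + 1):
                w *= A[path[u - 1], path[u]] * _gauss(
                    scores[u], means[path[u]], sigmas[path[u]]
                )
            weights[path[-1]] += w
        post[t] = weights / weights.sum()
    return post


def _markov_features(n_steps, transmat, sep=4.0, seed=0, n_features=4):
    """Features whose first column is a Gaussian score driven by a 2-state chain."""
    rng = np.random.default_rng(seed)
    A = np.asarray(transmat)
    states = np.zeros(n_steps, int)
    states[0] = rng.integers(2)
    for t in range(1, n_steps):
        states[t] = rng.random() < A[states[t - 1], 1]
    X = rng.standard_normal((n_steps, n_features))
    X[:, 0] += np.where(states == 1, sep / 2, -sep / 2)
    y = np.where(states == 1, MOVE, REST)
    return X, y


# ---------------------------------------------------------------------------

class TestForwardRecursion:
    @pytest.mark.parametrize("T", [1, 3, 7, 12])
    def test_forward_equals_exhaustive_path_enumeration(self, T):
        rng = np.random.default_rng(T)
        pi = np.array([0.6, 0.4])
        A = np.array([[0.85, 0.15], [0.3, 0.7]])
        means, sigmas = np.array([-0.8, 1.2]), np.array([0.9, 1.4])
        scores = rng.normal(0, 1.5, T)
        m = _make_model(pi, A, means, sigmas, n_features=1)
        m.lda_coef_ = np.ones(1)
        got = m.forward_posteriors(scores[:, None])
        exp = _enumeration_posteriors(scores, pi, A, means, sigmas)
        assert np.max(np.abs(got - exp)) < 1e-9

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_posterior_stays_a_valid_simplex(self, seed):
        rng = np.random.default_rng(seed)
        m = _make_model(n_features=1)
        m.lda_coef_ = np.ones(1)
        state = None
        for x in rng.normal(0, 5, 20):
            _, _, state = m.decode_step(np.array([x]), state)
            assert np.all(state.posterior >= 0)
            assert abs(state.posterior.sum() - 1.0) < 1e-10

    def test_symmetric_model_posterior_fixed_at_half(self):
        m = _make_model(
            startprob=(0.5, 0.5),
            transmat=((0.5, 0.5), (0.5, 0.5)),
            means=(0.0, 0.0),
            sigmas=(1.0, 1.0),
            n_features=1,
        )
        m.lda_coef_ = np.ones(1)
        state = None
        for x in (0.3, -1.2, 2.0):
            _, _, state = m.decode_step(np.array([x]), state)
            assert np.allclose(state.posterior, [0.5, 0.5])

    def test_nonfinite_features_reject_step_and_keep_state(self):
        m = _make_model(n_features=2)
        _, _, state = m.decode_step(np.array([1.0, 0.0]))
        before = state.posterior.copy()
        with pytest.warns(UserWarning):
            _, _, after = m.decode_step(np.array([np.nan, 0.0]), state)
        assert np.array_equal(after.posterior, before)

    def test_invalid_decode_state_rejected(self):
        with pytest.raises(ValueError):
            DecodeState(np.array([0.7, 0.7]))


class TestThreshold:
    def test_threshold_near_one_forces_rest(self):
        m = _make_model(lr=(2.0, -1.0), threshold=1 - 1e-9, n_features=1)
        m.lda_coef_ = np.ones(1)
        rng = np.random.default_rng(0)
        X = rng.normal(1.0, 1.0, (50, 1))  # MOVE-like scores
        assert np.all(m.predict(X) == REST)

    def test_raising_threshold_never_increases_move_commands(self):
        m = _make_model(n_features=1)
        m.lda_coef_ = np.ones(1)
        rng = np.random.default_rng(1)
        X = rng.normal(0, 2, (200, 1))
        counts = []
        for th in (0.2, 0.4, 0.6, 0.8):
            m.threshold = th
            counts.append(int(np.sum(m.predict(X) == MOVE)))
        assert counts == sorted(counts, reverse=True)

    def test_tie_at_threshold_decodes_move(self):
        # probability == threshold -> MOVE (>= comparison)
        m = _make_model(lr=(0.0, 0.0), threshold=0.5, n_features=1)  # prob always 0.5
        m.lda_coef_ = np.ones(1)
        cmd, prob, _ = m.decode_step(np.array([0.0]))
        assert prob == pytest.approx(0.5)
        assert cmd == MOVE


class TestTraining:
    def test_separable_classes_reach_high_training_accuracy(self):
        A = [[0.95, 0.05], [0.05, 0.95]]
        X, y = _markov_features(2000, A, sep=4.0, seed=2)
        m = MotorImageryDecoder(log_features=False).fit(X, y)
        rep = evaluate(m, X, y, transition_exclusion=0)
        assert rep.accuracy >= 0.95

    def test_shuffled_labels_give_chance_accuracy(self):
        A = [[0.95, 0.05], [0.05, 0.95]]
        X, y = _markov_features(3000, A, sep=4.0, seed=3)
        rng = np.random.default_rng(3)
        y_shuf = rng.permutation(y)
        m = MotorImageryDecoder(log_features=False).fit(X, y_shuf)
        rep = evaluate(m, X, y_shuf, transition_exclusion=0)
        assert rep.accuracy == pytest.approx(0.5, abs=0.05)

    def test_transition_matrix_recovered_from_known_chain(self):
        A = np.array([[0.93, 0.07], [0.12, 0.88]])
        X, y = _markov_features(3000, A, sep=4.0, seed=4)
        m = MotorImageryDecoder(log_features=False).fit(X, y)
        assert np.max(np.abs(m.transmat_ - A)) < 0.05

    def test_single_class_data_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 4))
        with pytest.raises(TrainingError):
            MotorImageryDecoder(log_features=False).fit(X, np.array([REST] * 100))

    def test_zero_variance_features_dropped_with_warning(self):
        A = [[0.9, 0.1], [0.1, 0.9]]
        X, y = _markov_features(500, A, seed=5)
        X[:, 2] = 7.0  # constant feature
        with pytest.warns(UserWarning, match="zero-variance"):
            m = MotorImageryDecoder(log_features=False).fit(X, y)
        assert m.n_dropped_features_ == 1
        assert not m.keep_mask_[2]

    def test_training_is_deterministic(self):
        A = [[0.9, 0.1], [0.1, 0.9]]
        X, y = _markov_features(800, A, seed=6)
        m1 = MotorImageryDecoder(log_features=False).fit(X, y)
        m2 = MotorImageryDecoder(log_features=False).fit(X, y)
        assert np.array_equal(m1.lda_coef_, m2.lda_coef_)
        assert np.array_equal(m1.transmat_, m2.transmat_)
        assert m1.lr_coef_ == m2.lr_coef_

    def test_transition_rows_are_stochastic(self):
        A = [[0.9, 0.1], [0.1, 0.9]]
        X, y = _markov_features(800, A, seed=7)
        m = MotorImageryDecoder(log_features=False).fit(X, y)
        assert np.allclose(m.transmat_.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m.emission_sigmas_ > 0)


class TestSerialization:
    def test_roundtrip_decodes_bitwise_identically(self, tmp_path):
        A = [[0.9, 0.1], [0.1, 0.9]]
        X, y = _markov_features(600, A, seed=8)
        m = MotorImageryDecoder(log_features=False).fit(X, y)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = MotorImageryDecoder.load(path)
        assert np.array_equal(m.predict_proba(X), m2.predict_proba(X))
        assert json.loads(path.read_text())["schema"] == "modbci-decoder-v1"

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema": "nope"}))
        with pytest.raises(ValueError):
            MotorImageryDecoder.load(path)


class TestEvaluate:
    def test_perfect_decoder_on_separable_stream_scores_one(self):
        m = _make_model(
            transmat=((0.9, 0.1), (0.1, 0.9)), means=(-3.0, 3.0),
            sigmas=(0.5, 0.5), lr=(20.0, -10.0), n_features=1,
        )
        m.lda_coef_ = np.ones(1)
        y = np.array([REST] * 20 + [MOVE] * 20)
        X = np.where(y == MOVE, 3.0, -3.0)[:, None]
        assert evaluate(m, X, y, transition_exclusion=0).accuracy == 1.0

    def test_constant_rest_decoder_scores_base_rate(self):
        m = _make_model(lr=(0.0, -5.0), n_features=1)  # probability ~0 always
        m.lda_coef_ = np.ones(1)
        y = np.array(([REST] * 10 + [MOVE] * 10) * 5)
        X = np.zeros((len(y), 1))
        rep = evaluate(m, X, y, transition_exclusion=0)
        assert rep.accuracy == pytest.approx(0.5, abs=0.01)
        assert rep.per_class_accuracy[REST] == 1.0

    def test_transition_exclusion_removes_packets_after_changes(self):
        m = _make_model(n_features=1)
        m.lda_coef_ = np.ones(1)
        y = np.array([REST] * 10 + [MOVE] * 10)
        X = np.zeros((20, 1))
        rep = evaluate(m, X, y, transition_exclusion=2)
        assert rep.n_evaluated == 18
        assert rep.n_excluded == 2

    def test_unlabeled_only_session_rejected(self):
        m = _make_model(n_features=1)
        m.lda_coef_ = np.ones(1)
        with pytest.raises(ValueError):
            evaluate(m, np.zeros((5, 1)), np.array(["UNLABELED"] * 5))
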