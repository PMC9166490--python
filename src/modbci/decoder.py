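"""The motor-imagery decoder chain: LDA -> 2-state HMM -> logistic regression.

The 644-dimensional spectral feature vectors are log-transformed and
standardized, projected to a scalar discriminant score by linear
discriminant analysis, temporally filtered by a 2-state hidden Markov
model (states REST and MOVE, Gaussian emissions on the LDA score), and
the forward (filtered) MOVE posterior is mapped to a movement probability
by a univariate logistic regression.  A command is MOVE when that
probability reaches the decision threshold (>= comparison).

Training is fully supervised and deterministic: the HMM start and
transition probabilities come from label counts with add-one smoothing,
emissions are per-state Gaussian maximum-likelihood fits of the LDA
scores, and the logistic stage is fit on the forward posteriors of the
training sequences.  No Baum-Welch iteration is involved.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression

from .simulator import MOVE, REST, UNLABELED

STATES = (REST, MOVE)  # state 0 = REST, state 1 = MOVE
MODEL_SCHEMA = "modbci-decoder-v1"


class TrainingError(ValueError):
    pass


@dataclasses.dataclass
class DecodeState:
    """Forward posterior over (REST, MOVE) carried between packets."""

    posterior: np.ndarray  # shape (2,), simplex
    last_packet_index: int = -1

    def __post_init__(self) -> None:
        p = np.asarray(self.posterior, dtype=float)
        if p.shape != (2,) or np.any(p < -1e-10) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("posterior must be a 2-simplex")
        self.posterior = p


def _sequence_slices(n: int, sequence_lengths) -> list[slice]:
    if sequence_lengths is None:
        return [slice(0, n)]
    lengths = [int(l) for l in sequence_lengths]
    if sum(lengths) != n:
        raise ValueError("sequence_lengths must sum to the number of rows")
    out, start = [], 0
    for l in lengths:
        out.append(slice(start, start + l))
        start += l
    return out


class MotorImageryDecoder(ClassifierMixin, BaseEstimator):
    """Binary MOVE/REST classifier over per-packet spectral features.

    Follows the scikit-learn estimator contract: ``fit(X, y)`` with X of
    shape (n_packets, n_features) and y of string labels; rows must be in
    temporal order, with ``sequence_lengths`` delimiting independent
    sessions.  ``predict_proba`` / ``predict`` run the forward recursion
    in row order; :meth:`decode_step` exposes the same recursion one
    packet at a time for online use.

    Parameters
    ----------
    threshold : float
        Decision threshold on the movement probability, in (0, 1).
        Command is MOVE when probability >= threshold.
    transition_smoothing : float
        Additive (Laplace) smoothing count on HMM transition and start
        tallies; avoids zero transition probabilities in short sessions.
    log_features : bool
        Apply log(x + log_eps) to the (nonnegative spectral) features
        before standardization; stabilizes the variance of periodogram
        bins.
    min_sigma : float
        Floor on emission standard deviations.
    """

    def __init__(
        self,
        threshold: float = 0.5,
        transition_smoothing: float = 1.0,
        log_features: bool = True,
        log_eps: float = 1e-12,
        min_sigma: float = 1e-6,
    ) -> None:
        self.threshold = threshold
        self.transition_smoothing = transition_smoothing
        self.log_features = log_features
        self.log_eps = log_eps
        self.min_sigma = min_sigma

    # ------------------------------------------------------------------
    # training

    def fit(self, X, y, sequence_lengths=None) -> "MotorImageryDecoder":
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        labeled = np.isin(y, STATES)
        classes = set(np.unique(y[labeled]))
        if classes != set(STATES):
            raise TrainingError(
                f"training data must contain both MOVE and REST labels, got {sorted(classes)}"
            )
        slices = _sequence_slices(len(X), sequence_lengths)

        Xt = self._pretransform(X)
        # drop features with zero variance across the labeled training set
        var = Xt[labeled].var(axis=0)
        self.keep_mask_ = var > 0
        n_dropped = int((~self.keep_mask_).sum())
        if n_dropped:
            warnings.warn(f"dropping {n_dropped} zero-variance features")
        Xk = Xt[:, self.keep_mask_]
        self.mean_ = Xk[labeled].mean(axis=0)
        self.scale_ = Xk[labeled].std(axis=0)
        Xs = (Xk - self.mean_) / self.scale_

        z = (y == MOVE).astype(int)
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(Xs[labeled], z[labeled])
        self.lda_coef_ = lda.coef_.ravel()
        self.lda_intercept_ = float(lda.intercept_[0])
        scores = Xs @ self.lda_coef_ + self.lda_intercept_

        self._fit_hmm(z, labeled, scores, slices)
        self._fit_logistic(z, labeled, scores, slices)
        self.classes_ = np.array(STATES)
        self.n_features_in_ = X.shape[1]
        self.n_dropped_features_ = n_dropped
        self.metadata_ = {
            "schema": MODEL_SCHEMA,
            "n_training_vectors": int(labeled.sum()),
            "n_sequences": len(slices),
            "dropped_features": n_dropped,
        }
        return self

    def _fit_hmm(self, z, labeled, scores, slices) -> None:
        a = self.transition_smoothing
        start = np.full(2, a)
        trans = np.full((2, 2), a)
        for sl in slices:
            zs, ls = z[sl], labeled[sl]
            idx = np.flatnonzero(ls)
            if len(idx) == 0:
                continue
            start[zs[idx[0]]] += 1
            # transitions only between consecutively labeled packets
            consec = idx[1:][np.diff(idx) == 1]
            np.add.at(trans, (zs[consec - 1], zs[consec]), 1)
        self.startprob_ = start / start.sum()
        self.transmat_ = trans / trans.sum(axis=1, keepdims=True)
        self.emission_means_ = np.array(
            [scores[labeled & (z == s)].mean() for s in (0, 1)]
        )
        sig = np.array([scores[labeled & (z == s)].std() for s in (0, 1)])
        self.emission_sigmas_ = np.maximum(sig, self.min_sigma)

    def _fit_logistic(self, z, labeled, scores, slices) -> None:
        post = np.concatenate(
            [self._forward(scores[sl])[:, 1] for sl in slices]
        )
        lr = LogisticRegression()
        lr.fit(post[labeled, None], z[labeled])
        self.lr_coef_ = float(lr.coef_[0, 0])
        self.lr_intercept_ = float(lr.intercept_[0])

    # ------------------------------------------------------------------
    # inference

    def _pretransform(self, X: np.ndarray) -> np.ndarray:
        if self.log_features:
            return np.log(np.clip(X, 0.0, None) + self.log_eps)
        return np.asarray(X, dtype=float)

    def _scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (self._pretransform(X)[:, self.keep_mask_] - self.mean_) / self.scale_
        return Xs @ self.lda_coef_ + self.lda_intercept_

    def _emission_likelihood(self, score: float) -> np.ndarray:
        mu, sig = self.emission_means_, self.emission_sigmas_
        return np.exp(-0.5 * ((score - mu) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))

    def _forward(self, scores: np.ndarray) -> np.ndarray:
        """Filtered (forward) posteriors, renormalized at every step."""
        post = np.empty((len(scores), 2))
        prior = self.startprob_
        for t, s in enumerate(scores):
            p = prior * self._emission_likelihood(s)
            tot = p.sum()
            if tot <= 0 or not np.isfinite(tot):
                p, tot = prior.copy(), prior.sum()
            post[t] = p / tot
            prior = post[t] @ self.transmat_
        return post

    def _move_probability(self, move_posterior: np.ndarray) -> np.ndarray:
        logit = self.lr_coef_ * move_posterior + self.lr_intercept_
        return 1.0 / (1.0 + np.exp(-logit))

    def initial_state(self) -> DecodeState:
        return DecodeState(self.startprob_.copy())

    def decode_step(
        self, fv, state: DecodeState | None = None
    ) -> tuple[str, float, DecodeState]:
        """Advance the forward recursion by one packet.

        Parameters
        ----------
        fv : array of 644 features or FeatureVector
        state : DecodeState or None
            None starts a fresh recursion from the HMM initial
            distribution (the prior is then the start distribution, not a
            propagated posterior).

        Returns
        -------
        (command, move_probability, new_state)
            Non-finite features reject the step: the state is returned
            unchanged and the command recomputed from the old posterior.
        """
        values = getattr(fv, "values", fv)
        packet_index = getattr(fv, "packet_index", None)
        values = np.asarray(values, dtype=float)
        if state is None:
            prior = self.startprob_
            state = DecodeState(self.startprob_.copy())
        else:
            prior = state.posterior @ self.transmat_
        if not np.all(np.isfinite(values)):
            warnings.warn("non-finite features: decode step rejected")
            prob = float(self._move_probability(state.posterior[1]))
            return (MOVE if prob >= self.threshold else REST), prob, state
        score = self._scores(values[None, :])[0]
        p = prior * self._emission_likelihood(score)
        tot = p.sum()
        if tot <= 0 or not np.isfinite(tot):
            p, tot = np.asarray(prior, dtype=float).copy(), float(np.sum(prior))
        posterior = p / tot
        prob = float(self._move_probability(posterior[1]))
        new_state = DecodeState(
            posterior,
            packet_index if packet_index is not None else state.last_packet_index + 1,
        )
        return (MOVE if prob >= self.threshold else REST), prob, new_state

    def predict_proba(self, X, sequence_lengths=None) -> np.ndarray:
        """Per-packet (REST, MOVE) movement probabilities, in row order."""
        X = np.asarray(X, dtype=float)
        scores = self._scores(X)
        probs = np.concatenate(
            [
                self._move_probability(self._forward(scores[sl])[:, 1])
                for sl in _sequence_slices(len(X), sequence_lengths)
            ]
        )
        return np.column_stack([1.0 - probs, probs])

    def predict(self, X, sequence_lengths=None) -> np.ndarray:
        p = self.predict_proba(X, sequence_lengths)[:, 1]
        return np.where(p >= self.threshold, MOVE, REST)

    def forward_posteriors(self, X, sequence_lengths=None) -> np.ndarray:
        scores = self._scores(np.asarray(X, dtype=float))
        return np.concatenate(
            [self._forward(scores[sl]) for sl in _sequence_slices(len(X), sequence_lengths)]
        )

    # ------------------------------------------------------------------
    # persistence

    _ARRAY_FIELDS = (
        "keep_mask_", "mean_", "scale_", "lda_coef_", "startprob_",
        "transmat_", "emission_means_", "emission_sigmas_",
    )
    _SCALAR_FIELDS = ("lda_intercept_", "lr_coef_", "lr_intercept_")

    def to_dict(self) -> dict:
        d = {
            "schema": MODEL_SCHEMA,
            "params": self.get_params(),
            "metadata": self.metadata_,
            "n_features_in": int(self.n_features_in_),
        }
        for f in self._ARRAY_FIELDS:
            d[f] = getattr(self, f).tolist()
        for f in self._SCALAR_FIELDS:
            d[f] = getattr(self, f)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MotorImageryDecoder":
        if d.get("schema") != MODEL_SCHEMA:
            raise ValueError(f"unknown model schema {d.get('schema')!r}")
        model = cls(**d["params"])
        for f in cls._ARRAY_FIELDS:
            arr = np.asarray(d[f])
            if f == "keep_mask_":
                arr = arr.astype(bool)
            setattr(model, f, arr)
        for f in cls._SCALAR_FIELDS:
            setattr(model, f, float(d[f]))
        model.metadata_ = d["metadata"]
        model.n_features_in_ = int(d["n_features_in"])
        model.classes_ = np.array(STATES)
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MotorImageryDecoder":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# evaluation

@dataclasses.dataclass
class AccuracyReport:
    """Windowed-accuracy report over one labeled session."""

    accuracy: float
    per_class_accuracy: dict
    confusion: dict            # {(true, predicted): count}
    n_evaluated: int
    n_excluded: int

    def __str__(self) -> str:
        pc = ", ".join(f"{k}: {v:.3f}" for k, v in self.per_class_accuracy.items())
        return (
            f"windowed accuracy {self.accuracy:.4f} over {self.n_evaluated} packets "
            f"({self.n_excluded} excluded; per-class {pc})"
        )


def evaluate(
    model: MotorImageryDecoder,
    X,
    labels,
    transition_exclusion: int = 1,
    sequence_lengths=None,
) -> AccuracyReport:
    """Windowed decoding accuracy on a labeled session.

    Accuracy is the fraction of correctly classified packets among labeled
    packets, after excluding ``transition_exclusion`` packets following
    every prompt change (reaction-time guard) and any UNLABELED packets.
    """
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    pred = model.predict(X, sequence_lengths)
    keep = np.isin(labels, STATES)
    for sl in _sequence_slices(len(X), sequence_lengths):
        seq = labels[sl]
        changes = np.flatnonzero(seq[1:] != seq[:-1]) + 1
        for c in changes:
            keep[sl.start + c: sl.start + c + transition_exclusion] = False
    if not keep.any():
        raise ValueError("no labeled packets to evaluate")
    t, p = labels[keep], pred[keep]
    confusion = {
        (a, b): int(np.sum((t == a) & (p == b))) for a in STATES for b in STATES
    }
    per_class = {
        s: float(np.mean(p[t == s] == s)) for s in STATES if np.any(t == s)
    }
    return AccuracyReport(
        accuracy=float(np.mean(t == p)),
        per_class_accuracy=per_class,
        confusion=confusion,
        n_evaluated=int(keep.sum()),
        n_excluded=int(len(labels) - keep.sum()),
    )
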