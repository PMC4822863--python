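"""Pitch-ranking experiment on pooled ISIHs.

A two-alternative task: given the temporal pitch codes (smoothed pooled
ISIHs) of two same-type vowel stimuli 1-12 semitones apart, decide which
has the higher pitch.  The decision model is a single-layer perceptron
with two softmax output units on the concatenated pair vector, trained by
the delta rule (back-propagation collapses to it for a single layer) with
early stopping on a validation split.  Per trial, 1500 training pairs
(10% held out for validation) and 500 unseen test pairs are drawn; scores
are averaged over 20 trials and reported per semitone interval.  Chance
is 50%.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

N_TRAIN_PAIRS = 1500
N_TEST_PAIRS = 500
N_TRIALS = 20
VALIDATION_FRACTION = 0.10
INTERVAL_RANGE = (1, 12)

#: pool key: (stimulus type, ladder index); value: smoothed ISIH vector
ISIHPool = Mapping[tuple[str, int], np.ndarray]


@dataclasses.dataclass
class RankingPair:
    isih_a: np.ndarray
    isih_b: np.ndarray
    interval_semitones: int
    label: int  # 0 if a is higher-pitched, 1 if b
    stimulus_type: str

    def __post_init__(self) -> None:
        lo, hi = INTERVAL_RANGE
        if not lo <= self.interval_semitones <= hi:
            raise ValueError("interval must be within 1-12 semitones")


@dataclasses.dataclass
class RankingExperiment:
    n_train: int = N_TRAIN_PAIRS
    n_test: int = N_TEST_PAIRS
    n_trials: int = N_TRIALS
    validation_fraction: float = VALIDATION_FRACTION
    seed: int = 0


def eligible_combinations(
    pool: ISIHPool, intervals: tuple[int, int] = INTERVAL_RANGE
) -> list[tuple[str, int, int]]:
    """All same-type (type, low index, high index) combinations in range."""
    by_type: dict[str, list[int]] = {}
    for (stype, idx) in pool:
        by_type.setdefault(stype, []).append(idx)
    combos = []
    for stype, idxs in sorted(by_type.items()):
        idxs = sorted(idxs)
        for a in idxs:
            for b in idxs:
                if b > a and intervals[0] <= b - a <= intervals[1]:
                    combos.append((stype, a, b))
    return combos


def _pair_from_combo(pool: ISIHPool, combo, rng: np.random.Generator) -> RankingPair:
    stype, lo, hi = combo
    if rng.random() < 0.5:  # randomize presentation order
        return RankingPair(pool[(stype, hi)], pool[(stype, lo)], hi - lo, 0, stype)
    return RankingPair(pool[(stype, lo)], pool[(stype, hi)], hi - lo, 1, stype)


def make_pairs(
    pool: ISIHPool,
    n: int,
    seed,
    intervals: tuple[int, int] = INTERVAL_RANGE,
    combos: Sequence[tuple[str, int, int]] | None = None,
) -> list[RankingPair]:
    """Draw ``n`` uniformly random eligible pairs with randomized order."""
    if combos is None:
        combos = eligible_combinations(pool, intervals)
    if not combos:
        if n == 0:
            return []
        raise ValueError("no eligible stimulus combinations in the pool")
    rng = np.random.default_rng(seed)
    picks = rng.integers(len(combos), size=n)
    return [_pair_from_combo(pool, combos[i], rng) for i in picks]


@dataclasses.dataclass
class Perceptron:
    """Two linear units + softmax over the concatenated ISIH pair.

    Inputs are standardized with the training-set mean/scale: the two
    histogram halves are strongly correlated, and the raw design matrix is
    too ill-conditioned for plain gradient descent.
    """

    weights: np.ndarray  # (2, n_features)
    bias: np.ndarray  # (2,)
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None

    def _prep(self, X: np.ndarray) -> np.ndarray:
        if self.mu is None:
            return X
        return (X - self.mu) / self.sd

    def scores(self, X: np.ndarray) -> np.ndarray:
        return self._prep(X) @ self.weights.T + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.scores(X), axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == y))


def _features(pairs: Sequence[RankingPair]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([np.concatenate([p.isih_a, p.isih_b]) for p in pairs])
    y = np.array([p.label for p in pairs])
    return X, y


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def perceptron_train(
    pairs: Sequence[RankingPair],
    epochs: int = 8000,
    learning_rate: float = 0.05,
    seed=0,
    validation_fraction: float = VALIDATION_FRACTION,
    patience: int = 800,
) -> Perceptron:
    """Delta-rule gradient descent with early stopping on a validation split."""
    if not pairs:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(seed)
    X, y = _features(pairs)
    n = len(pairs)
    perm = rng.permutation(n)
    n_val = int(round(validation_fraction * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    mu = X[tr_idx].mean(axis=0)
    sd = X[tr_idx].std(axis=0) + 1e-9
    Xt, yt = (X[tr_idx] - mu) / sd, y[tr_idx]
    Xv, yv = (X[val_idx] - mu) / sd, y[val_idx]
    model = Perceptron(
        weights=rng.normal(0.0, 0.01, size=(2, X.shape[1])), bias=np.zeros(2)
    )
    onehot = np.eye(2)[yt]
    best = (np.inf, model.weights.copy(), model.bias.copy())
    stale = 0
    for _ in range(epochs):
        probs = _softmax(model.scores(Xt))
        err = probs - onehot  # gradient of cross-entropy wrt logits
        model.weights -= learning_rate * (err.T @ Xt) / len(yt)
        model.bias -= learning_rate * err.mean(axis=0)
        if len(yv):
            pv = _softmax(model.scores(Xv))
            val_loss = -np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12))
            if val_loss < best[0] - 1e-6:
                best = (val_loss, model.weights.copy(), model.bias.copy())
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if len(yv):
        model.weights, model.bias = best[1], best[2]
    model.mu, model.sd = mu, sd
    return model


def run_experiment(exp: RankingExperiment, pool: ISIHPool) -> pd.DataFrame:
    """Full ranking experiment; returns per-interval mean score and SEM.

    Within each trial the eligible (type, pitch, pitch) combinations are
    split into disjoint train/test sets before pairs are drawn, so no test
    pair combination is ever seen in training.
    """
    combos = eligible_combinations(pool)
    if len(combos) < 8:
        raise ValueError("stimulus pool too small for a ranking experiment")
    master = np.random.SeedSequence(exp.seed)
    trial_scores: dict[int, list[float]] = {}
    overall = []
    for trial_seq in master.spawn(exp.n_trials):
        rng = np.random.default_rng(trial_seq)
        perm = rng.permutation(len(combos))
        n_test_combos = max(1, len(combos) // 4)
        test_combos = [combos[i] for i in perm[:n_test_combos]]
        train_combos = [combos[i] for i in perm[n_test_combos:]]
        train_pairs = make_pairs(pool, exp.n_train, rng, combos=train_combos)
        test_pairs = make_pairs(pool, exp.n_test, rng, combos=test_combos)
        model = perceptron_train(
            train_pairs, seed=rng, validation_fraction=exp.validation_fraction
        )
        Xte, yte = _features(test_pairs)
        correct = model.predict(Xte) == yte
        overall.append(float(np.mean(correct)))
        for p, ok in zip(test_pairs, correct):
            trial_scores.setdefault(p.interval_semitones, []).append(float(ok))
    rows = []
    for interval in sorted(trial_scores):
        s = np.asarray(trial_scores[interval])
        rows.append(
            {
                "interval_semitones": interval,
                "mean_score": s.mean(),
                "sem": s.std(ddof=1) / np.sqrt(s.size) if s.size > 1 else 0.0,
                "n_pairs": s.size,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["overall_scores"] = overall
    return df
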