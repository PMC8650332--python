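"""Classifier definitions: the 1D CNN and the linear-SVM baseline.

The central object is :class:`GaitCycleCNN`, a model built from a stack of
preprocessed gait cycles; ``fit()`` returns a :class:`CNNResults` carrying the
trained network, the training history, prediction and relevance-attribution
methods, and a ``summary()`` table. :class:`LinearSVMBaseline` wraps a linear
support-vector classifier (C = 0.01) on flattened cycles as the simple
reference model.

Architecture: B blocks of [conv -> ReLU -> local max pool], a global average
pooling layer reducing the sequence to a p-dimensional feature vector
(p = number of filters), dropout, and a dense softmax head over the two
classes. Training minimizes a class-weighted categorical cross-entropy with
Adam under a sigmoidal decaying learning rate lr(t) = lr0 * sigmoid(-s (t -
t_mid)) and a max-norm constraint on every weight vector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .nn import (
    Adam,
    Conv1D,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool1D,
    Network,
    ReLU,
    Softmax,
)
from .preprocessing import CLASS_ORDER, N_SAMPLES

PROB_FLOOR = 1e-12


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class Hyperparameters:
    """Architecture and optimization settings of the CNN."""

    n_blocks: int = 2
    filters: int = 8
    kernel: int = 9
    pool_width: int = 2
    dropout: float = 0.1
    max_norm: float = 2.0
    lr0: float = 3e-3
    schedule_steepness: float = 0.15
    schedule_midpoint: float = 20.0
    epochs: int = 40
    batch_size: int = 16
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def validate(self) -> None:
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if self.kernel % 2 != 1 or self.kernel > N_SAMPLES:
            raise ValueError(f"kernel must be odd and <= {N_SAMPLES}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.max_norm <= 0:
            raise ValueError("max_norm must be positive")
        if self.n_blocks < 1 or self.pool_width < 1:
            raise ValueError("n_blocks and pool_width must be >= 1")


def parameter_count(h: Hyperparameters, in_channels: int = 3, n_classes: int = 2) -> int:
    """Closed-form trainable-parameter count of the architecture."""
    total = 0
    c = in_channels
    for _ in range(h.n_blocks):
        total += h.filters * h.kernel * c + h.filters
        c = h.filters
    total += h.filters * n_classes + n_classes
    return total


def build_cnn(h: Hyperparameters, in_channels: int = 3, n_classes: int = 2) -> Network:
    """Assemble the (untrained) network; weight initialization is seeded."""
    h.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(h.seed), 31])))
    t = N_SAMPLES
    layers = []
    c = in_channels
    for _ in range(h.n_blocks):
        if h.kernel > t:
            raise ValueError(
                f"kernel {h.kernel} longer than sequence length {t} after pooling"
            )
        layers += [Conv1D(c, h.filters, h.kernel, rng), ReLU(), MaxPool1D(h.pool_width)]
        c = h.filters
        t = t // h.pool_width
        if t < 1:
            raise ValueError("pooling reduced the sequence to zero length")
    layers += [GlobalAvgPool(), Dropout(h.dropout, rng), Dense(h.filters, n_classes, rng),
               Softmax()]
    return Network(layers)


@dataclass(frozen=True)
class LossConfig:
    """Per-class weights of the weighted categorical cross-entropy."""

    alpha: np.ndarray  # aligned with CLASS_ORDER = (FGC, pre-FOG)

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        if np.any(a <= 0):
            raise ValueError("class weights must be positive")
        object.__setattr__(self, "alpha", a)


def class_weights(y) -> LossConfig:
    """Inverse-frequency class weights alpha_i = M / (2 * count_i).

    ``y`` holds 0 (FGC) / 1 (pre-FOG) labels. Both classes must be present;
    on balanced data the weights are (1, 1).
    """
    y = np.asarray(y)
    counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
    if np.any(counts == 0):
        raise ValueError("both classes must be present to compute class weights")
    return LossConfig(alpha=len(y) / (2.0 * counts))


def weighted_cross_entropy(Y, Y_hat, loss: LossConfig) -> float:
    """Weighted categorical cross-entropy, averaged over rows.

    ``Y`` is one-hot, ``Y_hat`` predicted probabilities (floored at 1e-12
    before the log).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Y_hat = np.atleast_2d(np.asarray(Y_hat, dtype=float))
    if Y.shape != Y_hat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Y_hat.shape}")
    logp = np.log(np.clip(Y_hat, PROB_FLOOR, None))
    per_row = -(loss.alpha[None, :] * Y * logp).sum(axis=1)
    return float(per_row.mean())


def learning_rate_schedule(h: Hyperparameters, epoch: int) -> float:
    """Sigmoidal decay lr(t) = lr0 * sigmoid(-s (t - t_mid))."""
    z = -h.schedule_steepness * (epoch - h.schedule_midpoint)
    return h.lr0 / (1.0 + np.exp(-z))


def train_cnn(net: Network, X, y, loss: LossConfig, h: Hyperparameters) -> pd.DataFrame:
    """Train the network in place; returns the per-epoch history.

    Dropout is active only here; after every Adam update the max-norm
    constraint renormalizes any weight vector exceeding the cap.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), y] = 1.0
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(h.seed), 47])))
    opt = Adam(net, beta1=h.adam_beta1, beta2=h.adam_beta2, eps=h.adam_eps)
    history = []
    for epoch in range(h.epochs):
        lr = learning_rate_schedule(h, epoch)
        order = rng.permutation(len(y))
        losses = []
        for start in range(0, len(y), h.batch_size):
            idx = order[start : start + h.batch_size]
            xb, yb = X[idx], Y[idx]
            probs = net.forward(xb, train=True)
            batch_loss = weighted_cross_entropy(yb, probs, loss)
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (lr={lr:.2e}); "
                    "reduce lr0 or inspect the input scaling"
                )
            alpha_row = (loss.alpha[None, :] * yb).sum(axis=1, keepdims=True)
            grad = alpha_row * (probs - yb) / len(idx)
            for layer in reversed(net.layers):
                grad = layer.backward(grad)
            if lr > 0:
                opt.step(lr)
                net.apply_max_norm(h.max_norm)
            losses.append(batch_loss)
        history.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
    return pd.DataFrame(history)


def predict(net: Network, X):
    """Class probabilities and hard labels (tie at 0.5 resolved to FGC)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1:] != (N_SAMPLES, 3):
        raise ValueError(f"expected (*, {N_SAMPLES}, 3) input, got {X.shape}")
    proba = net.forward(X, train=False)
    labels = (proba[:, 1] > 0.5).astype(int)
    if single:
        return proba[0], int(labels[0])
    return proba, labels


# ---------------------------------------------------------------------------
# model / results objects


class GaitCycleCNN:
    """CNN classifier of pre-FOG vs functional gait cycles.

    Parameters
    ----------
    X : (N, 101, 3) array of preprocessed cycles in [-1, 1]
    y : (N,) int labels, 1 = pre-FOG, 0 = FGC
    subjects : optional (N,) subject identifiers, carried into results
    hyperparameters : optional Hyperparameters (defaults used otherwise)
    """

    def __init__(self, X, y, subjects=None, hyperparameters: Hyperparameters | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.subjects = None if subjects is None else np.asarray(subjects, dtype=object)
        self.hyperparameters = hyperparameters or Hyperparameters()

    @classmethod
    def from_dataset(cls, dataset, hyperparameters: Hyperparameters | None = None):
        """Build from a MatchedDataset (all cycles, matched or not)."""
        from .preprocessing import dataset_arrays

        X, y, subjects = dataset_arrays(dataset.cycles)
        return cls(X, y, subjects=subjects, hyperparameters=hyperparameters)

    def fit(self, seed: int | None = None) -> "CNNResults":
        h = self.hyperparameters
        if seed is not None:
            h = dataclasses.replace(h, seed=int(seed))
        loss = class_weights(self.y)
        net = build_cnn(h)
        history = train_cnn(net, self.X, self.y, loss, h)
        return CNNResults(self, net, h, loss, history)


class CNNResults:
    """Fitted CNN: trained network, history, prediction and attribution."""

    def __init__(self, model: GaitCycleCNN, network: Network, h: Hyperparameters,
                 loss: LossConfig, history: pd.DataFrame):
        self.model = model
        self.network = network
        self.hyperparameters = h
        self.loss_config = loss
        self.history = history

    def predict(self, X):
        return predict(self.network, X)

    def relevance(self, cycle_values, target_class: str = "pre-FOG", epsilon: float = 1e-4):
        from .lrp import lrp_epsilon

        return lrp_epsilon(self.network, cycle_values, target_class, epsilon)

    def training_accuracy(self) -> float:
        _, labels = self.predict(self.model.X)
        return float((labels == self.model.y).mean())

    def summary(self) -> str:
        h = self.hyperparameters
        lines = [
            "Gait-cycle CNN results",
            "=" * 54,
            f"{'observations':28s}{len(self.model.y):>10d}",
            f"{'pre-FOG / FGC':28s}"
            f"{(self.model.y == 1).sum():>5d}/{(self.model.y == 0).sum():<5d}",
            f"{'conv blocks':28s}{h.n_blocks:>10d}",
            f"{'filters / kernel / pool':28s}{h.filters:>4d}/{h.kernel}/{h.pool_width}",
            f"{'trainable parameters':28s}{self.network.n_parameters():>10d}",
            f"{'dropout / max-norm':28s}{h.dropout:>7.2f}/{h.max_norm:.2f}",
            f"{'class weights (FGC, preFOG)':28s}"
            f"{self.loss_config.alpha[0]:>6.3f},{self.loss_config.alpha[1]:.3f}",
            f"{'epochs':28s}{h.epochs:>10d}",
            f"{'final training loss':28s}{self.history['loss'].iloc[-1]:>10.4f}",
            f"{'training accuracy':28s}{100 * self.training_accuracy():>9.1f}%",
            "=" * 54,
        ]
        return "\n".join(lines)


class LinearSVMBaseline:
    """Linear support-vector baseline on flattened 303-sample cycles."""

    def __init__(self, X, y, C: float = 0.01, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.C = C
        self.seed = int(seed)

    def fit(self) -> "SVMResults":
        if len(np.unique(self.y)) < 2:
            raise ValueError("training data must contain both classes")
        flat = self.X.reshape(len(self.y), -1)
        clf = LinearSVC(C=self.C, random_state=self.seed)
        clf.fit(flat, self.y)
        return SVMResults(self, clf)


class SVMResults:
    def __init__(self, model: LinearSVMBaseline, classifier: LinearSVC):
        self.model = model
        self.classifier = classifier

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        flat = X.reshape(X.shape[0], -1)
        return self.classifier.predict(flat).astype(int)

    def summary(self) -> str:
        return (
            "Linear SVM baseline\n"
            f"  C = {self.model.C}\n"
            f"  coefficients: {self.classifier.coef_.shape}\n"
            f"  training accuracy: "
            f"{100 * (self.predict(self.model.X) == self.model.y).mean():.1f}%"
        )


# ---------------------------------------------------------------------------
# hyperparameter search

#: default search space, spanning small architectures appropriate for ~100
#: training cycles of 101 samples
DEFAULT_SPACE = {
    "filters": ("choice", [4, 8, 16, 32]),
    "kernel": ("choice", [5, 9, 15, 25]),
    "n_blocks": ("choice", [1, 2, 3]),
    "dropout": ("uniform", 0.0, 0.6),
    "lr0": ("loguniform", 1e-4, 1e-2),
}


def sample_hyperparameters(space: dict, rng, base: Hyperparameters | None = None) -> Hyperparameters:
    """Draw one candidate from a search space.

    Space entries map a Hyperparameters field to ("choice", values),
    ("uniform", lo, hi) or ("loguniform", lo, hi).
    """
    base = base or Hyperparameters()
    draw = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "choice":
            val = spec[1][int(rng.integers(len(spec[1])))]
        elif kind == "uniform":
            val = float(rng.uniform(spec[1], spec[2]))
        elif kind == "loguniform":
            val = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        else:
            raise ValueError(f"unknown space entry kind {kind!r}")
        draw[name] = val
    return dataclasses.replace(base, **draw)


def random_search(space: dict, budget: int, rng, base=None):
    """Default sampling strategy: seeded i.i.d. draws from the space."""
    return [sample_hyperparameters(space, rng, base) for _ in range(budget)]


def inner_loso_accuracy(h: Hyperparameters, X, y, subjects) -> float:
    """Mean per-subject accuracy of leave-one-subject-out fits with fixed h."""
    subjects = np.asarray(subjects, dtype=object)
    accs = []
    for s in pd.unique(subjects):
        test = subjects == s
        train = ~test
        if len(np.unique(y[train])) < 2:
            continue
        net = build_cnn(h)
        train_cnn(net, X[train], y[train], class_weights(y[train]), h)
        _, labels = predict(net, X[test])
        accs.append(float((labels == y[test]).mean()))
    if not accs:
        raise ValueError("no valid inner folds (need both classes outside each subject)")
    return float(np.mean(accs))


def tune_hyperparameters(X, y, subjects, space: dict | None = None, budget: int = 4,
                         seed: int = 0, strategy=None,
                         base: Hyperparameters | None = None) -> Hyperparameters:
    """Select hyperparameters by inner leave-one-subject-out accuracy.

    ``strategy(space, budget, rng, base)`` proposes candidate sets; the
    default is a seeded random search. The candidate with the highest mean
    inner accuracy wins; ties go to the first one evaluated.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space if space is not None else DEFAULT_SPACE
    if not space:
        raise ValueError("empty search space")
    if len(pd.unique(np.asarray(subjects, dtype=object))) < 2:
        raise ValueError("need >= 2 inner subjects for leave-one-subject-out tuning")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 61])))
    strategy = strategy or random_search
    candidates = strategy(space, budget, rng, base)
    best_h, best_acc = None, -np.inf
    for h in candidates:
        acc = inner_loso_accuracy(h, X, y, subjects)
        if acc > best_acc:
            best_h, best_acc = h, acc
    return best_h
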