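"""Cost-sensitive mini-batch training for the CNN classifiers.

The loop follows the study protocol this package reproduces: Adadelta with
learning rate 0.5, batch size 32, 20 epochs, dropout 0.5 on the penultimate
feature vector, conv weights initialized U(-0.01, 0.01), and each filter's
weight vector projected back to max-norm 3 after every update.  Class
imbalance is handled by weighting each sample's cross-entropy term with
``1 / n_class`` so false predictions on the minority class cost more.

In the combined model the embedding table is shared by both branches but
fine-tuned only with gradients arriving from the word branch; the padding
row stays frozen at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ModelParams, batch_backward, batch_forward

__all__ = [
    "TrainConfig",
    "ClassWeights",
    "compute_class_weights",
    "weighted_cross_entropy",
    "Adadelta",
    "fit",
]

_EPS_PROB = 1e-12  # probability clamp for the log terms


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.5
    batch_size: int = 32
    epochs: int = 20
    dropout: float = 0.5
    max_norm: float = 3.0
    init_range: float = 0.01
    class_weighting: bool = True
    trainable_embeddings: bool = True
    rho: float = 0.95  # Adadelta decay (published default)
    eps: float = 1e-6  # Adadelta epsilon (published default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_norm <= 0:
            raise ValueError("learning_rate and max_norm must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights, 1/#samples of the class."""

    negative: float
    positive: float

    def for_labels(self, y: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(y) == 1, self.positive, self.negative)


def compute_class_weights(n_negative: int, n_positive: int) -> ClassWeights:
    if n_negative < 1 or n_positive < 1:
        raise ValueError("every class needs at least one sample")
    return ClassWeights(negative=1.0 / n_negative, positive=1.0 / n_positive)


def weighted_cross_entropy(p, y, weight=1.0) -> np.ndarray:
    """Elementwise -w_y [y log p + (1-y) log(1-p)], probabilities clamped."""
    p = np.clip(np.asarray(p, dtype=float), _EPS_PROB, 1.0 - _EPS_PROB)
    y = np.asarray(y, dtype=float)
    return -np.asarray(weight) * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


class Adadelta:
    """Adadelta for one parameter array (accumulated squared grads/deltas)."""

    def __init__(self, shape, lr: float, rho: float, eps: float):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.acc_g = np.zeros(shape, dtype=np.float32)
        self.acc_d = np.zeros(shape, dtype=np.float32)

    def step(self, grad: np.ndarray) -> np.ndarray:
        """Return the update to *add* to the parameter."""
        self.acc_g = self.rho * self.acc_g + (1 - self.rho) * grad**2
        delta = -np.sqrt((self.acc_d + self.eps) / (self.acc_g + self.eps)) * grad
        self.acc_d = self.rho * self.acc_d + (1 - self.rho) * delta**2
        return self.lr * delta


def _project_max_norm(groups, max_norm: float) -> None:
    for g in groups:
        norms = np.linalg.norm(g.weights, axis=1, keepdims=True)
        scale = np.minimum(1.0, max_norm / np.maximum(norms, 1e-12))
        g.weights *= scale


def _forward_all(params, X, batch_size=256):
    """Deterministic (no-dropout) probabilities over a whole dataset."""
    probs = []
    for lo in range(0, len(X["word"]), batch_size):
        sl = slice(lo, lo + batch_size)
        p, _ = batch_forward(
            params,
            X["word"][sl],
            None if X.get("sent") is None else X["sent"][sl],
            None if X.get("sent_len") is None else X["sent_len"][sl],
            dropout_rng=None,
        )
        probs.append(p)
    return np.concatenate(probs)


def fit(
    model: ModelParams,
    X_train: dict,
    y_train: np.ndarray,
    config: TrainConfig = TrainConfig(),
    X_valid: dict | None = None,
    y_valid: np.ndarray | None = None,
):
    """Train *model* in place; returns ``(model, trace)``.

    ``X_train`` is a dict with keys ``word`` (B, L index matrix) and, for the
    combined model, ``sent`` (B, S, W) and ``sent_len`` (B, S).  The trace is
    a list of per-epoch ``{"epoch", "train_loss", "valid_loss"}`` records
    (validation entries are None without a validation set).
    """
    y_train = np.asarray(y_train, dtype=float)
    n = len(y_train)
    if n == 0:
        raise ValueError("empty training set")
    n_pos = int(y_train.sum())
    if config.class_weighting:
        weights = compute_class_weights(n - n_pos, max(n_pos, 1))
        if n_pos == 0:
            raise ValueError("class weighting requires both classes present")
    else:
        weights = ClassWeights(1.0, 1.0)
    w_sample = weights.for_labels(y_train)

    rng = np.random.default_rng(config.seed)
    drop_rng = np.random.default_rng(rng.integers(2**31)) if config.dropout > 0 else None

    opts = {
        "w_out": Adadelta(model.w_out.shape, config.learning_rate, config.rho, config.eps),
        "b_out": Adadelta((), config.learning_rate, config.rho, config.eps),
    }
    for branch in ("word_groups", "sent_groups"):
        for i, g in enumerate(getattr(model, branch)):
            opts[(branch, i, "w")] = Adadelta(
                g.weights.shape, config.learning_rate, config.rho, config.eps
            )
            opts[(branch, i, "b")] = Adadelta(
                g.bias.shape, config.learning_rate, config.rho, config.eps
            )
    if config.trainable_embeddings:
        opts["embedding"] = Adadelta(
            model.embedding.shape, config.learning_rate, config.rho, config.eps
        )

    has_sent = model.has_sentence_branch
    # Per-batch suffix trim: padding embeddings are frozen at zero, so every
    # all-padding suffix window contributes the same relu(bias) to each map;
    # trimming to the batch's longest note (plus one all-pad window's worth)
    # preserves the pooled features while cutting conv cost.
    word_all = X_train["word"]
    from .preprocessing import PAD_INDEX as _PAD
    word_len = (word_all != _PAD).sum(axis=1)
    max_wl = max(g.filter_length for g in model.word_groups)
    if has_sent:
        sent_count = (X_train["sent_len"] > 0).sum(axis=1)
        max_sl = max(g.filter_length for g in model.sent_groups)
    trace = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            B = len(idx)
            Lb = min(word_all.shape[1], int(word_len[idx].max()) + max_wl)
            if has_sent:
                Sb = min(
                    X_train["sent"].shape[1],
                    max(int(sent_count[idx].max()) + max_sl, max_sl),
                )
            p, cache = batch_forward(
                model,
                word_all[idx][:, :Lb],
                X_train["sent"][idx][:, :Sb] if has_sent else None,
                X_train["sent_len"][idx][:, :Sb] if has_sent else None,
                dropout_rng=drop_rng,
            )
            yb, wb = y_train[idx], w_sample[idx]
            w_sum = wb.sum()
            loss = float(weighted_cross_entropy(p, yb, wb).sum() / w_sum)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss"
                )
            epoch_losses.append(loss)
            dlogits = wb * (p - yb) / w_sum  # d(weighted-mean BCE)/d logit
            grads = batch_backward(model, cache, dlogits)

            model.w_out += opts["w_out"].step(grads["w_out"])
            model.b_out += opts["b_out"].step(np.asarray(grads["b_out"]))
            for branch in ("word_groups", "sent_groups"):
                for i, g in enumerate(getattr(model, branch)):
                    gg = grads[branch][i]
                    g.weights += opts[(branch, i, "w")].step(gg["weights"])
                    g.bias += opts[(branch, i, "b")].step(gg["bias"])
            if config.trainable_embeddings:
                model.embedding += opts["embedding"].step(grads["embedding"])
            _project_max_norm(model.word_groups, config.max_norm)
            _project_max_norm(model.sent_groups, config.max_norm)

        valid_loss = None
        if X_valid is not None and y_valid is not None and len(y_valid):
            pv = _forward_all(model, X_valid)
            wv = weights.for_labels(y_valid)
            valid_loss = float(
                weighted_cross_entropy(pv, y_valid, wv).sum() / wv.sum()
            )
        trace.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else None,
                "valid_loss": valid_loss,
            }
        )
    return model, trace
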