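"""A small fully connected softmax classifier trained with Adam.

The architecture mirrors the study's detector: input (108 features) ->
64 ReLU -> 40 ReLU -> 2 softmax, categorical cross-entropy over the two
classes, Adam with an initial learning rate of 0.01 decayed as
lr_t = lr0 / (1 + decay * t) per step (decay 0.001), mini-batches of 2, and
inverted dropout (keep probability 0.5) on the hidden activations during
training. Written on numpy so training is exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ClassifierConfig:
    layer_sizes: tuple = (64, 40, 2)
    batch_size: int = 2
    learning_rate: float = 0.01
    lr_decay: float = 0.001
    dropout_keep: float = 0.5
    epochs: int = 100
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ValueError("dropout_keep must be in (0, 1]")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid optimizer settings")


class DenseClassifier:
    """Two-hidden-layer softmax network; binary (two-class) labels only."""

    def __init__(self, n_features: int, config: ClassifierConfig | None = None):
        self.config = ClassifierConfig() if config is None else config
        self.n_features = n_features
        self.loss_history: list[float] = []
        rng = np.random.default_rng(self.config.seed)
        sizes = (n_features, *self.config.layer_sizes)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization for the ReLU stack
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._rng = rng

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def _forward(self, X, train: bool):
        keep = self.config.dropout_keep
        acts = [X]
        masks = []
        a = X
        n_layers = len(self.weights)
        for li in range(n_layers):
            z = a @ self.weights[li] + self.biases[li]
            if li < n_layers - 1:
                a = np.maximum(z, 0.0)
                if train and keep < 1.0:
                    mask = (self._rng.random(a.shape) < keep) / keep
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
            else:
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                a = e / e.sum(axis=1, keepdims=True)
            acts.append(a)
        return acts, masks

    def fit(self, X, y):
        """Train on features X (n, d) and integer labels y in {0, 1}."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 classes, got {len(classes)}")
        self.classes_ = classes
        yi = np.searchsorted(classes, y)
        onehot = np.eye(2)[yi]

        cfg = self.config
        m = [np.zeros_like(w) for w in self.weights] + [np.zeros_like(b) for b in self.biases]
        v = [np.zeros_like(p) for p in m]
        step = 0
        n = len(X)
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                Xb, Yb = X[batch], onehot[batch]
                acts, masks = self._forward(Xb, train=True)
                probs = acts[-1]
                epoch_loss += -np.sum(Yb * np.log(probs + 1e-12))
                grads_w, grads_b = self._backward(acts, masks, Yb)
                step += 1
                lr = cfg.learning_rate / (1.0 + cfg.lr_decay * step)
                params = self.weights + self.biases
                grads = grads_w + grads_b
                for pi, (p, g) in enumerate(zip(params, grads)):
                    m[pi] = cfg.adam_beta1 * m[pi] + (1 - cfg.adam_beta1) * g
                    v[pi] = cfg.adam_beta2 * v[pi] + (1 - cfg.adam_beta2) * g * g
                    mhat = m[pi] / (1 - cfg.adam_beta1**step)
                    vhat = v[pi] / (1 - cfg.adam_beta2**step)
                    p -= lr * mhat / (np.sqrt(vhat) + cfg.adam_eps)
            self.loss_history.append(epoch_loss / n)
        return self

    def _backward(self, acts, masks, Yb):
        nb = len(Yb)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = (acts[-1] - Yb) / nb  # softmax + CE gradient
        for li in range(len(self.weights) - 1, -1, -1):
            grads_w[li] = acts[li].T @ delta
            grads_b[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.weights[li].T
                if masks[li - 1] is not None:
                    delta = delta * masks[li - 1]
                delta = delta * (acts[li] > 0)
        return grads_w, grads_b

    def predict_proba(self, X):
        acts, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return acts[-1]

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
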