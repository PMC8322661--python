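"""Greedy DBN pre-training and the discriminative network built from it.

Pre-training stacks RBMs: the first is trained on the (label-free) input
rows, each further RBM on the previous layer's hidden conditional means.
The resulting weights initialize a feed-forward classifier whose hidden
part mirrors the DBN, followed by an extra fully connected sigmoid layer
and a two-class softmax output.  Fine-tuning minimizes cross-entropy by
mini-batch SGD with early stopping on a validation set: training stops
once the validation loss has not improved for ``patience`` epochs and the
best-validation weights (including the untrained starting point) are
restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rbm import RBMParams, TrainConfig, hidden_conditional, init_rbm, sigmoid, train_rbm


@dataclass
class DBNModel:
    layers: list[RBMParams]

    def __post_init__(self) -> None:
        for lower, upper in zip(self.layers, self.layers[1:]):
            if lower.n_hidden != upper.n_visible:
                raise ValueError("adjacent DBN layer dimensions do not chain")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Stacked hidden conditional means of the input rows."""
        out = np.atleast_2d(np.asarray(X, dtype=float))
        for layer in self.layers:
            out = hidden_conditional(layer, out)
        return out


@dataclass
class FineTuneConfig:
    learning_rate: float = 0.1
    batch_size: int = 25
    max_epochs: int = 500
    patience: int = 25
    seed: int = 0


@dataclass
class FineTunedNet:
    """Sigmoid MLP with a two-class softmax head.

    ``hidden`` holds every sigmoid layer (DBN-copied layers plus the extra
    fully connected sigmoid head); ``softmax_W``/``softmax_b`` map the last
    sigmoid activation to class logits.
    """

    hidden: list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...]
    softmax_W: np.ndarray  # (width_last, 2)
    softmax_b: np.ndarray  # (2,)
    history: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.hidden[0][0].shape[0]

    @property
    def head_width(self) -> int:
        return self.hidden[-1][0].shape[1]

    def copy(self) -> "FineTunedNet":
        return FineTunedNet(
            [(W.copy(), b.copy()) for W, b in self.hidden],
            self.softmax_W.copy(),
            self.softmax_b.copy(),
            dict(self.history),
        )

    def hidden_forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations after each sigmoid layer (last = pre-softmax features)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        acts = []
        a = X
        for W, b in self.hidden:
            a = sigmoid(a @ W + b)
            acts.append(a)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        feats = self.hidden_forward(X)[-1]
        return softmax(feats @ self.softmax_W + self.softmax_b)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(proba: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-probability of the true class."""
    eps = 1e-12
    return float(-np.mean(np.log(proba[np.arange(len(y)), y] + eps)))


def pretrain_dbn(
    data: np.ndarray, layer_sizes: list[int], cfg: TrainConfig
) -> DBNModel:
    """Greedy layer-wise RBM stacking on labeled + unlabeled rows (no labels).

    Layer t's training data are layer t-1's hidden conditional means; every
    layer uses the same CD-k configuration with a layer-offset seed.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty pre-training data")
    layers: list[RBMParams] = []
    current = data
    for depth, n_hidden in enumerate(layer_sizes):
        layer_cfg = TrainConfig(
            k=cfg.k,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            weight_decay=cfg.weight_decay,
            epochs=cfg.epochs,
            seed=cfg.seed + depth,
        )
        rbm = train_rbm(current, n_hidden, layer_cfg)
        layers.append(rbm)
        current = hidden_conditional(rbm, current)
    return DBNModel(layers)


def _fresh_layer(
    rng: np.random.Generator, d_in: int, d_out: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fan-in-scaled Gaussian weights (keeps sigmoid pre-activations O(1))."""
    return rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, d_out)), np.zeros(d_out)


def init_classifier_from_dbn(
    dbn: DBNModel, head_width: int = 15, seed: int = 0
) -> FineTunedNet:
    """Copy DBN weights into a classifier and seed a fresh sigmoid + softmax head."""
    rng = np.random.default_rng(seed)
    hidden = [(layer.W.copy(), layer.c.copy()) for layer in dbn.layers]
    last_width = dbn.layers[-1].n_hidden
    hidden.append(_fresh_layer(rng, last_width, head_width))
    softmax_W, softmax_b = _fresh_layer(rng, head_width, 2)
    return FineTunedNet(hidden=hidden, softmax_W=softmax_W, softmax_b=softmax_b)


def init_classifier_random(
    n_features: int,
    layer_sizes: list[int],
    head_width: int = 15,
    seed: int = 0,
) -> FineTunedNet:
    """Identically shaped classifier with random (non-pre-trained) weights."""
    rng = np.random.default_rng(seed)
    dims = [n_features] + list(layer_sizes) + [head_width]
    hidden = [_fresh_layer(rng, d_in, d_out) for d_in, d_out in zip(dims, dims[1:])]
    softmax_W, softmax_b = _fresh_layer(rng, head_width, 2)
    return FineTunedNet(hidden=hidden, softmax_W=softmax_W, softmax_b=softmax_b)


def loss_and_gradients(
    net: FineTunedNet, X: np.ndarray, y: np.ndarray
) -> tuple[float, list[tuple[np.ndarray, np.ndarray]], np.ndarray, np.ndarray]:
    """Mean cross-entropy and its gradients for every weight and bias."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = len(X)
    acts = net.hidden_forward(X)
    feats = acts[-1]
    proba = softmax(feats @ net.softmax_W + net.softmax_b)
    loss = cross_entropy(proba, y)
    onehot = np.eye(2)[y]
    delta = (proba - onehot) / n  # d loss / d logits
    g_soft_W = feats.T @ delta
    g_soft_b = delta.sum(axis=0)
    g_hidden: list[tuple[np.ndarray, np.ndarray]] = [None] * len(net.hidden)
    back = delta @ net.softmax_W.T
    for i in range(len(net.hidden) - 1, -1, -1):
        a = acts[i]
        pre = back * a * (1 - a)  # sigmoid derivative
        inp = X if i == 0 else acts[i - 1]
        g_hidden[i] = (inp.T @ pre, pre.sum(axis=0))
        if i > 0:
            back = pre @ net.hidden[i][0].T
    return loss, g_hidden, g_soft_W, g_soft_b


def _sgd_step(net: FineTunedNet, grads, g_soft_W, g_soft_b, lr: float) -> None:
    for (W, b), (gW, gb) in zip(net.hidden, grads):
        W -= lr * gW
        b -= lr * gb
    net.softmax_W -= lr * g_soft_W
    net.softmax_b -= lr * g_soft_b


def fine_tune(
    net: FineTunedNet,
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    cfg: FineTuneConfig | None = None,
) -> FineTunedNet:
    """Early-stopped SGD on cross-entropy; returns the best-validation weights."""
    cfg = cfg or FineTuneConfig()
    X, y = np.atleast_2d(np.asarray(train[0], dtype=float)), np.asarray(
        train[1], dtype=int
    )
    Xv, yv = np.atleast_2d(np.asarray(validation[0], dtype=float)), np.asarray(
        validation[1], dtype=int
    )
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(Xv) == 0:
        raise ValueError("validation set is empty")
    rng = np.random.default_rng(cfg.seed)
    net = net.copy()
    best = net.copy()
    best_val = cross_entropy(best.predict_proba(Xv), yv)
    train_losses: list[float] = []
    val_losses: list[float] = [best_val]
    since_improved = 0
    n = len(X)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _, g_hidden, g_sW, g_sb = loss_and_gradients(net, X[idx], y[idx])
            _sgd_step(net, g_hidden, g_sW, g_sb, cfg.learning_rate)
        train_losses.append(cross_entropy(net.predict_proba(X), y))
        val_loss = cross_entropy(net.predict_proba(Xv), yv)
        val_losses.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best = net.copy()
            since_improved = 0
        else:
            since_improved += 1
            if since_improved > cfg.patience:
                break
    best.history = {
        "train_loss": train_losses,
        "val_loss": val_losses,
        "best_val_loss": best_val,
        "epochs_run": len(train_losses),
    }
    return best


def predict_proba(net: FineTunedNet, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix (samples x 2); rows sum to one."""
    return net.predict_proba(X)
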