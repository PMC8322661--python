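"""Bernoulli restricted Boltzmann machine with CD-k training.

The model places a Boltzmann distribution P(v, h) = exp(-E(v, h)) / Z over
binary visible and hidden layers with energy

    E(v, h) = -b.v - c.h - v' W h,

whose conditionals factorize: P(h_j = 1 | v) = sigmoid(c_j + v.W[:, j]) and
P(v_i = 1 | h) = sigmoid(b_i + W[i, :].h).  Continuous inputs in [0, 1]
are treated as Bernoulli means (mean-field visible states).

Training uses contrastive divergence: positive statistics come from the
data-clamped hidden conditionals; negative statistics from a k-step Gibbs
chain started at the data batch.  Visible states along the chain are
sampled; the terminal hidden factor uses conditional probabilities
(Rao-Blackwellized), the common CD recipe.  For small models the exact
partition function, likelihood and gradient are available by enumeration
and serve as test oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

_ENUM_LIMIT = 20  # max n_visible + n_hidden for exact enumeration


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBMParams:
    W: np.ndarray  # (n_visible, n_hidden)
    b: np.ndarray  # visible bias
    c: np.ndarray  # hidden bias

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.W.shape != (self.b.size, self.c.size):
            raise ValueError("inconsistent RBM parameter shapes")
        if not (
            np.all(np.isfinite(self.W))
            and np.all(np.isfinite(self.b))
            and np.all(np.isfinite(self.c))
        ):
            raise ValueError("non-finite RBM parameters")

    @property
    def n_visible(self) -> int:
        return self.b.size

    @property
    def n_hidden(self) -> int:
        return self.c.size

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b.copy(), self.c.copy())

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"W": self.W.tolist(), "b": self.b.tolist(), "c": self.c.tolist()},
                fh,
            )

    @classmethod
    def load(cls, path: str | Path) -> "RBMParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["W"]), np.array(d["b"]), np.array(d["c"]))


@dataclass
class TrainConfig:
    k: int = 1
    learning_rate: float = 0.05
    batch_size: int = 25
    weight_decay: float = 0.001
    epochs: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


def init_rbm(
    n_visible: int, n_hidden: int, rng: np.random.Generator, scale: float = 0.01
) -> RBMParams:
    """Small-Gaussian weight initialization, zero biases."""
    return RBMParams(
        W=rng.normal(0.0, scale, size=(n_visible, n_hidden)),
        b=np.zeros(n_visible),
        c=np.zeros(n_hidden),
    )


def hidden_conditional(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v) for one vector or a batch of rows."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != rbm.n_visible:
        raise ValueError("visible vector has wrong length")
    return sigmoid(rbm.c + v @ rbm.W)


def visible_conditional(rbm: RBMParams, h: np.ndarray) -> np.ndarray:
    """P(v_i = 1 | h) for one vector or a batch of rows."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != rbm.n_hidden:
        raise ValueError("hidden vector has wrong length")
    return sigmoid(rbm.b + h @ rbm.W.T)


def free_energy(rbm: RBMParams, v: np.ndarray) -> np.ndarray:
    """F(v) = -b.v - sum_j log(1 + exp(c_j + v.W[:, j])); P(v) prop exp(-F)."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    act = rbm.c + v @ rbm.W
    F = -(v @ rbm.b) - np.logaddexp(0.0, act).sum(axis=1)
    return F if F.size > 1 else F.reshape(())


def _all_states(n: int) -> np.ndarray:
    """All binary vectors of length n as a (2^n, n) array."""
    return np.array(list(product((0.0, 1.0), repeat=n)))


def log_partition(rbm: RBMParams) -> float:
    """log Z by enumerating visible states and marginalizing hidden analytically."""
    if rbm.n_visible + rbm.n_hidden > _ENUM_LIMIT:
        raise ValueError("model too large for exact enumeration")
    V = _all_states(rbm.n_visible)
    F = free_energy(rbm, V)
    m = float(np.max(-F))
    return m + float(np.log(np.sum(np.exp(-F - m))))


def enumerate_joint(rbm: RBMParams) -> np.ndarray:
    """Full joint table P(v, h), shape (2^n_visible, 2^n_hidden)."""
    if rbm.n_visible + rbm.n_hidden > _ENUM_LIMIT:
        raise ValueError("model too large for exact enumeration")
    V = _all_states(rbm.n_visible)
    H = _all_states(rbm.n_hidden)
    energy = -(V @ rbm.b)[:, None] - (H @ rbm.c)[None, :] - V @ rbm.W @ H.T
    un = np.exp(-energy)
    return un / un.sum()


def exact_log_likelihood(rbm: RBMParams, data: np.ndarray) -> float:
    """Mean log P(v) over data rows, with Z by full enumeration."""
    if rbm.n_visible + rbm.n_hidden > _ENUM_LIMIT:
        raise ValueError("model too large for exact enumeration")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    logZ = log_partition(rbm)
    return float(np.mean(-free_energy(rbm, data) - logZ))


def exact_gradient(
    rbm: RBMParams, data: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradient of the mean log-likelihood (dW, db, dc) by enumeration."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    H_data = hidden_conditional(rbm, data)
    pos_W = data.T @ H_data / len(data)
    pos_b = data.mean(axis=0)
    pos_c = H_data.mean(axis=0)
    V = _all_states(rbm.n_visible)
    F = free_energy(rbm, V)
    p_v = np.exp(-F - np.max(-F))
    p_v = p_v / p_v.sum()
    H_model = hidden_conditional(rbm, V)
    neg_W = (V * p_v[:, None]).T @ H_model
    neg_b = p_v @ V
    neg_c = p_v @ H_model
    return pos_W - neg_W, pos_b - neg_b, pos_c - neg_c


def cd_statistics(
    rbm: RBMParams, batch: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One CD-k gradient estimate (dW, db, dc), averaged over the batch."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    n = len(batch)
    H_pos = hidden_conditional(rbm, batch)
    v = batch
    h_prob = H_pos
    for _ in range(k):
        h = (rng.random(h_prob.shape) < h_prob).astype(float)
        v_prob = visible_conditional(rbm, h)
        v = (rng.random(v_prob.shape) < v_prob).astype(float)
        h_prob = hidden_conditional(rbm, v)
    dW = (batch.T @ H_pos - v.T @ h_prob) / n
    db = (batch - v).mean(axis=0)
    dc = (H_pos - h_prob).mean(axis=0)
    return dW, db, dc


def cd_k_update(
    rbm: RBMParams,
    batch: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> RBMParams:
    """Apply one CD-k stochastic gradient step (weight decay on W only)."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    dW, db, dc = cd_statistics(rbm, batch, cfg.k, rng)
    lr = cfg.learning_rate
    return RBMParams(
        W=rbm.W + lr * (dW - cfg.weight_decay * rbm.W),
        b=rbm.b + lr * db,
        c=rbm.c + lr * dc,
    )


def train_rbm(
    data: np.ndarray, n_hidden: int, cfg: TrainConfig
) -> RBMParams:
    """Train an RBM by mini-batch CD-k on rows of ``data`` (values in [0, 1])."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    rbm = init_rbm(data.shape[1], n_hidden, rng)
    n = len(data)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = data[order[start : start + cfg.batch_size]]
            rbm = cd_k_update(rbm, batch, cfg, rng)
    return rbm


def gibbs_visible_marginal(
    rbm: RBMParams, n_steps: int, rng: np.random.Generator, burn_in: int = 100
) -> dict[tuple[int, ...], float]:
    """Empirical visible-state frequencies from a single long Gibbs chain."""
    v = (rng.random(rbm.n_visible) < 0.5).astype(float)
    counts: dict[tuple[int, ...], int] = {}
    for step in range(burn_in + n_steps):
        h_prob = hidden_conditional(rbm, v)
        h = (rng.random(rbm.n_hidden) < h_prob).astype(float)
        v_prob = visible_conditional(rbm, h)
        v = (rng.random(rbm.n_visible) < v_prob).astype(float)
        if step >= burn_in:
            key = tuple(int(x) for x in v)
            counts[key] = counts.get(key, 0) + 1
    return {k: c / n_steps for k, c in counts.items()}


def reconstruction_cross_entropy(rbm: RBMParams, data: np.ndarray) -> float:
    """Mean cross-entropy between data and its one-step reconstruction."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    h = hidden_conditional(rbm, data)
    recon = visible_conditional(rbm, h)
    eps = 1e-12
    ce = -(data * np.log(recon + eps) + (1 - data) * np.log(1 - recon + eps))
    return float(ce.sum(axis=1).mean())
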