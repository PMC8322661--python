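"""Pairwise intermediate-feature fusion of single-modality networks.

Two fine-tuned single-modality classifiers are joined by dropping their
softmax outputs, concatenating the activations of their sigmoid heads
(the pre-softmax features) and stacking one fresh softmax layer on top.
The combined model is then trained end-to-end: branch weights are warm
started from the single-modality networks and updated jointly with the
head under the cross-entropy loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dbn import (
    FineTunedNet,
    FineTuneConfig,
    cross_entropy,
    softmax,
)


def extract_intermediate_features(net: FineTunedNet, X: np.ndarray) -> np.ndarray:
    """Sigmoid-head activations (the features fed to the softmax), in (0, 1)."""
    return net.hidden_forward(X)[-1]


@dataclass
class FusionModel:
    branch_a: FineTunedNet  # softmax part unused
    branch_b: FineTunedNet
    joint_W: np.ndarray  # (width_a + width_b, 2)
    joint_b: np.ndarray
    modality_pair: tuple[str, str] = ("a", "b")

    def copy(self) -> "FusionModel":
        return FusionModel(
            self.branch_a.copy(),
            self.branch_b.copy(),
            self.joint_W.copy(),
            self.joint_b.copy(),
            self.modality_pair,
        )

    def _features(self, Xa: np.ndarray, Xb: np.ndarray) -> tuple[list, list, np.ndarray]:
        acts_a = self.branch_a.hidden_forward(Xa)
        acts_b = self.branch_b.hidden_forward(Xb)
        return acts_a, acts_b, np.hstack([acts_a[-1], acts_b[-1]])

    def predict_proba(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        if len(np.atleast_2d(Xa)) != len(np.atleast_2d(Xb)):
            raise ValueError("modality sample counts differ")
        _, _, feats = self._features(Xa, Xb)
        return softmax(feats @ self.joint_W + self.joint_b)

    def predict(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(Xa, Xb), axis=1)


def build_fusion_model(
    net_a: FineTunedNet,
    net_b: FineTunedNet,
    seed: int = 0,
    modality_pair: tuple[str, str] = ("a", "b"),
) -> FusionModel:
    """Warm-start both branches from trained nets; freshly seed the joint head."""
    from .dbn import _fresh_layer

    rng = np.random.default_rng(seed)
    width = net_a.head_width + net_b.head_width
    joint_W, joint_b = _fresh_layer(rng, width, 2)
    return FusionModel(
        branch_a=net_a.copy(),
        branch_b=net_b.copy(),
        joint_W=joint_W,
        joint_b=joint_b,
        modality_pair=modality_pair,
    )


def _fusion_loss_and_gradients(model: FusionModel, Xa, Xb, y):
    n = len(Xa)
    acts_a, acts_b, feats = model._features(Xa, Xb)
    proba = softmax(feats @ model.joint_W + model.joint_b)
    loss = cross_entropy(proba, y)
    onehot = np.eye(2)[y]
    delta = (proba - onehot) / n
    g_joint_W = feats.T @ delta
    g_joint_b = delta.sum(axis=0)
    back = delta @ model.joint_W.T
    wa = model.branch_a.head_width
    grads = {}
    for tag, branch, acts, X, back_b in (
        ("a", model.branch_a, acts_a, Xa, back[:, :wa]),
        ("b", model.branch_b, acts_b, Xb, back[:, wa:]),
    ):
        g_hidden = [None] * len(branch.hidden)
        bb = back_b
        for i in range(len(branch.hidden) - 1, -1, -1):
            a = acts[i]
            pre = bb * a * (1 - a)
            inp = X if i == 0 else acts[i - 1]
            g_hidden[i] = (inp.T @ pre, pre.sum(axis=0))
            if i > 0:
                bb = pre @ branch.hidden[i][0].T
        grads[tag] = g_hidden
    return loss, grads, g_joint_W, g_joint_b


def train_fusion(
    model: FusionModel,
    train: tuple[np.ndarray, np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray, np.ndarray],
    cfg: FineTuneConfig | None = None,
) -> FusionModel:
    """End-to-end SGD over both branches and the joint softmax head.

    ``train`` and ``validation`` are (X_modality_a, X_modality_b, y) triples
    restricted to samples present in both modalities.  Early stopping and
    best-weight restoration follow the single-modality fine-tuning rules.
    """
    cfg = cfg or FineTuneConfig()
    Xa, Xb, y = (np.atleast_2d(np.asarray(train[0], float)),
                 np.atleast_2d(np.asarray(train[1], float)),
                 np.asarray(train[2], int))
    Xav, Xbv, yv = (np.atleast_2d(np.asarray(validation[0], float)),
                    np.atleast_2d(np.asarray(validation[1], float)),
                    np.asarray(validation[2], int))
    if len(Xa) == 0:
        raise ValueError("no samples shared between the two modalities")
    if len(Xa) != len(Xb) or len(y) != len(Xa):
        raise ValueError("misaligned fusion training inputs")
    rng = np.random.default_rng(cfg.seed)
    model = model.copy()
    best = model.copy()
    best_val = cross_entropy(best.predict_proba(Xav, Xbv), yv)
    since_improved = 0
    n = len(Xa)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _, grads, g_jW, g_jb = _fusion_loss_and_gradients(
                model, Xa[idx], Xb[idx], y[idx]
            )
            for tag, branch in (("a", model.branch_a), ("b", model.branch_b)):
                for (W, b), (gW, gb) in zip(branch.hidden, grads[tag]):
                    W -= cfg.learning_rate * gW
                    b -= cfg.learning_rate * gb
            model.joint_W -= cfg.learning_rate * g_jW
            model.joint_b -= cfg.learning_rate * g_jb
        val_loss = cross_entropy(model.predict_proba(Xav, Xbv), yv)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best = model.copy()
            since_improved = 0
        else:
            since_improved += 1
            if since_improved > cfg.patience:
                break
    return best


def pairwise_improvement_matrix(
    single_acc: dict[str, float],
    pair_acc: dict[tuple[str, str], float],
) -> pd.DataFrame:
    """Accuracy deltas from adding a column modality to a row modality.

    cell(r, c) = accuracy(fused r+c) - accuracy(single r).  The diagonal is
    defined as zero; a missing pair leaves the cell NaN.  The matrix is not
    antisymmetric: cell(r, c) - cell(c, r) = accuracy(single c) -
    accuracy(single r).
    """
    mods = sorted(single_acc)
    mat = pd.DataFrame(np.nan, index=mods, columns=mods)
    for r in mods:
        mat.loc[r, r] = 0.0
    for (a, b), acc in pair_acc.items():
        if a not in single_acc or b not in single_acc:
            raise KeyError(f"pair ({a}, {b}) references unknown modality")
        mat.loc[a, b] = acc - single_acc[a]
        mat.loc[b, a] = acc - single_acc[b]
    return mat
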