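"""End-to-end single-modality pipelines: selection, scaling, model, predict.

Every pipeline follows the same contract so the evaluation protocols can
swap models freely::

    pipeline(X_train, y_train, X_test, X_unlab=None, X_val=None, y_val=None)
        -> predicted 0/1 labels for X_test

Feature selection (mRMR on discretized probes) and z-score parameters are
fit on the labeled training samples only and then applied to every other
matrix, so held-out samples can never influence the selected probe set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .baselines import train_lapsvm, train_linear_svm, GraphSpec
from .dbn import (
    FineTuneConfig,
    fine_tune,
    init_classifier_from_dbn,
    pretrain_dbn,
)
from .mrmr import discretize, mrmr_select, squash, zscore_apply, zscore_fit
from .rbm import TrainConfig


def _holdout_validation(y: np.ndarray, frac: float, rng: np.random.Generator):
    """Stratified boolean mask selecting a validation subset of the labels."""
    n = len(y)
    mask = np.zeros(n, bool)
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        take = max(1, int(np.floor(frac * len(members))))
        mask[rng.choice(members, size=take, replace=False)] = True
    if mask.all() or not mask.any():
        raise ValueError("cannot carve a validation subset from the training set")
    return mask


class _FeatureStage:
    """Shared mRMR + z-score front end (fit on labeled training data only)."""

    def __init__(self, n_features: int):
        self.n_features = n_features

    def fit(self, X_train: np.ndarray, y_train: np.ndarray) -> None:
        disc = discretize(np.asarray(X_train, float))
        sel = mrmr_select(disc, np.asarray(y_train, int), self.n_features)
        self.indices_ = np.asarray(sel.selected_indices, int)
        self.mean_, self.sd_ = zscore_fit(np.asarray(X_train, float)[:, self.indices_])

    def transform(self, X: np.ndarray | None) -> np.ndarray | None:
        if X is None or np.size(X) == 0:
            return None
        X = np.atleast_2d(np.asarray(X, float))
        return zscore_apply(X[:, self.indices_], self.mean_, self.sd_)


@dataclass
class DBNPipeline:
    """mRMR -> z-score -> logistic squash -> DBN pre-training -> fine-tuning."""

    n_features: int = 50
    layer_sizes: tuple[int, ...] = (15, 15)
    head_width: int = 15
    pretrain_cfg: TrainConfig = field(
        default_factory=lambda: TrainConfig(epochs=3000)
    )
    finetune_cfg: FineTuneConfig = field(default_factory=FineTuneConfig)
    val_frac: float = 0.15
    seed: int = 0
    pretrained: bool = True  # False: random initialization (ablation twin)

    def __call__(
        self,
        X_train,
        y_train,
        X_test,
        X_unlab=None,
        X_val=None,
        y_val=None,
    ) -> np.ndarray:
        net = self.fit(X_train, y_train, X_unlab, X_val, y_val)
        return self.predict(net, X_test)

    def fit(self, X_train, y_train, X_unlab=None, X_val=None, y_val=None):
        from .dbn import init_classifier_random

        y_train = np.asarray(y_train, int)
        stage = _FeatureStage(self.n_features)
        stage.fit(X_train, y_train)
        self.stage_ = stage
        Xt = squash(stage.transform(X_train))
        Xu = stage.transform(X_unlab)
        Xu = squash(Xu) if Xu is not None else None
        if X_val is not None and y_val is not None and len(np.atleast_1d(y_val)):
            Xv = squash(stage.transform(X_val))
            yv = np.asarray(y_val, int)
            Xtr, ytr = Xt, y_train
            pool = [Xt, Xv] if Xu is None else [Xt, Xv, Xu]
        else:
            rng = np.random.default_rng(self.seed)
            vmask = _holdout_validation(y_train, self.val_frac, rng)
            Xtr, ytr = Xt[~vmask], y_train[~vmask]
            Xv, yv = Xt[vmask], y_train[vmask]
            pool = [Xt] if Xu is None else [Xt, Xu]
        pretrain_pool = np.vstack(pool)
        if self.pretrained:
            cfg = replace(self.pretrain_cfg, seed=self.seed)
            dbn = pretrain_dbn(pretrain_pool, list(self.layer_sizes), cfg)
            net = init_classifier_from_dbn(
                dbn, head_width=self.head_width, seed=self.seed
            )
        else:
            net = init_classifier_random(
                Xt.shape[1],
                list(self.layer_sizes),
                head_width=self.head_width,
                seed=self.seed,
            )
        ft = replace(self.finetune_cfg, seed=self.seed)
        return fine_tune(net, (Xtr, ytr), (Xv, yv), ft)

    def predict(self, net, X_test) -> np.ndarray:
        Xs = squash(self.stage_.transform(X_test))
        return net.predict(Xs)


@dataclass
class SVMPipeline:
    """mRMR -> z-score -> soft-margin linear SVM."""

    n_features: int = 50
    C: float = 1.0

    def __call__(
        self, X_train, y_train, X_test, X_unlab=None, X_val=None, y_val=None
    ) -> np.ndarray:
        stage = _FeatureStage(self.n_features)
        stage.fit(X_train, np.asarray(y_train, int))
        model = train_linear_svm(stage.transform(X_train), np.asarray(y_train, int), self.C)
        return model.predict(stage.transform(X_test))


@dataclass
class LapSVMPipeline:
    """mRMR -> z-score -> Laplacian SVM over labeled + unlabeled samples."""

    n_features: int = 50
    gamma_A: float = 0.1
    gamma_I: float = 1.0
    sigma: float = 3.0
    kernel: str = "rbf"
    graph: GraphSpec = field(default_factory=GraphSpec)

    def __call__(
        self, X_train, y_train, X_test, X_unlab=None, X_val=None, y_val=None
    ) -> np.ndarray:
        y = np.asarray(y_train, int)
        stage = _FeatureStage(self.n_features)
        stage.fit(X_train, y)
        Xl = stage.transform(X_train)
        Xu = stage.transform(X_unlab)
        model = train_lapsvm(
            Xl,
            np.where(y == 1, 1.0, -1.0),
            Xu,
            gamma_A=self.gamma_A,
            gamma_I=self.gamma_I,
            kernel=self.kernel,
            sigma=self.sigma,
            graph=self.graph,
        )
        pred = model.predict(stage.transform(X_test))
        return (pred == 1).astype(int)
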