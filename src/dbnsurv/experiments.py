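"""Reusable synthetic-study designs exercising the pipeline end to end.

Each experiment fixes one scientific question at desk scale:

* ``pretraining_benefit`` — does generative pre-training on the pooled
  labeled + unlabeled samples improve a small cohort's test accuracy over
  an identically sized, identically trained randomly initialized network?
* ``fusion_experiment`` — does joining two modality networks at their
  pre-softmax features help when the modalities are complementary, stay
  neutral when they are redundant, and stay robust when one is noise?
* ``semi_supervised_clusters`` — with two labeled points and a cloud of
  unlabeled ones arranged in two interleaved clusters, does the manifold
  regularizer recover the cluster structure a supervised SVM cannot see?

The designs (sample sizes, probe counts, effect sizes) are fixed here so
that every caller measures the same study.
"""

from __future__ import annotations

import numpy as np
from sklearn.datasets import make_moons
from sklearn.svm import SVC

from .baselines import GraphSpec, train_lapsvm
from .dbn import FineTuneConfig, fine_tune
from .fusion import build_fusion_model, train_fusion
from .mrmr import squash
from .pipeline import DBNPipeline
from .rbm import TrainConfig
from .simulate import GeneratorSpec, ModalitySpec, generate_dataset


def _split_labeled(lab: np.ndarray, n_train_per_class: int, rng: np.random.Generator):
    """Stratified train/test index split of the intended labeled classes."""
    pos = np.flatnonzero(lab == "positive")
    neg = np.flatnonzero(lab == "negative")
    tr = np.concatenate(
        [
            rng.choice(pos, n_train_per_class, replace=False),
            rng.choice(neg, n_train_per_class, replace=False),
        ]
    )
    te = np.setdiff1d(np.concatenate([pos, neg]), tr)
    unl = np.flatnonzero(lab == "unlabeled")
    return tr, te, unl


def pretraining_benefit(
    seeds: range | list[int] = range(20),
    pretrain_epochs: int = 1000,
) -> dict:
    """Pre-trained vs randomly initialized twin on a 40-labeled/400-unlabeled design.

    Each seed draws a fresh cohort (640 samples, 60 probes of which 8 read
    out the latent risk), trains on 40 labeled samples (20 per class) with
    400 censored samples available only to pre-training, and scores both
    networks on the 200 remaining labeled samples.
    """
    acc_pre, acc_rand = [], []
    for seed in seeds:
        spec = GeneratorSpec(
            n_samples=640,
            modalities={"gene": ModalitySpec(n_probes=60, n_informative=8)},
            class_counts=(120, 120, 400),
            seed=seed,
        )
        mats, _, truth = generate_dataset(spec)
        X = mats["gene"].values
        lab = np.array(truth.intended_labels)
        y = (lab == "positive").astype(int)
        rng = np.random.default_rng(seed + 1000)
        tr, te, unl = _split_labeled(lab, 20, rng)
        for pretrained, sink in ((True, acc_pre), (False, acc_rand)):
            pipe = DBNPipeline(
                n_features=30,
                pretrain_cfg=TrainConfig(epochs=pretrain_epochs, seed=seed),
                finetune_cfg=FineTuneConfig(max_epochs=500, patience=50, seed=seed),
                seed=seed,
                pretrained=pretrained,
            )
            pred = pipe(X[tr], y[tr], X[te], X[unl])
            sink.append(float(np.mean(pred == y[te])))
    return {
        "pretrained_accuracies": acc_pre,
        "random_accuracies": acc_rand,
        "pretrained_mean": float(np.mean(acc_pre)),
        "random_mean": float(np.mean(acc_rand)),
        "delta": float(np.mean(acc_pre) - np.mean(acc_rand)),
    }


def _train_branch(X, y, tr, va, te, unl, seed, n_features, pretrain_epochs):
    pipe = DBNPipeline(
        n_features=n_features,
        pretrain_cfg=TrainConfig(epochs=pretrain_epochs, seed=seed),
        finetune_cfg=FineTuneConfig(max_epochs=300, patience=50, seed=seed),
        seed=seed,
    )
    net = pipe.fit(X[tr], y[tr], X[unl], X[va], y[va])
    acc = float(np.mean(pipe.predict(net, X[te]) == y[te]))
    return pipe, net, acc


def fusion_experiment(
    mode: str,
    seeds: range | list[int] = range(20),
    pretrain_epochs: int = 300,
) -> dict:
    """Pairwise fusion under three modality relationships.

    ``mode`` selects the generator configuration:

    * ``"complementary"`` — two modalities observing partially independent
      views (latent correlation 0.7) of the risk through disjoint probes;
      fusing should beat the better single-modality model in most seeds.
    * ``"redundant"`` — latent correlation 1.0 with strong probes (effect
      2.0, probe noise 0.5), so each modality alone already reads the risk
      near its ceiling; fusing should change accuracy very little.
    * ``"noise"`` — the second modality has no informative probes at all;
      fusing should degrade the informative branch only marginally.
    """
    if mode not in ("complementary", "redundant", "noise"):
        raise ValueError(f"unknown fusion mode {mode!r}")
    rho = {"complementary": 0.7, "redundant": 1.0, "noise": 1.0}[mode]
    m_b_informative = 0 if mode == "noise" else 8
    overlap = "disjoint" if mode == "complementary" else "identical"
    effect, noise_sd = (2.0, 0.5) if mode == "redundant" else (1.0, 1.0)
    deltas_vs_a, deltas_vs_best, rows = [], [], []
    for seed in seeds:
        spec = GeneratorSpec(
            n_samples=700,
            modalities={
                "gene": ModalitySpec(
                    n_probes=40, n_informative=8,
                    effect_size=effect, noise_sd=noise_sd,
                ),
                "mirna": ModalitySpec(
                    n_probes=40, n_informative=m_b_informative,
                    effect_size=effect, noise_sd=noise_sd,
                ),
            },
            cross_modality_correlation=rho,
            informative_overlap=overlap,
            class_counts=(250, 250, 200),
            seed=seed,
        )
        mats, _, truth = generate_dataset(spec)
        lab = np.array(truth.intended_labels)
        y = (lab == "positive").astype(int)
        rng = np.random.default_rng(seed + 2000)
        tr_all, te, unl = _split_labeled(lab, 100, rng)
        # carve a validation subset out of the training indices
        va = np.concatenate(
            [
                rng.choice(tr_all[y[tr_all] == c], 25, replace=False)
                for c in (0, 1)
            ]
        )
        tr = np.setdiff1d(tr_all, va)
        branches = {}
        for name in ("gene", "mirna"):
            X = mats[name].values
            branches[name] = _train_branch(
                X, y, tr, va, te, unl, seed, 20, pretrain_epochs
            )
        (pipe_a, net_a, acc_a) = branches["gene"]
        (pipe_b, net_b, acc_b) = branches["mirna"]
        fused = build_fusion_model(net_a, net_b, seed=seed)

        def prep(pipe, X):
            return squash(pipe.stage_.transform(X))

        Xa, Xb = mats["gene"].values, mats["mirna"].values
        fused = train_fusion(
            fused,
            (prep(pipe_a, Xa[tr]), prep(pipe_b, Xb[tr]), y[tr]),
            (prep(pipe_a, Xa[va]), prep(pipe_b, Xb[va]), y[va]),
            FineTuneConfig(max_epochs=300, patience=50, seed=seed),
        )
        pred = fused.predict(prep(pipe_a, Xa[te]), prep(pipe_b, Xb[te]))
        acc_f = float(np.mean(pred == y[te]))
        deltas_vs_a.append(acc_f - acc_a)
        deltas_vs_best.append(acc_f - max(acc_a, acc_b))
        rows.append({"seed": seed, "single_a": acc_a, "single_b": acc_b, "fused": acc_f})
    return {
        "mode": mode,
        "runs": rows,
        "mean_delta_vs_a": float(np.mean(deltas_vs_a)),
        "mean_delta_vs_best": float(np.mean(deltas_vs_best)),
        "n_fused_ge_best": int(np.sum(np.asarray(deltas_vs_best) >= 0)),
        "n_seeds": len(rows),
    }


def semi_supervised_clusters(
    seeds: range | list[int] = range(20),
    gamma_A: float = 1e-6,
    gamma_I: float = 100.0,
    sigma: float = 0.35,
) -> dict:
    """Two interleaved half-moon clusters, two labels, 200 unlabeled points.

    The labeled pair sits at the outer tips of the moons, so the
    supervised maximum-margin boundary cuts both clusters; the Laplacian
    SVM can follow the cluster structure through the unlabeled cloud.
    """
    acc_lap, acc_svm = [], []
    for seed in seeds:
        X, y = make_moons(n_samples=202, noise=0.08, random_state=seed)
        yy = np.where(y == 1, 1.0, -1.0)
        i0 = np.flatnonzero(y == 0)[np.argmin(X[y == 0, 0])]
        i1 = np.flatnonzero(y == 1)[np.argmax(X[y == 1, 0])]
        lab = np.array([i0, i1])
        unlab = np.setdiff1d(np.arange(len(X)), lab)
        model = train_lapsvm(
            X[lab],
            yy[lab],
            X[unlab],
            gamma_A=gamma_A,
            gamma_I=gamma_I,
            kernel="rbf",
            sigma=sigma,
            graph=GraphSpec(n_neighbors=6),
        )
        acc_lap.append(float(np.mean(model.predict(X[unlab]) == yy[unlab])))
        svc = SVC(
            kernel="rbf", gamma=1.0 / (2 * sigma**2), C=1.0 / (2 * 2 * gamma_A)
        ).fit(X[lab], yy[lab])
        acc_svm.append(float(np.mean(svc.predict(X[unlab]) == yy[unlab])))
    return {
        "lapsvm_accuracies": acc_lap,
        "svm_accuracies": acc_svm,
        "lapsvm_mean": float(np.mean(acc_lap)),
        "svm_mean": float(np.mean(acc_svm)),
    }
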