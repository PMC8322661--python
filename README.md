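# dbnsurv

Semi-supervised deep belief networks for binary cancer-survival risk
prediction from omics data, with pairwise modality fusion, SVM and
Laplacian-SVM baselines, and Kaplan-Meier / log-rank evaluation.

## The problem

Survival cohorts ask a simple question of high-dimensional molecular
profiles: will this patient survive at least *T* years?  Two things make
the supervised version of that question hard.  First, omics matrices
have tens of thousands of probes and a few hundred samples.  Second,
censoring: many patients are alive at last contact but short of the
threshold, so their class is unknown — yet their molecular profiles are
perfectly good observations of the data manifold.

This package treats the problem semi-supervised end to end:

1. **Labeling** — samples past the follow-up threshold are positive,
   deaths before it are negative, early-censored samples are unlabeled.
2. **Feature selection** — minimum-redundancy-maximum-relevance (mRMR)
   over 3-bin discretized probes, then z-scoring and a logistic squash
   into (0, 1).
3. **Pre-training** — a stack of Bernoulli restricted Boltzmann machines
   (a deep belief network, default two hidden layers of 15 units) is
   trained layer-by-layer with contrastive divergence on **all** samples,
   labeled and unlabeled alike.
4. **Fine-tuning** — the DBN weights initialize a feed-forward classifier
   (fresh sigmoid layer + 2-class softmax) trained with SGD and
   early stopping on the labeled samples only.
5. **Fusion** — two single-modality networks can be joined by
   concatenating their last hidden layers under a fresh softmax and
   fine-tuning end to end.
6. **Baselines & evaluation** — linear SVM and a Laplacian SVM (which
   also exploits unlabeled samples, through a graph-manifold penalty);
   repeated stratified random splits, leave-one-out risk stratification,
   Kaplan-Meier curves and the log-rank test.

A seeded synthetic-cohort generator (latent-risk factor model with
exponential/Weibull survival and calibrated censoring) makes every claim
testable on a desk. See [docs/methods.md](docs/methods.md) for the full
model and design documentation.

## Worked example

Simulate a 300-sample single-modality cohort (60 probes, 8 informative,
30% censoring), train the DBN and both baselines, then run leave-one-out
risk stratification.  All commands are deterministic given `--seed`.

```console
$ dbnsurv simulate --n-samples 300 --n-probes 60 --n-informative 8 \
    --effect-size 1.5 --censoring-rate 0.3 --seed 11 --out demo/data
{"n_samples": 300, "labels": {"positive": 131, "negative": 135, "unlabeled": 34}}

$ dbnsurv train --data-dir demo/data --model dbn --n-features 20 \
    --pretrain-epochs 200 --max-epochs 200 --seed 5 --out demo/dbn
{"test_accuracy": 0.717948717948718}

$ dbnsurv train --data-dir demo/data --model svm --n-features 20 \
    --seed 5 --out demo/svm
{"test_accuracy": 0.6410256410256411}

$ dbnsurv train --data-dir demo/data --model lapsvm --n-features 20 \
    --seed 5 --out demo/lapsvm
{"test_accuracy": 0.5128205128205128}

$ dbnsurv evaluate --data-dir demo/data --n-features 10 --seed 5 --out demo/loo
{"modality": "gene", "n_samples": 266, "chi_square": 85.13748322124448,
 "p_value": 2.7832405818549013e-20, "accuracy": 0.7255639097744361}
```

On this cohort the pre-trained DBN (71.8% test accuracy) beats the
linear SVM (64.1%) and the LapSVM (51.3%), and the leave-one-out
predicted risk groups separate sharply on the log-rank test
(chi-square 85.1, p ~ 2.8e-20 over 266 labeled samples).  Each command
writes a `metrics.json` with the full payload (predictions, split sizes,
seed); `dbnsurv fuse` joins two trained modalities, and
`dbnsurv benchmark` repeats stratified random splits.

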