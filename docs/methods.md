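# Methods

This document describes the models, assumptions, parameter choices,
numerical decisions, and known limitations of the package.

## Problem setting

Given one or more omics matrices (samples x probes) and clinical follow-up
(time in days, vital status), the task is binary risk classification:
did the patient survive at least a threshold number of years?  Samples
are labeled three ways:

- **positive** — follow-up time >= threshold (dead or alive afterwards);
- **negative** — died before the threshold;
- **unlabeled** — censored (alive at last contact) before the threshold.

Unlabeled samples carry no class information but still describe the data
manifold; they are used by the generative pre-training stage and by the
Laplacian SVM, never by supervised losses.

## Preprocessing

1. **Discretization for feature scoring.** Each probe is cut into three
   bins at mean +/- 0.7 standard deviations (computed per probe on the
   labeled training samples only).  Constant probes fall in the middle
   bin.
2. **mRMR selection.** Greedy minimum-redundancy-maximum-relevance with
   the mutual-information difference criterion: at each step pick the
   probe maximizing I(x; y) - (1/|S|) sum_{s in S} I(x; s).  Mutual
   information is the plug-in estimate on the 3-bin codes, in bits.  Ties
   resolve to the lowest probe index.  Per the pipeline defaults the top
   50 probes are kept (30 or fewer in the desk-scale studies).
3. **Z-scoring.** Per selected probe, using training-sample mean and
   standard deviation (ddof=1); zero-variance probes map to 0.
4. **Logistic squash.** RBM visible units are Bernoulli, so z-scores are
   mapped into (0, 1) by sigmoid(gain * z) with gain = 3.0.  The gain
   matters: with gain 1 the squashed data variance (~0.04) is far below
   the Bernoulli sampling variance (0.25) of the contrastive-divergence
   reconstruction chain, and the linearized CD dynamics then shrink the
   weights toward zero — pre-training learns nothing.  Gain 3 restores
   enough input variance for CD to pick up covariance structure.

All selection and scaling parameters are fit on labeled training samples
only and applied unchanged to validation, test, and unlabeled matrices.

## Restricted Boltzmann machines

Energy E(v, h) = -b.v - c.h - v'Wh over binary v (visible) and h
(hidden); conditionals factorize as sigmoid(c + vW) and sigmoid(b + hW').
Training is CD-k (k = 1 by default): positive statistics use the
data-clamped hidden conditional means (Rao-Blackwellized), negative
statistics come from a k-step Gibbs chain that samples visible states and
ends with hidden conditional means.  Updates use learning rate 0.05,
mini-batches of 25, L2 weight decay 0.001 on W only, and 3000 epochs by
default (the desk-scale studies use fewer; each study fixes its own
budget).

For models with n_visible + n_hidden <= 20 the package provides exact
oracles — partition function, joint enumeration, likelihood, and the
exact likelihood gradient — used by the test suite to verify the sampler
and the CD statistics.

## Deep belief network and classifier

Greedy layer-wise stacking: the first RBM trains on the squashed features
of **all** available samples (labeled + unlabeled, no labels involved),
each subsequent RBM on the previous layer's hidden conditional means.
The default architecture is two hidden layers of 15 units.

The classifier copies the DBN weights, appends a fresh fully connected
sigmoid layer (width 15) and a two-class softmax.  Fresh layers use
fan-in-scaled Gaussian init N(0, 1/sqrt(d_in)); the tiny N(0, 0.01) RBM
init would starve a three-sigmoid-deep network of gradient.  Fine-tuning
is plain SGD on the softmax cross-entropy (learning rate 0.1, batch 25,
up to 500 epochs) with early stopping: training stops once the validation
loss has not improved for `patience` consecutive epochs, and the
best-validation weights are restored.  The untrained starting point is
itself a best-weight candidate, so fine-tuning never returns a network
worse than its initialization on the validation loss.  A randomly
initialized twin of the same shape (`pretrained=False`) serves as the
ablation control for the pre-training-benefit study.

## Pairwise fusion

Two fine-tuned single-modality networks are joined by dropping their
softmax heads, concatenating the activations of their last sigmoid layers
(the pre-softmax features) and stacking one fresh softmax on top.  The
combined model trains end to end (branches warm-started, same SGD and
early-stopping rules).  `pairwise_improvement_matrix` reports
cell(r, c) = accuracy(fused r+c) - accuracy(single r).

## Baselines

- **Linear SVM** on the same selected, z-scored features.
- **Laplacian SVM**: minimizes hinge loss + gamma_A ||f||_K^2 +
  (gamma_I / N^2) f' L^p f over labeled and unlabeled samples, with a
  k-NN similarity graph (k = 6, union-symmetrized, heat-kernel weights
  with scale = mean k-NN distance) and graph Laplacian L = D - W
  (power p = 1 by default).  By the representer theorem the problem
  reduces to a standard SVM quadratic program with the modified kernel
  Q = J K M^{-1} J', M = 2 gamma_A I + (2 gamma_I / N^2) L^p K.  That QP
  is solved with sklearn's SVC on the precomputed kernel with C = 1/l —
  exactly the same box-constrained dual — so no external QP library is
  needed.  At gamma_I = 0 the construction is algebraically identical to
  a supervised SVM with C = 1/(2 l gamma_A), which the tests verify to
  ~1e-10.

## Survival evaluation

- **Kaplan-Meier** product-limit estimator, with deaths processed before
  censorings at tied times.
- **Two-group log-rank test** in observed-minus-expected form with the
  hypergeometric variance at each distinct death time; p-value from
  chi-square with 1 df.  Both are implemented directly; lifelines serves
  only as an independent cross-check in the tests (agreement to 1e-8).
- **Leave-one-out protocol**: for each labeled sample the full pipeline
  (feature selection included) is refit on the remaining samples and
  predicts the held-out sample's risk class; the two predicted groups are
  compared with KM curves and the log-rank test.
- **Repeated random splits**: stratified 70/15/15 train/test/validation
  splits (100 by default), every model retrained per split; reported as
  mean (sd) accuracy.

## Synthetic data generator

Each sample has a latent risk z ~ N(0,1).  Modality m observes
z_m = rho z + sqrt(1 - rho^2) zeta_m with modality-specific zeta_m, so
rho interpolates between redundant (rho = 1) and independent modalities.
Informative probes read effect_size * z_m + N(0, noise_sd^2); all other
probes are standard normal noise.  Informative positions are drawn at
random or placed in disjoint blocks across modalities
(`informative_overlap="disjoint"`).

Survival is exponential (optionally Weibull) with hazard
baseline_hazard * exp(z); censoring is an independent exponential whose
rate is calibrated by root-finding so the requested fraction of the drawn
cohort is censored.  Alternatively `class_counts=(pos, neg, unlabeled)`
constructs follow-up by quota: the censored subset is drawn at random,
the lowest-risk remainder becomes the long-survivor class, and times are
placed on the correct side of the labeling threshold while remaining
monotone in latent risk, so exact published-style cohort compositions can
be reproduced.

### Generator limitations

- A single global risk factor drives both survival and all informative
  probes; real cohorts have many partially overlapping programs.
- Probes are linear read-outs with Gaussian noise; no count noise,
  batch effects, or heavy tails.
- The quota construction makes class membership a deterministic threshold
  on z within the labeled subset, which is cleaner than survival reality.
- Censoring is independent of risk (random censoring assumption).

## Desk-scale study designs

The package fixes several self-contained studies in
`dbnsurv.experiments` so every caller measures the same design:

- **Pre-training benefit**: 640 samples, 60 probes (8 informative),
  120/120/400 positive/negative/censored; 20 labeled training samples per
  class, all 400 censored samples available only to pre-training.
- **Fusion**: 700 samples, two modalities of 40 probes (8 informative
  each), 250/250/200; complementary (rho = 0.7, disjoint probes),
  redundant (rho = 1, strong probes: effect 2.0, noise 0.5), and noise
  (second modality uninformative) relationships.  The redundant condition
  uses strong probes deliberately: with weak probes a second
  identical-signal modality still averages down independent probe noise
  and genuinely gains accuracy, which would not be "redundant".
- **Semi-supervised clusters**: two interleaved half-moon clusters, one
  labeled point per class at the outer tips, 200 unlabeled points;
  LapSVM (gamma_A = 1e-6, gamma_I = 100, RBF sigma = 0.35) vs a
  supervised SVM with the matched kernel.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; training loops re-derive their generators from config
  seeds, so every experiment, CLI command, and the acceptance script are
  bit-reproducible given a seed.
- Softmax and sigmoid computations are overflow-guarded; cross-entropy
  uses a 1e-12 floor inside the log.
- The LapSVM linear system is solved directly, with one ridge-jitter
  retry on singularity.
- Free energies use log1p/exp formulations stable for |pre-activation|
  up to several hundred.

## Limitations

- SGD is plain (no momentum or adaptive rates), matching the described
  training procedure; very weak signals can stall on the cross-entropy
  plateau before early stopping triggers.
- The log-rank chi-square approximation is anti-conservative for small,
  heavily censored groups (excess of small p-values); this is a property
  of the test statistic, not of the implementation, which matches an
  independent library to 1e-8.
- CD-k is a biased gradient estimator; the exact-enumeration oracles
  quantify that bias only for tiny models.
- Only pairwise fusion is implemented (no three-or-more-way fusion, no
  attention/gating), and branches must observe the same samples.
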