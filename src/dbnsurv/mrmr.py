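"""Probe discretization, mutual information, mRMR selection and z-scoring.

Each probe is discretized into three bins centered at its mean with cut
points at +/- c standard deviations (c = 0.7 by default): values at or
below mean - c*sigma are coded 0, values at or above mean + c*sigma are
coded 2, everything strictly between is coded 1.  Mutual information is
the plug-in estimate from the empirical joint distribution, in bits.

mRMR is the incremental (greedy) search: the first feature maximizes
relevance I(x; y); each subsequent feature maximizes the MID difference
criterion I(x; y) - (1/|S|) * sum_{s in S} I(x; s).  Ties resolve to the
lowest probe index, making the selection deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import OmicsMatrix


@dataclass
class DiscretizedMatrix:
    codes: np.ndarray  # (n_samples, n_probes) int8 in {0, 1, 2}
    thresholds: np.ndarray  # (n_probes, 2) low/high cut points
    probe_ids: list[str]


@dataclass
class MRMRSelection:
    selected_probe_ids: list[str]
    selected_indices: list[int]
    score_trace: list[float]


def discretize(matrix: OmicsMatrix, c: float = 0.7) -> DiscretizedMatrix:
    """Three-level coding of every probe at mean +/- c * sample sd.

    A probe with zero variance has no meaningful cut points and is coded
    all-1 (the middle bin).  Accepts either an OmicsMatrix or a bare
    samples-by-probes array (probe ids are then synthesized).
    """
    if isinstance(matrix, np.ndarray):
        matrix = OmicsMatrix(
            "gene",
            [f"S{i}" for i in range(matrix.shape[0])],
            [f"P{j}" for j in range(matrix.shape[1])],
            matrix,
        )
    X = matrix.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    low = mean - c * sd
    high = mean + c * sd
    codes = np.ones(X.shape, dtype=np.int8)
    nondeg = sd > 0
    codes[:, nondeg] = np.where(
        X[:, nondeg] <= low[nondeg], 0, np.where(X[:, nondeg] >= high[nondeg], 2, 1)
    )
    return DiscretizedMatrix(
        codes=codes,
        thresholds=np.column_stack([low, high]),
        probe_ids=list(matrix.probe_ids),
    )


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_joint(joint[None, :, :])[0]


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """MI in bits for a stack of contingency tables, shape (k, nx, ny)."""
    joint = joint.astype(float)
    n = joint.sum(axis=(1, 2), keepdims=True)
    p = joint / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (px * py))
    return np.nansum(term, axis=(1, 2))


def mi_profile(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MI in bits between every column of ``codes`` and the vector ``y``.

    Vectorized over probes: per-class one-hot products give every 3 x L
    contingency table with three matrix multiplications.
    """
    y = np.asarray(y)
    _, yi = np.unique(y, return_inverse=True)
    n_levels = yi.max() + 1
    onehot = np.eye(n_levels)[yi]  # (n, L)
    tables = np.stack(
        [(codes == c).T.astype(float) @ onehot for c in (0, 1, 2)], axis=1
    )  # (p, 3, L)
    return _mi_from_joint(tables)


def mrmr_select(
    disc: DiscretizedMatrix, y: np.ndarray, k: int
) -> MRMRSelection:
    """Greedy incremental mRMR (MID difference criterion) over labeled samples."""
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = disc.codes
    n_probes = codes.shape[1]
    if len(y) != codes.shape[0]:
        raise ValueError("label vector length does not match sample count")
    if k > n_probes:
        warnings.warn(
            f"requested {k} probes but only {n_probes} available; truncating"
        )
        k = n_probes
    relevance = mi_profile(codes, y)
    selected: list[int] = []
    trace: list[float] = []
    redundancy_sum = np.zeros(n_probes)
    available = np.ones(n_probes, dtype=bool)
    for step in range(k):
        if step == 0:
            score = relevance.copy()
        else:
            score = relevance - redundancy_sum / len(selected)
        score[~available] = -np.inf
        # lowest index among scores within 1e-12 of the max, so exact
        # mathematical ties are not broken by float summation order
        best = int(np.flatnonzero(score >= score.max() - 1e-12)[0])
        selected.append(best)
        trace.append(float(score[best]))
        available[best] = False
        if step < k - 1:
            redundancy_sum += mi_profile(codes, codes[:, best])
    return MRMRSelection(
        selected_probe_ids=[disc.probe_ids[i] for i in selected],
        selected_indices=selected,
        score_trace=trace,
    )


def zscore_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe mean and sample standard deviation (n-1) of the training set."""
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1) if train.shape[0] > 1 else np.zeros(train.shape[1])
    return mean, sd


def zscore_apply(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Standardize with training parameters; zero-variance probes map to 0."""
    X = np.asarray(X, dtype=float)
    safe = np.where(sd > 0, sd, 1.0)
    out = (X - mean) / safe
    out[:, sd == 0] = 0.0
    return out


def zscore_fit_apply(
    train: np.ndarray, *others: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Fit z-score parameters on ``train`` and apply to train plus others."""
    mean, sd = zscore_fit(train)
    transformed = [zscore_apply(train, mean, sd)]
    transformed.extend(zscore_apply(X, mean, sd) for X in others)
    return transformed, mean, sd


def squash(X: np.ndarray, gain: float = 3.0) -> np.ndarray:
    """Map standardized features into (0, 1) by a logistic with slope ``gain``.

    Pre-training treats inputs as Bernoulli means, so z-scored expression
    must land in the unit interval before it reaches the visible layer.
    The gain sets how much of the unit interval a one-sigma excursion
    covers; with a unit slope the squashed variance is so far below the
    Bernoulli sampling variance of the reconstruction chain that the
    contrastive-divergence weight dynamics contract toward zero, and the
    hidden layer never differentiates.  A gain of 3 puts typical z-scores
    deep into the saturating region and restores weight growth.
    """
    return 1.0 / (1.0 + np.exp(-gain * np.asarray(X, dtype=float)))
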