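"""Supervised SVM and semi-supervised Laplacian SVM baselines.

The Laplacian SVM augments the usual SVM objective with an intrinsic
smoothness penalty (gamma_I / N^2) f' L f on a sample-similarity graph
over labeled *and* unlabeled points:

    f* = argmin (1/l) sum_i hinge(y_i, f(x_i)) + gamma_A ||f||_K^2
                + (gamma_I / N^2) f' L^p f.

By the representer theorem f(x) = sum_{i=1..N} alpha_i K(x_i, x) + b, and
the dual reduces to a standard SVM quadratic program with the modified
kernel Q = J K (2 gamma_A I + 2 gamma_I / N^2 L^p K)^{-1} J', where J
selects the labeled rows.  That box-constrained QP is solved with the
same SVM solver used for the supervised baseline, so the two methods
differ only in the objective, not in optimization machinery.  At
gamma_I = 0 the construction is algebraically identical to a supervised
SVM with C = 1 / (2 l gamma_A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


def rbf_kernel(X1: np.ndarray, X2: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Gaussian kernel K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X1 = np.atleast_2d(np.asarray(X1, float))
    X2 = np.atleast_2d(np.asarray(X2, float))
    sq = (
        (X1**2).sum(axis=1)[:, None]
        + (X2**2).sum(axis=1)[None, :]
        - 2 * X1 @ X2.T
    )
    return np.exp(-np.maximum(sq, 0.0) / (2 * sigma**2))


@dataclass
class GraphSpec:
    """k-nearest-neighbour similarity graph with heat-kernel edge weights."""

    n_neighbors: int = 6
    laplacian_degree: int = 1  # power p applied to L
    normalized: bool = False
    heat_sigma: float | None = None  # None -> mean k-NN distance


def build_graph_laplacian(X: np.ndarray, spec: GraphSpec | None = None) -> np.ndarray:
    """Graph Laplacian L = D - W (optionally normalized), raised to power p.

    The k-NN graph is symmetrized by union; edge weights are
    exp(-d^2 / (2 sigma_g^2)) with sigma_g defaulting to the mean k-NN
    distance.  A disconnected graph is allowed and logged.
    """
    spec = spec or GraphSpec()
    X = np.atleast_2d(np.asarray(X, float))
    n = len(X)
    if n < 2:
        raise ValueError("need at least two samples to build a graph")
    k = min(spec.n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    sigma_g = spec.heat_sigma if spec.heat_sigma is not None else float(dist.mean())
    if sigma_g <= 0:
        sigma_g = 1.0  # all points coincide; any positive scale gives weight 1
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    w = np.exp(-(dist.ravel() ** 2) / (2 * sigma_g**2))
    W[rows, idx.ravel()] = w
    W = np.maximum(W, W.T)  # union symmetrization
    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp > 1:
        logger.info("similarity graph has %d connected components", n_comp)
    D = np.diag(W.sum(axis=1))
    L = D - W
    if spec.normalized:
        d = W.sum(axis=1)
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        L = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    return np.linalg.matrix_power(L, spec.laplacian_degree)


@dataclass
class LapSVMModel:
    """Kernel-expansion classifier over all training points."""

    X_train: np.ndarray  # all N points (labeled first)
    alpha: np.ndarray  # expansion coefficients, length N
    bias: float
    sigma: float
    gamma_A: float
    gamma_I: float
    kernel: str = "rbf"

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = _kernel(X, self.X_train, self.kernel, self.sigma)
        return K @ self.alpha + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {-1, +1}."""
        return np.where(self.decision_function(X) >= 0, 1, -1)


def _kernel(X1, X2, kind: str, sigma: float) -> np.ndarray:
    if kind == "rbf":
        return rbf_kernel(X1, X2, sigma)
    if kind == "linear":
        return np.atleast_2d(np.asarray(X1, float)) @ np.atleast_2d(
            np.asarray(X2, float)
        ).T
    raise ValueError(f"unknown kernel {kind!r}")


def train_lapsvm(
    X_lab: np.ndarray,
    y: np.ndarray,
    X_unlab: np.ndarray,
    gamma_A: float = 1.0,
    gamma_I: float = 1.0,
    kernel: str = "rbf",
    sigma: float = 3.0,
    graph: GraphSpec | None = None,
) -> LapSVMModel:
    """Fit a Laplacian SVM in representer form via the modified-kernel dual."""
    X_lab = np.atleast_2d(np.asarray(X_lab, float))
    y = np.asarray(y, float).ravel()
    if len(X_lab) == 0:
        raise ValueError("LapSVM requires labeled samples")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if gamma_A <= 0:
        raise ValueError("gamma_A must be positive")
    X_unlab = (
        np.atleast_2d(np.asarray(X_unlab, float))
        if X_unlab is not None and np.size(X_unlab)
        else np.empty((0, X_lab.shape[1]))
    )
    X_all = np.vstack([X_lab, X_unlab])
    l, N = len(X_lab), len(X_all)
    K = _kernel(X_all, X_all, kernel, sigma)
    # The dual is solved in the rescaled variables beta' = beta / (2 gamma_A)
    # with kernel 2 gamma_A * J K M^{-1} J' and box 1 / (2 gamma_A l): at
    # gamma_I = 0 the solver then sees exactly the supervised SVM problem
    # (kernel K, C = 1 / (2 gamma_A l)) instead of a rescaled twin whose
    # ill-conditioned dual libsvm may resolve differently.
    if gamma_I > 0:
        L = build_graph_laplacian(X_all, graph)
        M = 2 * gamma_A * np.eye(N) + (2 * gamma_I / N**2) * (L @ K)
        Minv_Jt = _solve_with_jitter(M, np.eye(N)[:, :l])
        K_mod = 2 * gamma_A * (K[:l] @ Minv_Jt)
        K_mod = 0.5 * (K_mod + K_mod.T)
    else:
        K_mod = K[:l, :l]
    svc = SVC(kernel="precomputed", C=1.0 / (2 * gamma_A * l), tol=1e-9)
    svc.fit(K_mod, y)
    beta_y = np.zeros(l)  # y_i * beta'_i at support vectors
    beta_y[svc.support_] = svc.dual_coef_.ravel()
    # expansion coefficients alpha = M^{-1} J' (2 gamma_A beta'); at
    # gamma_I = 0 this collapses to alpha = beta' exactly
    alpha = Minv_Jt @ (2 * gamma_A * beta_y) if gamma_I > 0 else beta_y
    return LapSVMModel(
        X_train=X_all,
        alpha=alpha,
        bias=float(svc.intercept_[0]),
        sigma=sigma,
        gamma_A=gamma_A,
        gamma_I=gamma_I,
        kernel=kernel,
    )


def _solve_with_jitter(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve M X = B, retrying once with a ridge jitter on singularity."""
    try:
        return np.linalg.solve(M, B)
    except np.linalg.LinAlgError:
        logger.warning("singular LapSVM system; retrying with ridge jitter")
        jitter = 1e-8 * np.trace(M) / len(M)
        return np.linalg.solve(M + jitter * np.eye(len(M)), B)


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Soft-margin linear SVM with the same solver backing the LapSVM dual."""
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    svc = SVC(kernel="linear", C=C, tol=1e-9)
    svc.fit(np.atleast_2d(np.asarray(X, float)), y)
    return svc


def grid_search_baseline(
    evaluate,
    grid: dict[str, list],
    tie_break: tuple[str, ...] = ("n_features", "gamma_I"),
) -> tuple[dict, float, list[dict]]:
    """Exhaustive grid search maximizing validation accuracy.

    ``evaluate(params) -> accuracy`` is called for every point of the
    cartesian product of ``grid``.  Ties resolve by the smallest value of
    each ``tie_break`` key in order (keys absent from the grid are
    ignored).  Returns (best_params, best_accuracy, trace).
    """
    from itertools import product as iproduct

    keys = list(grid)
    trace: list[dict] = []
    best_params, best_acc, best_key = None, -np.inf, None
    for combo in iproduct(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        acc = float(evaluate(params))
        trace.append({**params, "validation_accuracy": acc})
        key = tuple(params.get(t, 0) for t in tie_break)
        if acc > best_acc or (acc == best_acc and key < best_key):
            best_params, best_acc, best_key = params, acc, key
    return best_params, best_acc, trace


def log_grid(lo: float, hi: float, per_decade: int = 5) -> list[float]:
    """Logarithmically spaced grid from lo to hi, per_decade points a decade."""
    n = int(round(np.log10(hi / lo) * per_decade)) + 1
    return list(np.logspace(np.log10(lo), np.log10(hi), n))
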