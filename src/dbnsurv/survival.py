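"""Kaplan-Meier estimation, the log-rank test, and benchmarking protocols.

The product-limit estimator and the two-group log-rank statistic are
implemented directly (deaths are processed before censorings at tied
times, the standard convention); an established survival-analysis library
serves as an independent cross-check in the test suite, not as the
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .labels import SurvivalLabelSet


@dataclass
class KMCurve:
    event_times: np.ndarray  # sorted distinct death times
    survival_prob: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    died: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of the estimator at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class BenchmarkResult:
    model: str
    modality: str
    accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times[events])
    n = len(times)
    surv, at_risk, died = [], [], []
    s = 1.0
    for t in distinct:
        n_i = int(np.sum(times >= t))  # deaths precede censorings at ties
        d_i = int(np.sum((times == t) & events))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        died.append(d_i)
    return KMCurve(
        event_times=distinct,
        survival_prob=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        died=np.asarray(died),
    )


def logrank_test(
    group1: tuple[np.ndarray, np.ndarray], group2: tuple[np.ndarray, np.ndarray]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Uses the observed-minus-expected form with the hypergeometric variance
    at every distinct death time; p comes from chi-square with 1 df.
    """
    t1, e1 = np.asarray(group1[0], float), np.asarray(group1[1], bool)
    t2, e2 = np.asarray(group2[0], float), np.asarray(group2[1], bool)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be nonempty")
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    member1 = np.concatenate([np.ones(t1.size, bool), np.zeros(t2.size, bool)])
    death_times = np.unique(times[events])
    if death_times.size == 0:
        return 0.0, 1.0
    O1 = E1 = V = 0.0
    for t in death_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & member1).sum()
        d = ((times == t) & events).sum()
        d1 = ((times == t) & events & member1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O1 - E1) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def loo_km_protocol(
    pipeline: Callable,
    X: np.ndarray,
    labels: SurvivalLabelSet,
    sample_ids: list[str] | None = None,
    X_unlab: np.ndarray | None = None,
) -> dict:
    """Leave-one-out risk stratification with KM curves and a log-rank p.

    For every labeled sample the pipeline is refit on the remaining labeled
    samples (feature selection included, so nothing leaks from the held-out
    sample) and predicts that sample's risk class.  The two predicted
    groups are then compared on their raw follow-up times with the
    log-rank test.

    ``pipeline(X_train, y_train, X_test, X_unlab) -> predicted labels``.
    """
    ids = sample_ids if sample_ids is not None else labels.labeled_ids
    if len(ids) < 10:
        raise ValueError("need at least 10 labeled samples for the protocol")
    y = labels.binary_y(ids)
    X = np.atleast_2d(np.asarray(X, float))
    if len(X) != len(ids):
        raise ValueError("feature matrix does not match sample list")
    preds = np.empty(len(ids), dtype=int)
    for i in range(len(ids)):
        mask = np.ones(len(ids), bool)
        mask[i] = False
        try:
            preds[i] = int(
                np.asarray(pipeline(X[mask], y[mask], X[i : i + 1], X_unlab))[0]
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on held-out sample {ids[i]}") from exc
    times, events = labels.survival_of(ids)
    high = preds == 0  # predicted short survival
    if high.all() or (~high).all():
        chi2, p = 0.0, 1.0
        curves = {}
    else:
        chi2, p = logrank_test(
            (times[high], events[high]), (times[~high], events[~high])
        )
        curves = {
            "high_risk": km_estimate(times[high], events[high]),
            "low_risk": km_estimate(times[~high], events[~high]),
        }
    return {
        "sample_ids": list(ids),
        "predictions": preds,
        "curves": curves,
        "chi_square": chi2,
        "p_value": p,
        "accuracy": float(np.mean(preds == y)),
    }


def benchmark_random_splits(
    pipelines: dict[str, Callable],
    X: np.ndarray,
    labels: SurvivalLabelSet,
    sample_ids: list[str] | None = None,
    X_unlab: np.ndarray | None = None,
    seeds: range | list[int] = range(100),
    modality: str = "",
    split_fn: Callable | None = None,
) -> tuple[list[BenchmarkResult], pd.DataFrame]:
    """Repeated random train/test/validation benchmark (100 splits by default).

    Each seed produces one stratified 70/15/15 split of the labeled
    samples; every pipeline is trained once per split and scored by test
    accuracy.  Returns per-pipeline results plus a long-format per-run
    table from which every reported mean and sd can be recomputed.
    """
    from .labels import random_split

    ids = sample_ids if sample_ids is not None else labels.labeled_ids
    y = labels.binary_y(ids)
    X = np.atleast_2d(np.asarray(X, float))
    pos = {s: i for i, s in enumerate(ids)}
    rows = []
    accs: dict[str, list[float]] = {name: [] for name in pipelines}
    for seed in seeds:
        if split_fn is not None:
            train_ids, test_ids, val_ids = split_fn(labels, seed)
        else:
            train_ids, test_ids, val_ids = random_split(labels, seed)
        tr = [pos[s] for s in train_ids if s in pos]
        te = [pos[s] for s in test_ids if s in pos]
        va = [pos[s] for s in val_ids if s in pos]
        for name, pipe in pipelines.items():
            pred = np.asarray(
                pipe(X[tr], y[tr], X[te], X_unlab, X[va], y[va])
            )
            acc = float(np.mean(pred == y[te]))
            accs[name].append(acc)
            rows.append(
                {"model": name, "modality": modality, "seed": seed, "accuracy": acc}
            )
    results = [
        BenchmarkResult(model=name, modality=modality, accuracies=np.asarray(a))
        for name, a in accs.items()
    ]
    return results, pd.DataFrame(rows)


def results_table(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Wide 'mean (sd)' accuracy table: rows are models, columns modalities."""
    models = sorted({r.model for r in results})
    mods = sorted({r.modality for r in results})
    table = pd.DataFrame(index=models, columns=mods, dtype=object)
    for r in results:
        table.loc[r.model, r.modality] = f"{100 * r.mean:.2f} ({100 * r.sd:.2f})"
    return table
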