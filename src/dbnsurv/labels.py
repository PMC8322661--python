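"""Three-way survival labeling and reproducible split schemes.

A sample is *positive* if it survived at least the threshold (dead or
alive at last follow-up), *negative* if it died before the threshold, and
*unlabeled* if it was censored (alive at last contact) before reaching the
threshold.  Unlabeled samples never enter supervised training but are
pooled with labeled samples for generative pre-training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import DAYS_PER_YEAR, ClinicalTable

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"


@dataclass
class SurvivalLabelSet:
    sample_ids: list[str]
    label: list[str]  # positive | negative | unlabeled
    time: np.ndarray  # days
    event: np.ndarray  # bool, True = deceased

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)

    def ids_with(self, label: str) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.label) if l == label]

    @property
    def labeled_ids(self) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.label) if l != UNLABELED]

    @property
    def unlabeled_ids(self) -> list[str]:
        return self.ids_with(UNLABELED)

    def binary_y(self, sample_ids: list[str]) -> np.ndarray:
        """0/1 vector (1 = positive) for the given labeled samples."""
        lab = dict(zip(self.sample_ids, self.label))
        out = []
        for s in sample_ids:
            l = lab[s]
            if l == UNLABELED:
                raise ValueError(f"sample {s} is unlabeled")
            out.append(1 if l == POSITIVE else 0)
        return np.asarray(out, dtype=int)

    def survival_of(self, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return self.time[rows], self.event[rows]


@dataclass
class SplitScheme:
    validation_ids: list[str]
    folds: list[list[str]]
    unlabeled_ids: list[str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "validation_ids": self.validation_ids,
                    "folds": self.folds,
                    "unlabeled_ids": self.unlabeled_ids,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitScheme":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["validation_ids"], d["folds"], d["unlabeled_ids"], d["seed"])


def assign_survival_labels(
    clinical: ClinicalTable, threshold_years: float
) -> SurvivalLabelSet:
    """Assign positive / negative / unlabeled survival classes.

    The threshold comparison is inclusive: a sample whose follow-up time is
    exactly the threshold counts as positive regardless of vital status.
    """
    if threshold_years < 0:
        raise ValueError("threshold_years must be nonnegative")
    thr_days = threshold_years * DAYS_PER_YEAR
    event = clinical.event
    labels = []
    for t, e in zip(clinical.survival_time, event):
        if t >= thr_days:
            labels.append(POSITIVE)
        elif e:
            labels.append(NEGATIVE)
        else:
            labels.append(UNLABELED)
    return SurvivalLabelSet(
        sample_ids=list(clinical.sample_ids),
        label=labels,
        time=clinical.survival_time.copy(),
        event=event,
    )


def _stratified_draw(
    ids: list[str], y: dict[str, str], n: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``n`` ids stratified by class, proportional with largest remainder."""
    by_class: dict[str, list[str]] = {}
    for s in ids:
        by_class.setdefault(y[s], []).append(s)
    total = len(ids)
    exact = {c: n * len(m) / total for c, m in by_class.items()}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    rest = n - sum(counts.values())
    for c in sorted(exact, key=lambda c: exact[c] - counts[c], reverse=True)[:rest]:
        counts[c] += 1
    chosen: list[str] = []
    for c in sorted(by_class):
        members = sorted(by_class[c])
        take = min(counts.get(c, 0), len(members))
        chosen.extend(rng.choice(members, size=take, replace=False).tolist())
    return chosen


def make_splits(
    labels: SurvivalLabelSet,
    val_frac: float = 0.15,
    k: int = 5,
    seed: int = 0,
) -> SplitScheme:
    """Hold out floor(val_frac * n_labeled) validation samples, then build
    ``k`` stratified cross-validation folds from the remaining labeled set."""
    rng = np.random.default_rng(seed)
    labeled = sorted(labels.labeled_ids)
    ymap = dict(zip(labels.sample_ids, labels.label))
    n_val = int(np.floor(val_frac * len(labeled)))
    if len(labeled) - n_val < k:
        raise ValueError(
            f"too few labeled samples ({len(labeled)}) for {k} folds "
            f"after removing {n_val} validation samples"
        )
    validation = _stratified_draw(labeled, ymap, n_val, rng)
    remaining = [s for s in labeled if s not in set(validation)]
    folds: list[list[str]] = [[] for _ in range(k)]
    # deal each class round-robin after a seeded shuffle: folds end up
    # stratified and sized within one sample of each other
    by_class: dict[str, list[str]] = {}
    for s in remaining:
        by_class.setdefault(ymap[s], []).append(s)
    offset = 0
    for c in sorted(by_class):
        members = sorted(by_class[c])
        rng.shuffle(members)
        for i, s in enumerate(members):
            folds[(i + offset) % k].append(s)
        offset += len(members)
    return SplitScheme(
        validation_ids=sorted(validation),
        folds=[sorted(f) for f in folds],
        unlabeled_ids=sorted(labels.unlabeled_ids),
        seed=seed,
    )


def random_split(
    labels: SurvivalLabelSet,
    seed: int,
    train_frac: float = 0.70,
    test_frac: float = 0.15,
) -> tuple[list[str], list[str], list[str]]:
    """One stratified train/test/validation split of the labeled samples.

    Proportions default to 70/15/15; validation receives the remainder so
    that the three lists always cover the labeled set exactly.
    """
    rng = np.random.default_rng(seed)
    labeled = sorted(labels.labeled_ids)
    ymap = dict(zip(labels.sample_ids, labels.label))
    n = len(labeled)
    n_train = int(np.floor(train_frac * n))
    n_test = int(np.floor(test_frac * n))
    train = _stratified_draw(labeled, ymap, n_train, rng)
    rest = [s for s in labeled if s not in set(train)]
    test = _stratified_draw(rest, ymap, n_test, rng)
    validation = [s for s in rest if s not in set(test)]
    return sorted(train), sorted(test), sorted(validation)
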