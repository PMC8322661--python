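"""Synthetic multi-omics survival data with a planted latent risk factor.

Each sample carries a latent risk z ~ N(0, 1).  Modality m observes a
modality-specific latent z_m = rho * z + sqrt(1 - rho^2) * zeta_m, so
``rho`` controls how redundant the modalities are (rho = 1: identical
signal; rho = 0: independent).  Informative probes are noisy linear
read-outs effect_size * z_m + N(0, noise_sd^2); the remaining probes are
pure standard-normal noise.  Survival is exponential with hazard
baseline_hazard * exp(z) (a proportional-hazards model on the latent
risk); censoring is an independent exponential whose rate is calibrated
on the drawn cohort so that the requested fraction of samples is
censored.  Follow-up is reported in days.

When explicit class counts are requested (to mimic a published cohort's
labeled/unlabeled composition exactly) follow-up times are constructed by
quota: the censored (unlabeled) subset is drawn at random, the remaining
lowest-risk samples become long-survivors, and times are placed on the
correct side of the labeling threshold while staying monotone in risk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .io import DAYS_PER_YEAR, ClinicalTable, OmicsMatrix


@dataclass
class ModalitySpec:
    n_probes: int = 1000
    n_informative: int = 10
    effect_size: float = 1.0
    noise_sd: float = 1.0


@dataclass
class GeneratorSpec:
    n_samples: int = 500
    modalities: dict[str, ModalitySpec] = field(
        default_factory=lambda: {"gene": ModalitySpec()}
    )
    cross_modality_correlation: float = 1.0  # rho
    baseline_hazard: float = 0.1  # events per year at z = 0
    censoring_rate: float = 0.5
    label_threshold_years: float = 5.0
    seed: int = 0
    weibull_shape: float | None = None  # None -> exponential survival
    class_counts: tuple[int, int, int] | None = None  # (pos, neg, unlabeled)
    informative_overlap: str = "identical"  # or "disjoint"

    def __post_init__(self) -> None:
        rho = self.cross_modality_correlation
        if not 0.0 <= rho <= 1.0:
            raise ValueError("cross_modality_correlation must be in [0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        for name, m in self.modalities.items():
            if m.n_informative > m.n_probes:
                raise ValueError(f"modality {name}: n_informative > n_probes")


@dataclass
class GroundTruth:
    latent_risk: np.ndarray
    informative_probes: dict[str, list[str]]
    intended_labels: list[str] | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "latent_risk": self.latent_risk.tolist(),
                    "informative_probes": self.informative_probes,
                    "intended_labels": self.intended_labels,
                },
                fh,
            )


def _calibrate_censoring_rate(
    hazards: np.ndarray, target: float
) -> float:
    """Exponential censoring rate c with mean_i c / (c + lambda_i) = target."""
    if target == 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - target

    hi = hazards.max()
    upper = hi
    while frac(upper) < 0:
        upper *= 10
        if upper > 1e12 * hi:
            raise ValueError("censoring rate not achievable")
    return brentq(frac, 1e-12 * hi, upper)


def generate_dataset(
    spec: GeneratorSpec,
) -> tuple[dict[str, OmicsMatrix], ClinicalTable, GroundTruth]:
    """Draw one dataset: omics matrices per modality, clinical table, truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    z = rng.standard_normal(n)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    rho = spec.cross_modality_correlation

    matrices: dict[str, OmicsMatrix] = {}
    informative: dict[str, list[str]] = {}
    offset = 0
    for name, mspec in spec.modalities.items():
        zeta = rng.standard_normal(n)
        z_m = rho * z + np.sqrt(1.0 - rho**2) * zeta
        X = rng.standard_normal((n, mspec.n_probes))
        if spec.informative_overlap == "disjoint":
            # deterministic non-overlapping blocks across modalities
            positions = (offset + np.arange(mspec.n_informative)) % mspec.n_probes
            offset += mspec.n_informative
        else:
            positions = rng.choice(
                mspec.n_probes, size=mspec.n_informative, replace=False
            )
        X[:, positions] = (
            mspec.effect_size * z_m[:, None]
            + mspec.noise_sd * rng.standard_normal((n, mspec.n_informative))
        )
        probe_ids = [f"{name}_p{j:05d}" for j in range(mspec.n_probes)]
        matrices[name] = OmicsMatrix(
            modality=name if name in ("gene", "isoform", "junction", "mirna", "methylation") else "gene",
            sample_ids=list(sample_ids),
            probe_ids=probe_ids,
            values=X,
        )
        informative[name] = [probe_ids[j] for j in sorted(positions)]

    if spec.class_counts is not None:
        clinical, intended = _quota_clinical(spec, z, sample_ids, rng)
        truth = GroundTruth(z, informative, intended)
        return matrices, clinical, truth

    hazards = spec.baseline_hazard * np.exp(z)  # per-year
    if spec.weibull_shape is None:
        T = rng.exponential(1.0 / hazards)
    else:
        k = spec.weibull_shape
        U = rng.uniform(size=n)
        T = (-np.log(U) / hazards) ** (1.0 / k)
    c_rate = _calibrate_censoring_rate(hazards, spec.censoring_rate)
    C = rng.exponential(1.0 / c_rate, size=n) if c_rate > 0 else np.full(n, np.inf)
    observed = np.minimum(T, C)
    event = T <= C
    clinical = ClinicalTable(
        sample_ids=list(sample_ids),
        survival_time=observed * DAYS_PER_YEAR,
        vital_status=["deceased" if e else "alive" for e in event],
    )
    return matrices, clinical, GroundTruth(z, informative)


def _quota_clinical(
    spec: GeneratorSpec,
    z: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> tuple[ClinicalTable, list[str]]:
    """Build follow-up satisfying exact positive/negative/unlabeled counts.

    Times stay anti-monotone in latent risk within each group so that risk
    remains learnable and KM curves separate.
    """
    n_pos, n_neg, n_unl = spec.class_counts
    n = len(z)
    if n_pos + n_neg + n_unl != n:
        raise ValueError("class counts must sum to n_samples")
    thr = spec.label_threshold_years * DAYS_PER_YEAR
    idx = np.arange(n)
    unl = rng.choice(idx, size=n_unl, replace=False)
    rest = np.setdiff1d(idx, unl)
    rest = rest[np.argsort(z[rest])]  # ascending risk
    pos = rest[:n_pos]  # lowest-risk survivors
    neg = rest[n_pos:]
    time = np.empty(n)
    status = np.empty(n, dtype=object)
    labels = np.empty(n, dtype=object)
    # survivors: time at least the threshold, longer for lower risk
    time[pos] = thr * (1.0 + rng.exponential(0.5, size=n_pos) * np.exp(-0.5 * z[pos]))
    status[pos] = ["deceased" if rng.random() < 0.3 else "alive" for _ in pos]
    labels[pos] = "positive"
    # early deaths: below threshold, shorter for higher risk
    u = rng.uniform(0.05, 0.95, size=n_neg)
    time[neg] = thr * np.sort(u)[::-1][np.argsort(np.argsort(z[neg]))]
    status[neg] = "deceased"
    labels[neg] = "negative"
    # censored short of the threshold
    time[unl] = thr * rng.uniform(0.05, 0.95, size=n_unl)
    status[unl] = "alive"
    labels[unl] = "unlabeled"
    clinical = ClinicalTable(
        sample_ids=list(sample_ids),
        survival_time=time,
        vital_status=list(status),
    )
    return clinical, list(labels)


# Published-cohort-like presets at one-tenth probe scale.  Counts follow the
# labeled/unlabeled composition of three real cohorts (kidney clear-cell
# carcinoma, head-and-neck squamous carcinoma, neuroblastoma).
_TABLE1_LIKE = {
    "KIRC-like": dict(counts=(110, 141, 281), n_probes=2053, threshold=5.0),
    "HNSC-like": dict(counts=(115, 128, 276), n_probes=2053, threshold=2.5),
    "NB-like": dict(counts=(115, 104, 279), n_probes=6078, threshold=9.0),
}


def spec_like_table1(disease: str, seed: int = 0) -> GeneratorSpec:
    """Generator preset mimicking a published cohort's composition."""
    if disease not in _TABLE1_LIKE:
        raise ValueError(
            f"unknown disease {disease!r}; choose from {sorted(_TABLE1_LIKE)}"
        )
    d = _TABLE1_LIKE[disease]
    n_pos, n_neg, n_unl = d["counts"]
    return GeneratorSpec(
        n_samples=n_pos + n_neg + n_unl,
        modalities={
            "gene": ModalitySpec(n_probes=d["n_probes"], n_informative=20)
        },
        label_threshold_years=d["threshold"],
        class_counts=(n_pos, n_neg, n_unl),
        seed=seed,
    )
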