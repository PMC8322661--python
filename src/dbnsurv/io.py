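"""Tabular input/output for omics matrices, clinical tables and run configs.

Expression matrices are tab-separated text. On disk the convention follows
the common repository layout of probes in rows and samples in columns (the
first column holds probe identifiers, the first row sample identifiers);
the loader transposes so that the in-memory orientation is always samples
by probes. The opposite on-disk orientation is supported via
``orientation="samples_by_probes"``.

Clinical tables carry one row per sample with overall-survival time in days
and a vital status of ``alive`` or ``deceased``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MODALITIES = ("gene", "isoform", "junction", "mirna", "methylation")

DAYS_PER_YEAR = 365.25

_STATUS_MAP = {
    "alive": "alive",
    "living": "alive",
    "0": "alive",
    "deceased": "deceased",
    "dead": "deceased",
    "1": "deceased",
}


class FormatError(ValueError):
    """Raised when a file does not conform to the expected tabular layout."""


@dataclass
class OmicsMatrix:
    """One modality's samples-by-probes expression (or beta-value) matrix."""

    modality: str
    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_probes)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=float)
        n_s, n_p = self.values.shape
        if n_s != len(self.sample_ids) or n_p != len(self.probe_ids):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in omics matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Return a copy restricted to ``sample_ids``, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return OmicsMatrix(
            self.modality, list(sample_ids), list(self.probe_ids), self.values[rows]
        )

    def subset_probes(self, probe_ids: Sequence[str]) -> "OmicsMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        cols = [index[p] for p in probe_ids]
        return OmicsMatrix(
            self.modality, list(self.sample_ids), list(probe_ids), self.values[:, cols]
        )


@dataclass
class ClinicalTable:
    """Per-sample overall-survival follow-up: time in days plus vital status."""

    sample_ids: list[str]
    survival_time: np.ndarray  # days, >= 0
    vital_status: list[str]  # "alive" | "deceased"

    def __post_init__(self) -> None:
        self.survival_time = np.asarray(self.survival_time, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in clinical table")
        if len(self.sample_ids) != len(self.survival_time) or len(
            self.sample_ids
        ) != len(self.vital_status):
            raise ValueError("clinical table column lengths differ")
        if self.survival_time.size and np.any(self.survival_time < 0):
            raise ValueError("negative survival time")
        bad = set(self.vital_status) - {"alive", "deceased"}
        if bad:
            raise ValueError(f"unknown vital status value(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def event(self) -> np.ndarray:
        """Boolean event indicator (True = death observed)."""
        return np.array([s == "deceased" for s in self.vital_status])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "time_days": self.survival_time,
                "status": self.vital_status,
            }
        )


def read_expression_matrix(
    path: str | Path,
    modality: str,
    orientation: str = "probes_by_samples",
) -> OmicsMatrix:
    """Read a TSV expression matrix and return it oriented samples x probes.

    Empty cells and "NA" are mean-imputed per probe (imputation counts are
    logged); a probe with no observed value at all is imputed to zero.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate identifiers in {path}")
    non_numeric = df.select_dtypes(exclude=[np.number]).columns
    if len(non_numeric):
        col = non_numeric[0]
        row = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        where = row.index[0] if len(row) else "?"
        raise FormatError(
            f"non-numeric cell in {path} (column {col!r}, row {where!r})"
        )
    if orientation == "probes_by_samples":
        df = df.T  # now samples x probes
    elif orientation != "samples_by_probes":
        raise ValueError(f"unknown orientation {orientation!r}")
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        logger.info("mean-imputing %d missing cells in %s", n_missing, path)
        df = df.fillna(df.mean(axis=0)).fillna(0.0)
    return OmicsMatrix(
        modality=modality,
        sample_ids=[str(s) for s in df.index],
        probe_ids=[str(p) for p in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_matrix(
    matrix: OmicsMatrix, path: str | Path, orientation: str = "probes_by_samples"
) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.sample_ids, columns=matrix.probe_ids
    )
    if orientation == "probes_by_samples":
        df = df.T
        df.index.name = "probe_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, time_days, status."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return ClinicalTable([], np.empty(0), [])
    if df.empty and len(df.columns) <= 1:
        return ClinicalTable([], np.empty(0), [])
    required = {"sample_id", "time_days", "status"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"clinical table {path} must have columns {sorted(required)}"
        )
    times = pd.to_numeric(df["time_days"], errors="coerce")
    if times.isna().any():
        bad = df.loc[times.isna(), "sample_id"].iloc[0]
        raise ValueError(f"non-numeric survival time for sample {bad!r}")
    statuses = []
    for sid, raw in zip(df["sample_id"], df["status"]):
        key = str(raw).strip().lower()
        if key not in _STATUS_MAP:
            raise ValueError(f"unknown vital status {raw!r} for sample {sid!r}")
        statuses.append(_STATUS_MAP[key])
    return ClinicalTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        survival_time=times.to_numpy(dtype=float),
        vital_status=statuses,
    )


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def align_samples(
    matrix: OmicsMatrix, clinical: ClinicalTable
) -> tuple[OmicsMatrix, ClinicalTable]:
    """Restrict both objects to their common samples, in matrix order."""
    clin_ids = set(clinical.sample_ids)
    keep = [s for s in matrix.sample_ids if s in clin_ids]
    idx = {s: i for i, s in enumerate(clinical.sample_ids)}
    rows = [idx[s] for s in keep]
    aligned_clin = ClinicalTable(
        sample_ids=keep,
        survival_time=clinical.survival_time[rows],
        vital_status=[clinical.vital_status[i] for i in rows],
    )
    return matrix.subset_samples(keep), aligned_clin


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping")
    return cfg
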