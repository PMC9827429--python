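"""Core data containers: patient-by-feature tables and cluster assignments.

The cohort table is the single in-memory currency of the pipeline: an
``n_patients x n_features`` matrix of continuous measurements with an
explicit missingness mask.  Missing cells are carried as ``NaN`` in
``values`` *and* flagged in ``missing_mask`` so that imputation can fill
values while preserving provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "ClusterAssignment", "canonicalize_labels"]


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class CohortTable:
    """Patients x features matrix with metadata.

    Parameters
    ----------
    patient_ids : array of str
        Unique patient identifiers, one per row.
    feature_names : array of str
        Unique feature (biomarker / clinical variable) names, one per column.
    values : ndarray, shape (n, p)
        Continuous measurements; ``NaN`` marks a missing cell.
    missing_mask : ndarray of bool, shape (n, p)
        True where the original measurement was missing.  Preserved across
        imputation for provenance.
    cohort_tag : {"development", "validation"}
    """

    patient_ids: np.ndarray
    feature_names: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    cohort_tag: str = "development"

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, p = self.values.shape
        if self.patient_ids.shape != (n,):
            raise ValidationError(
                f"patient_ids length {self.patient_ids.shape} does not match {n} rows"
            )
        if self.feature_names.shape != (p,):
            raise ValidationError(
                f"feature_names length {self.feature_names.shape} does not match {p} columns"
            )
        if self.missing_mask.shape != (n, p):
            raise ValidationError("missing_mask shape does not match values")
        if len(set(self.patient_ids)) != n:
            raise ValidationError("duplicate patient ids")
        if len(set(self.feature_names)) != p:
            raise ValidationError("duplicate feature names")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValidationError("non-finite value in non-missing cell")
        if self.cohort_tag not in ("development", "validation"):
            raise ValidationError(f"unknown cohort_tag {self.cohort_tag!r}")

    # -- conveniences -----------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.patient_ids.copy(),
            self.feature_names.copy(),
            self.values.copy(),
            self.missing_mask.copy(),
            self.cohort_tag,
        )

    def feature_index(self, name: str) -> int:
        idx = np.nonzero(self.feature_names == name)[0]
        if idx.size == 0:
            raise KeyError(f"unknown feature {name!r}")
        return int(idx[0])

    def drop_feature(self, name: str) -> "CohortTable":
        j = self.feature_index(name)
        keep = np.ones(self.n_features, dtype=bool)
        keep[j] = False
        return CohortTable(
            self.patient_ids.copy(),
            self.feature_names[keep].copy(),
            self.values[:, keep].copy(),
            self.missing_mask[:, keep].copy(),
            self.cohort_tag,
        )

    def with_values(self, values: np.ndarray) -> "CohortTable":
        return replace(self, values=np.asarray(values, dtype=float))

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "patient_id", list(self.patient_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort_tag: str = "development") -> "CohortTable":
        if "patient_id" not in df.columns:
            raise ValidationError("cohort CSV must contain a 'patient_id' column")
        ids = df["patient_id"].astype(str).to_numpy(dtype=object)
        feats = df.drop(columns=["patient_id"])
        return cls(
            ids,
            feats.columns.to_numpy(dtype=object),
            feats.to_numpy(dtype=float),
            cohort_tag=cohort_tag,
        )

    def to_csv(self, path) -> None:
        # empty cell == still-missing value; imputed cells carry their value
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, cohort_tag: str = "development") -> "CohortTable":
        return cls.from_frame(pd.read_csv(path), cohort_tag=cohort_tag)


@dataclass
class ClusterAssignment:
    """Per-patient integer cluster labels at a given dendrogram cut.

    Labels are canonical: consecutive integers starting at 1, ordered by
    cluster size descending, ties broken by the smallest member row index.
    """

    labels: np.ndarray
    cut_height: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)

    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    def to_series(self, patient_ids=None) -> pd.Series:
        idx = None if patient_ids is None else list(patient_ids)
        return pd.Series(self.labels, index=idx, name="cluster")


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel an arbitrary integer partition into canonical form.

    Clusters are numbered 1..k by size descending; ties between equal-size
    clusters go to the one containing the smallest row index.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda u: (-int(np.sum(labels == u)), int(np.argmax(labels == u))),
    )
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.array([mapping[u] for u in labels], dtype=int)
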