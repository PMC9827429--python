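"""Median imputation and standardization of clustering inputs.

Missing biomarker values are imputed with the per-feature median and every
feature is mapped to z-scores before distances are computed.  The scaling
parameters (median, mean, sample sd) can be frozen from a development
cohort and re-applied to a validation cohort, or recomputed per table;
``ScalingParams`` serializes to JSON so either choice is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable

__all__ = ["ScalingParams", "impute_median", "standardize", "unstandardize"]


class PreprocessError(ValueError):
    pass


@dataclass
class ScalingParams:
    """Per-feature median / mean / sample sd (n-1 denominator)."""

    feature_names: np.ndarray
    median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        self.median = np.asarray(self.median, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)

    def align_to(self, feature_names: np.ndarray) -> "ScalingParams":
        """Reorder parameters to match another table's feature order."""
        index = {n: i for i, n in enumerate(self.feature_names)}
        missing = [n for n in feature_names if n not in index]
        if missing:
            raise PreprocessError(f"no stored scaling parameters for features {missing}")
        order = [index[n] for n in feature_names]
        return ScalingParams(
            np.asarray(feature_names, dtype=object),
            self.median[order],
            self.mean[order],
            self.sd[order],
        )

    def to_json(self, path) -> None:
        payload = {
            "features": list(self.feature_names),
            "median": self.median.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScalingParams":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            np.asarray(raw["features"], dtype=object),
            np.asarray(raw["median"], dtype=float),
            np.asarray(raw["mean"], dtype=float),
            np.asarray(raw["sd"], dtype=float),
        )


def _medians(table: CohortTable) -> np.ndarray:
    med = np.full(table.n_features, np.nan)
    for j in range(table.n_features):
        col = table.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise PreprocessError(
                f"feature {table.feature_names[j]!r} is entirely missing and no "
                "stored median is available"
            )
        med[j] = np.median(obs)
    return med


def impute_median(table: CohortTable, params: ScalingParams | None = None) -> CohortTable:
    """Replace missing cells with the per-feature median.

    With ``params`` given (validation cohort), the stored medians are used;
    otherwise medians are computed from the table itself.  Observed cells
    are never altered and ``missing_mask`` is preserved for provenance.
    """
    if params is not None:
        med = params.align_to(table.feature_names).median
    else:
        med = _medians(table)
    values = table.values.copy()
    nan = np.isnan(values)
    values[nan] = np.broadcast_to(med, values.shape)[nan]
    out = table.with_values(values)
    return out


def standardize(
    table: CohortTable, params: ScalingParams | None = None
) -> tuple[CohortTable, ScalingParams]:
    """Map each feature to (x - mean) / sd and return the parameters used.

    ``params`` given -> frozen development-cohort statistics are applied
    (validation path); absent -> mean and sample sd (n-1 denominator) are
    computed from the table.  Zero-variance features are an error: the
    caller decides whether to drop them.
    """
    if table.has_missing:
        raise PreprocessError("standardize requires an imputed table (no missing cells)")
    if params is not None:
        params = params.align_to(table.feature_names)
    else:
        med = np.median(table.values, axis=0)
        mean = table.values.mean(axis=0)
        sd = table.values.std(axis=0, ddof=1)
        params = ScalingParams(table.feature_names, med, mean, sd)
    bad = [str(n) for n, s in zip(params.feature_names, params.sd) if not s > 0]
    if bad:
        raise PreprocessError(f"zero-variance features cannot be standardized: {bad}")
    out = table.with_values((table.values - params.mean) / params.sd)
    return out, params


def unstandardize(table: CohortTable, params: ScalingParams) -> CohortTable:
    """Inverse of :func:`standardize` (round-trip audit helper)."""
    params = params.align_to(table.feature_names)
    return table.with_values(table.values * params.sd + params.mean)
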