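"""Gaussian naive Bayes cluster classifier tolerant of missing biomarkers.

The classifier carries each development cluster's prevalence as its prior
and a per-cluster, per-feature Gaussian for the likelihood.  At prediction
time the log-posterior sums likelihood terms over *observed* features
only; a missing biomarker simply contributes no evidence, which is what
makes the model robust when validation-cohort panels are incomplete — no
imputation is needed at predict time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import ClusterAssignment, CohortTable

__all__ = ["NaiveBayesModel", "fit", "predict", "predict_table", "lofo_cv_accuracy", "lopo_cv_accuracy"]

VARIANCE_FLOOR_FACTOR = 1e-9  # times the largest per-feature variance


class FitError(ValueError):
    pass


@dataclass
class NaiveBayesModel:
    classes: np.ndarray              # cluster labels, ascending
    priors: np.ndarray               # cluster prevalences, sum to 1
    feature_names: np.ndarray
    means: np.ndarray                # (k, p)
    variances: np.ndarray            # (k, p), floored
    variance_floor: float = 0.0
    cv_flavor: str | None = field(default=None)  # set by the CV helpers

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        self.priors = np.asarray(self.priors, dtype=float)
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise FitError("priors must sum to 1")
        if np.any(self.variances <= 0):
            raise FitError("variances must be positive")

    def to_json(self, path=None):
        payload = {
            "classes": self.classes.tolist(),
            "priors": self.priors.tolist(),
            "features": list(self.feature_names),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "variance_floor": self.variance_floor,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    @classmethod
    def from_json(cls, path) -> "NaiveBayesModel":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            np.asarray(raw["classes"]),
            np.asarray(raw["priors"]),
            np.asarray(raw["features"], dtype=object),
            np.asarray(raw["means"]),
            np.asarray(raw["variances"]),
            float(raw.get("variance_floor", 0.0)),
        )


def fit(table: CohortTable, labels: ClusterAssignment | np.ndarray) -> NaiveBayesModel:
    """Estimate priors and per-class Gaussians from labeled development data.

    Priors are class frequencies; means/variances are per-class sample
    statistics (n-1 denominator) with a relative variance floor guarding
    near-constant features.  Every class needs at least 2 members.
    """
    y = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels, dtype=int)
    if y.shape[0] != table.n_patients:
        raise FitError("labels length does not match the table")
    X = table.values
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        raise FitError(f"classes with fewer than 2 members: {small.tolist()}")
    k, p = classes.size, table.n_features
    means = np.empty((k, p))
    variances = np.empty((k, p))
    for i, c in enumerate(classes):
        rows = X[y == c]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            means[i] = np.nanmean(rows, axis=0)
            variances[i] = np.nanvar(rows, axis=0, ddof=1)
    floor = VARIANCE_FLOOR_FACTOR * float(np.nanmax(variances)) if np.nanmax(variances) > 0 else 1e-12
    variances = np.where(np.isnan(variances) | (variances < floor), floor, variances)
    means = np.where(np.isnan(means), 0.0, means)
    return NaiveBayesModel(
        classes, counts / counts.sum(), table.feature_names, means, variances, floor
    )


def predict(model: NaiveBayesModel, row: np.ndarray) -> tuple[int, np.ndarray]:
    """Posterior over clusters for one patient row (NaN = missing feature).

    Returns ``(label, posterior)``.  Ties go to the higher-prior class,
    then the lower label id.  With every feature missing the posterior
    equals the priors.
    """
    row = np.asarray(row, dtype=float)
    if row.shape[0] != model.feature_names.size:
        raise FitError("row length does not match model features")
    observed = ~np.isnan(row)
    log_post = np.log(model.priors).copy()
    if not observed.any():
        warnings.warn("every feature missing; posterior falls back to the priors", stacklevel=2)
    if observed.any():
        x = row[observed]
        mu = model.means[:, observed]
        var = model.variances[:, observed]
        log_post += (-0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)).sum(axis=1)
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    # argmax with deterministic tie-breaking: posterior, then prior, then -label
    order = sorted(
        range(model.classes.size),
        key=lambda i: (-post[i], -model.priors[i], model.classes[i]),
    )
    return int(model.classes[order[0]]), post


def predict_table(model: NaiveBayesModel, table: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """Vector of predicted labels and (n, k) posterior matrix for a cohort."""
    idx = {n: i for i, n in enumerate(table.feature_names)}
    missing = [n for n in model.feature_names if n not in idx]
    cols = [idx[n] for n in model.feature_names if n in idx]
    present = [j for j, n in enumerate(model.feature_names) if n in idx]
    labels = np.empty(table.n_patients, dtype=int)
    posts = np.empty((table.n_patients, model.classes.size))
    for i in range(table.n_patients):
        row = np.full(model.feature_names.size, np.nan)
        row[present] = table.values[i, cols]
        labels[i], posts[i] = predict(model, row)
    if missing:
        warnings.warn(f"features absent from the input cohort: {missing}", stacklevel=2)
    return labels, posts


def lofo_cv_accuracy(
    table: CohortTable, labels: ClusterAssignment | np.ndarray
) -> float:
    """Leave-one-feature-out cross-validation accuracy on the development cohort.

    For each feature the model is refit without it and every development
    patient is re-predicted; the accuracy is the mean agreement with the
    cluster labels over all (feature, patient) pairs.
    """
    y = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels, dtype=int)
    if table.n_features < 2:
        raise FitError("leave-one-feature-out needs at least 2 features")
    hits = 0
    total = 0
    for name in table.feature_names:
        reduced = table.drop_feature(str(name))
        model = fit(reduced, y)
        pred, _ = predict_table(model, reduced)
        hits += int((pred == y).sum())
        total += y.size
    return hits / total


def lopo_cv_accuracy(
    table: CohortTable, labels: ClusterAssignment | np.ndarray
) -> float:
    """Leave-one-patient-out cross-validation accuracy (alternative reading)."""
    y = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels, dtype=int)
    hits = 0
    n = table.n_patients
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = CohortTable(
            table.patient_ids[keep],
            table.feature_names.copy(),
            table.values[keep],
            table.missing_mask[keep],
            table.cohort_tag,
        )
        model = fit(sub, y[keep])
        pred, _ = predict(model, table.values[i])
        hits += int(pred == y[i])
    return hits / n
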