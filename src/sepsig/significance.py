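"""Permutation reference distribution and significance cuts for dendrograms.

The null hypothesis of "no clusters" is emulated by independently shuffling
each biomarker column across patients, which preserves every marginal
distribution while destroying between-feature alignment.  Clustering each
permuted table yields a vector of merge heights; sorting each replicate's
heights and averaging rank-wise across replicates gives the reference
distribution ``D_ref`` (same length as the observed ``D_0``).  Significant
clusters are obtained by cutting the observed dendrogram at a high
percentile of ``D_ref`` — at significance level ``alpha`` the cut height is
the 100*(1-alpha) percentile, e.g. alpha = 0.004 cuts at the 99.6th
percentile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cohort import ClusterAssignment, CohortTable
from .hclust import Dendrogram, agglomerate_complete, pairwise_distance

__all__ = [
    "ReferenceDistribution",
    "SignificanceCut",
    "permute_table",
    "reference_distribution",
    "percentile_threshold",
    "significant_clusters",
    "significance_ladder",
    "qq_pairs",
]


class SignificanceError(ValueError):
    pass


@dataclass
class ReferenceDistribution:
    """Rank-averaged permuted merge heights (ascending), with provenance."""

    values: np.ndarray
    n_reps: int
    seed: int
    normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < -1e-12):
            raise SignificanceError("reference distribution must be ascending")

    def to_json(self, path=None):
        payload = {
            "values": self.values.tolist(),
            "n_reps": self.n_reps,
            "seed": self.seed,
            "normalized": self.normalized,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload


@dataclass
class SignificanceCut:
    alpha: float
    threshold_height: float
    labels: ClusterAssignment
    n_clusters: int


def permute_table(table: CohortTable, seed) -> CohortTable:
    """Shuffle each feature column independently across patients.

    Column marginals are preserved exactly; any joint structure between
    features is destroyed.  Deterministic given the seed (which may be an
    integer or a ``numpy.random.SeedSequence``).
    """
    if table.has_missing:
        raise SignificanceError("permutation requires an imputed table")
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    for j in range(values.shape[1]):
        rng.shuffle(values[:, j])
    return table.with_values(values)


def reference_distribution(
    table: CohortTable,
    n_reps: int = 10,
    seed: int = 0,
    normalize: bool = True,
) -> ReferenceDistribution:
    """Build ``D_ref`` by permuting, reclustering, and rank-averaging.

    Each replicate uses a fresh child seed spawned from the master seed, so
    replicates are independent and the whole procedure is reproducible.
    """
    if n_reps < 1:
        raise SignificanceError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    per_rep = np.empty((n_reps, table.n_patients - 1))
    for r, child in enumerate(children):
        permuted = permute_table(table, child)
        dend = agglomerate_complete(pairwise_distance(permuted, normalize=normalize))
        per_rep[r] = np.sort(dend.heights)
    return ReferenceDistribution(per_rep.mean(axis=0), n_reps, seed, normalize)


def percentile_threshold(ref: ReferenceDistribution, alpha: float) -> float:
    """The 100*(1-alpha) percentile of ``D_ref``.

    Computed by linear interpolation between closest order statistics with
    inclusive endpoints (alpha -> 0 gives max(D_ref)).
    """
    if not (0 < alpha < 1):
        raise SignificanceError(f"alpha must be in (0,1), got {alpha}")
    return float(np.percentile(ref.values, 100.0 * (1.0 - alpha), method="linear"))


def significant_clusters(
    dend: Dendrogram, ref: ReferenceDistribution, alpha: float
) -> SignificanceCut:
    """Cut the observed dendrogram at the reference-percentile threshold."""
    if ref.values.size != dend.n_leaves - 1:
        raise SignificanceError(
            f"reference length {ref.values.size} does not match the "
            f"{dend.n_leaves - 1} observed merges"
        )
    t = percentile_threshold(ref, alpha)
    from .hclust import cut_at_height

    labels = cut_at_height(dend, t)
    return SignificanceCut(alpha, t, labels, labels.n_clusters)


def significance_ladder(
    dend: Dendrogram, ref: ReferenceDistribution, alphas
) -> list[SignificanceCut]:
    """Cuts at each level of an alpha ladder (diagnostic for robustness)."""
    return [significant_clusters(dend, ref, a) for a in alphas]


def qq_pairs(dend: Dendrogram, ref: ReferenceDistribution) -> list[tuple[float, float]]:
    """Rank-matched (expected, observed) merge-height pairs for a QQ plot.

    Under the null the points lie near the diagonal; tight clusters pull
    low ranks below it and separated clusters push top ranks above it.
    """
    obs = np.sort(dend.heights)
    if ref.values.size != obs.size:
        raise SignificanceError("observed and reference height vectors differ in length")
    return [(float(e), float(o)) for e, o in zip(ref.values, obs)]
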