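"""Leave-one-feature-out (LOFO) robustness of the cluster assignment.

The full pipeline (normalized distances, complete linkage, permutation
reference, significance cut) is rerun with each feature removed in turn,
and the resulting labels are compared with the primary labels through the
absolute Spearman correlation.  A low concordance means the removed
feature was load-bearing for the partition.

The same master permutation seed is reused for every ablated run, so
differences between runs reflect the removed feature rather than
Monte-Carlo noise in the reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .cohort import ClusterAssignment, CohortTable, canonicalize_labels
from .hclust import agglomerate_complete, pairwise_distance
from .significance import reference_distribution, significant_clusters

__all__ = ["LofoResult", "lofo_run", "label_concordance", "lofo_table"]


@dataclass
class LofoResult:
    feature_name: str
    n_clusters_without: int
    concordance_abs: float
    degenerate: bool = False  # true when either partition had a single cluster


def primary_run(
    table: CohortTable, alpha: float = 0.004, reps: int = 10, seed: int = 0
) -> ClusterAssignment:
    """Significance-cut clustering of the full table (the primary analysis)."""
    dend = agglomerate_complete(pairwise_distance(table, normalize=True))
    ref = reference_distribution(table, n_reps=reps, seed=seed)
    return significant_clusters(dend, ref, alpha).labels


def lofo_run(
    table: CohortTable,
    feature_name: str,
    alpha: float = 0.004,
    reps: int = 10,
    seed: int = 0,
) -> ClusterAssignment:
    """Rerun the whole significance pipeline without one feature.

    Distance normalization uses sqrt(p-1) on the reduced table, keeping
    heights on the same per-feature scale as the primary run.
    """
    reduced = table.drop_feature(feature_name)  # raises KeyError if unknown
    if reduced.n_features < 1:
        raise ValueError("at least one feature must remain after removal")
    return primary_run(reduced, alpha=alpha, reps=reps, seed=seed)


def label_concordance(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Absolute Spearman correlation between two cluster label vectors.

    Labels are canonicalized first (size-descending numbering) so that
    arbitrary label ids cannot flip the sign; the absolute value is
    reported.  If either partition is a single cluster the correlation is
    undefined and the concordance is defined as 0.
    """
    la = np.asarray(a.labels)
    lb = np.asarray(b.labels)
    if la.shape != lb.shape:
        raise ValueError("label vectors cover different patient sets")
    la = canonicalize_labels(la)
    lb = canonicalize_labels(lb)
    if np.unique(la).size < 2 or np.unique(lb).size < 2:
        return 0.0
    rho = spearmanr(la, lb).statistic
    return float(abs(rho))


def lofo_table(
    table: CohortTable, alpha: float = 0.004, reps: int = 10, seed: int = 0
) -> list[LofoResult]:
    """One ablated rerun + concordance per feature, sorted ascending.

    The most influential features come first (lowest concordance with the
    primary labels).
    """
    primary = primary_run(table, alpha=alpha, reps=reps, seed=seed)
    results = []
    for name in table.feature_names:
        ablated = lofo_run(table, str(name), alpha=alpha, reps=reps, seed=seed)
        degenerate = primary.n_clusters < 2 or ablated.n_clusters < 2
        results.append(
            LofoResult(
                feature_name=str(name),
                n_clusters_without=ablated.n_clusters,
                concordance_abs=label_concordance(primary, ablated),
                degenerate=degenerate,
            )
        )
    results.sort(key=lambda r: (r.concordance_abs, r.feature_name))
    return results
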