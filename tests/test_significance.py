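"""Permutation reference distribution and percentile significance cuts."""

import numpy as np
import pytest

from sepsig import (
    agglomerate_complete,
    pairwise_distance,
    percentile_threshold,
    permute_table,
    qq_pairs,
    reference_distribution,
    significance_ladder,
    significant_clusters,
)
from sepsig.cohort import CohortTable
from sepsig.significance import ReferenceDistribution, SignificanceError

from conftest import standardized_planted, two_phenotype_spec


def test_permutation_preserves_column_marginals(noise_table):
    permuted = permute_table(noise_table, seed=5)
    for j in range(noise_table.n_features):
        assert sorted(permuted.values[:, j]) == pytest.approx(
            sorted(noise_table.values[:, j])
        )


def test_single_patient_table_unchanged():
    t = CohortTable(
        np.array(["p"], dtype=object), np.array(["a", "b"], dtype=object),
        np.array([[1.0, 2.0]]),
    )
    assert np.array_equal(permute_table(t, 0).values, t.values)


def test_different_seeds_differ(noise_table):
    a = permute_table(noise_table, seed=1)
    b = permute_table(noise_table, seed=2)
    assert not np.array_equal(a.values, b.values)


def test_reference_determinism(noise_table):
    r1 = reference_distribution(noise_table, n_reps=5, seed=9)
    r2 = reference_distribution(noise_table, n_reps=5, seed=9)
    assert np.array_equal(r1.values, r2.values)


def test_single_rep_reference_is_that_runs_heights(noise_table):
    ref = reference_distribution(noise_table, n_reps=1, seed=3)
    child = np.random.SeedSequence(3).spawn(1)[0]
    permuted = permute_table(noise_table, child)
    dend = agglomerate_complete(pairwise_distance(permuted))
    assert np.allclose(ref.values, np.sort(dend.heights))


def test_null_table_qq_points_near_diagonal(noise_table):
    dend = agglomerate_complete(pairwise_distance(noise_table))
    ref = reference_distribution(noise_table, n_reps=10, seed=0)
    pairs = np.array(qq_pairs(dend, ref))
    rel = np.abs(pairs[:, 1] - pairs[:, 0]) / pairs[:, 1].max()
    assert np.median(rel) < 0.05
    assert rel.max() < 0.25


def test_planted_separation_exceeds_reference_maximum():
    std, _ = standardized_planted(two_phenotype_spec(n=100, p=30, gap=6.0, seed=1))
    dend = agglomerate_complete(pairwise_distance(std))
    ref = reference_distribution(std, n_reps=10, seed=1)
    assert dend.root_height > ref.values.max()
    pairs = np.array(qq_pairs(dend, ref))
    assert pairs[-1, 1] > pairs[-1, 0]  # top rank above the diagonal


def test_percentile_interpolated_median_by_hand():
    ref = ReferenceDistribution(np.arange(1.0, 101.0), 1, 0)
    assert percentile_threshold(ref, 0.5) == pytest.approx(50.5)


def test_percentile_alpha_to_zero_limit_is_max():
    ref = ReferenceDistribution(np.arange(1.0, 101.0), 1, 0)
    assert percentile_threshold(ref, 1e-12) == pytest.approx(100.0)


@pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
def test_percentile_alpha_domain(alpha):
    ref = ReferenceDistribution(np.arange(1.0, 11.0), 1, 0)
    with pytest.raises(SignificanceError):
        percentile_threshold(ref, alpha)


def test_threshold_above_root_gives_one_cluster(noise_table):
    dend = agglomerate_complete(pairwise_distance(noise_table))
    ref = ReferenceDistribution(
        np.linspace(0.1, dend.root_height * 2, noise_table.n_patients - 1), 1, 0
    )
    cut = significant_clusters(dend, ref, 0.004)
    assert cut.n_clusters == 1


def test_toy_dendrogram_two_clusters():
    t = CohortTable(
        np.array(["a", "b", "c"], dtype=object), np.array(["x"], dtype=object),
        np.array([[0.0], [1.0], [10.0]]),
    )
    dend = agglomerate_complete(pairwise_distance(t, normalize=False))
    # reference whose 99.6 percentile is ~5: between the two merge heights
    ref = ReferenceDistribution(np.array([4.0, 5.0]), 1, 0)
    cut = significant_clusters(dend, ref, 0.004)
    assert cut.n_clusters == 2


def test_mismatched_lengths_rejected(noise_table):
    dend = agglomerate_complete(pairwise_distance(noise_table))
    ref = ReferenceDistribution(np.arange(1.0, 5.0), 1, 0)
    with pytest.raises(SignificanceError, match="length"):
        significant_clusters(dend, ref, 0.004)
    with pytest.raises(SignificanceError):
        qq_pairs(dend, ref)


def test_alpha_ladder_monotone(noise_table):
    dend = agglomerate_complete(pairwise_distance(noise_table))
    ref = reference_distribution(noise_table, n_reps=10, seed=2)
    ladder = significance_ladder(dend, ref, [0.05, 0.01, 0.004, 0.001, 1e-5])
    counts = [c.n_clusters for c in ladder]
    assert counts == sorted(counts, reverse=True)  # smaller alpha, fewer clusters


def test_planted_two_cluster_recovery_with_labels():
    spec = two_phenotype_spec(n=150, p=40, gap=6.0, seed=0)
    std, truth = standardized_planted(spec)
    dend = agglomerate_complete(pairwise_distance(std))
    ref = reference_distribution(std, n_reps=10, seed=0)
    cut = significant_clusters(dend, ref, 0.004)
    assert cut.n_clusters == 2
    # agreement up to relabeling
    agree = max(
        (cut.labels.labels - 1 == truth).mean(),
        (2 - cut.labels.labels == truth).mean(),
    )
    assert agree >= 0.99
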