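import numpy as np
import pytest

from sepsig import CohortSpec, CohortTable, PhenotypeSpec, generate_cohort, standardize


def two_phenotype_spec(
    n=150, p=40, gap=3.0, prevalences=(0.5, 0.5), missing_rate=0.0, seed=0, **outcome_kw
):
    """Two phenotypes with per-feature means +/- gap/2 (total mean gap = gap)."""
    half = gap / 2.0
    phenos = [
        PhenotypeSpec(0, prevalences[0], np.full(p, -half), np.ones(p), **outcome_kw),
        PhenotypeSpec(1, prevalences[1], np.full(p, +half), np.ones(p), **outcome_kw),
    ]
    return CohortSpec(n_patients=n, n_features=p, phenotypes=phenos,
                      missing_rate=missing_rate, seed=seed)


def block_spec(K, n, p, amplitude, seed=0):
    """K phenotypes, each with its own block of elevated features."""
    q = p // K
    phenos = []
    for k in range(K):
        means = np.zeros(p)
        means[k * q:(k + 1) * q] = amplitude
        phenos.append(PhenotypeSpec(k, 1.0 / K, means, np.ones(p)))
    # fix rounding of prevalences
    phenos[-1].prevalence = 1.0 - (K - 1) / K
    return CohortSpec(n_patients=n, n_features=p, phenotypes=phenos, seed=seed)


def standardized_planted(spec):
    table, labels = generate_cohort(spec)
    std, _ = standardize(table)
    return std, labels


@pytest.fixture
def noise_table():
    """Structureless standardized table, 60 patients x 12 features."""
    rng = np.random.default_rng(7)
    values = rng.standard_normal((60, 12))
    table = CohortTable(
        np.array([f"P{i}" for i in range(60)], dtype=object),
        np.array([f"f{j}" for j in range(12)], dtype=object),
        values,
    )
    std, _ = standardize(table)
    return std


@pytest.fixture
def small_table():
    """4 x 3 table with one missing cell, unstandardized."""
    values = np.array(
        [[1.0, 10.0, 0.0], [np.nan, 12.0, 2.0], [3.0, 14.0, 4.0], [5.0, 20.0, 6.0]]
    )
    return CohortTable(
        np.array(["a", "b", "c", "d"], dtype=object),
        np.array(["x", "y", "z"], dtype=object),
        values,
    )
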