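"""Synthetic sepsis cohorts with planted phenotype structure.

Real biomarker panels from the study cohort are not publicly deposited, so
every downstream stage is exercised on generated cohorts: ``n`` patients are
drawn from ``K`` latent phenotypes, each phenotype a diagonal Gaussian over
``p`` standardized features, with per-column MCAR missingness and
phenotype-linked clinical outcomes (14-day mortality, ICU length of stay,
day-14 SOFA persistence).

Features are generated directly on the standardized scale (mixture
components with mean ~0, sd ~1 noise); raw laboratory units are not
emulated because clustering operates on standardized values anyway.

Three independent RNG streams (features, missingness, outcomes) are spawned
from the master seed, so e.g. requesting outcomes never perturbs the
feature draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import CohortTable
from .outcomes import OutcomeRecord, SOFA_SYSTEMS

__all__ = ["PhenotypeSpec", "CohortSpec", "generate_cohort", "generate_outcomes"]


class SpecError(ValueError):
    """A cohort specification violates one of its invariants."""


@dataclass
class PhenotypeSpec:
    """One latent phenotype: feature distribution plus outcome propensities.

    ``feature_means``/``feature_sds`` are in standardized units (one entry
    per cohort feature).  ``mortality_14d`` is the probability of death
    within 14 days of sepsis onset; ``icu_los_mean`` the mean ICU length of
    stay in days; ``sofa_persist_prob`` the probability that day-14 SOFA
    criteria for persistent organ dysfunction are met.
    """

    id: int
    prevalence: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    mortality_14d: float = 0.1
    icu_los_mean: float = 8.0
    sofa_persist_prob: float = 0.3

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)

    def validate(self, n_features: int) -> None:
        if not (0 < self.prevalence <= 1):
            raise SpecError(f"phenotype {self.id}: prevalence must be in (0,1]")
        for name in ("mortality_14d", "sofa_persist_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SpecError(f"phenotype {self.id}: {name} must be in [0,1]")
        if self.icu_los_mean <= 0:
            raise SpecError(f"phenotype {self.id}: icu_los_mean must be positive")
        if self.feature_means.shape != (n_features,):
            raise SpecError(
                f"phenotype {self.id}: feature_means length "
                f"{self.feature_means.size} != n_features {n_features}"
            )
        if self.feature_sds.shape != (n_features,):
            raise SpecError(
                f"phenotype {self.id}: feature_sds length "
                f"{self.feature_sds.size} != n_features {n_features}"
            )
        if np.any(self.feature_sds <= 0):
            raise SpecError(f"phenotype {self.id}: feature_sds must be positive")


@dataclass
class CohortSpec:
    n_patients: int
    n_features: int
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise SpecError("n_patients must be >= 4")
        if self.n_features < 2:
            raise SpecError("n_features must be >= 2")
        if not self.phenotypes:
            raise SpecError("at least one phenotype is required")
        if not (0 <= self.missing_rate < 1):
            raise SpecError("missing_rate must be in [0,1)")
        total = sum(ph.prevalence for ph in self.phenotypes)
        if abs(total - 1.0) > 1e-8:
            raise SpecError(f"phenotype prevalences sum to {total}, expected 1")
        for ph in self.phenotypes:
            ph.validate(self.n_features)

    # -- YAML -------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortSpec":
        phenos = [
            PhenotypeSpec(
                id=int(ph["id"]),
                prevalence=float(ph["prevalence"]),
                feature_means=np.asarray(ph["feature_means"], dtype=float),
                feature_sds=np.asarray(ph["feature_sds"], dtype=float),
                mortality_14d=float(ph.get("mortality_14d", 0.1)),
                icu_los_mean=float(ph.get("icu_los_mean", 8.0)),
                sofa_persist_prob=float(ph.get("sofa_persist_prob", 0.3)),
            )
            for ph in raw["phenotypes"]
        ]
        return cls(
            n_patients=int(raw["n_patients"]),
            n_features=int(raw["n_features"]),
            phenotypes=phenos,
            missing_rate=float(raw.get("missing_rate", 0.0)),
            seed=int(raw.get("seed", 0)),
        )


def _streams(seed: int):
    """One independent child stream per logical draw."""
    ss = np.random.SeedSequence(seed)
    feat, miss, out = ss.spawn(3)
    return (
        np.random.default_rng(feat),
        np.random.default_rng(miss),
        np.random.default_rng(out),
    )


def _allocate_labels(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Exact prevalence counts (largest remainder), then a seeded shuffle.

    Allocating counts deterministically rather than sampling a multinomial
    honors the stated prevalences exactly and keeps class sizes free of
    sampling noise.
    """
    n = spec.n_patients
    quotas = np.array([ph.prevalence * n for ph in spec.phenotypes])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder:
        frac_order = np.argsort(-(quotas - counts), kind="stable")
        for k in frac_order[:remainder]:
            counts[k] += 1
    labels = np.repeat([ph.id for ph in spec.phenotypes], counts)
    rng.shuffle(labels)
    return labels


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, np.ndarray]:
    """Draw a cohort table and its ground-truth phenotype labels.

    Each patient's feature vector is drawn from its phenotype's per-feature
    normal distribution; missingness is applied independently per cell at
    ``spec.missing_rate``.  Bit-identical output for identical spec + seed.
    """
    spec.validate()
    rng_feat, rng_miss, _ = _streams(spec.seed)

    labels = _allocate_labels(spec, rng_feat)
    by_id = {ph.id: ph for ph in spec.phenotypes}
    n, p = spec.n_patients, spec.n_features
    means = np.stack([by_id[l].feature_means for l in labels])
    sds = np.stack([by_id[l].feature_sds for l in labels])
    values = means + sds * rng_feat.standard_normal((n, p))

    mask = rng_miss.random((n, p)) < spec.missing_rate
    values = np.where(mask, np.nan, values)

    ids = np.array([f"P{i:04d}" for i in range(n)], dtype=object)
    names = np.array([f"bm{j:03d}" for j in range(p)], dtype=object)
    table = CohortTable(ids, names, values, mask)
    return table, labels


def generate_outcomes(true_labels: np.ndarray, spec: CohortSpec) -> list[OutcomeRecord]:
    """Sample phenotype-linked outcome records for each patient.

    Death within 14 days is Bernoulli(``mortality_14d``) with a uniform
    death day in 1..14; ICU length of stay is geometric with the
    phenotype's mean (truncated at the death day); day-14 SOFA components
    are sampled so that ``sofa_persist_prob`` controls whether the
    persistent-organ-dysfunction gates (cardiovascular >=1 or any other
    system >=2) are met.
    """
    spec.validate()
    by_id = {ph.id: ph for ph in spec.phenotypes}
    unknown = set(np.unique(np.asarray(true_labels))) - set(by_id)
    if unknown:
        raise SpecError(f"labels reference unknown phenotypes: {sorted(unknown)}")
    _, _, rng = _streams(spec.seed)

    records: list[OutcomeRecord] = []
    for i, lab in enumerate(np.asarray(true_labels)):
        ph = by_id[int(lab)]
        dies_early = rng.random() < ph.mortality_14d
        death_day = int(rng.integers(1, 15)) if dies_early else None

        icu = int(rng.geometric(min(1.0, 1.0 / ph.icu_los_mean)))
        if death_day is not None:
            icu = min(icu, death_day)
        hospital = icu + int(rng.geometric(0.2)) - 1
        if death_day is not None:
            hospital = min(hospital, death_day)
        vent = int(rng.binomial(icu, 0.6))
        rrt = int(rng.binomial(icu, 0.15))

        persist = rng.random() < ph.sofa_persist_prob
        sofa: dict[str, int] = {}
        if persist:
            sofa["cardiovascular"] = int(rng.integers(1, 5))
            for sys_ in SOFA_SYSTEMS[1:]:
                sofa[sys_] = int(rng.integers(0, 5))
        else:
            sofa["cardiovascular"] = 0
            for sys_ in SOFA_SYSTEMS[1:]:
                sofa[sys_] = int(rng.integers(0, 2))

        records.append(
            OutcomeRecord(
                patient_id=f"P{i:04d}",
                death_day=death_day,
                icu_los=icu,
                hospital_los=hospital,
                ventilator_days=vent,
                rrt_days=rrt,
                day14_sofa=sofa,
            )
        )
    return records
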