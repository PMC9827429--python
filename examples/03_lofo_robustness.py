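"""Leave-one-feature-out robustness of a cluster assignment.

A strongly two-clustered panel is augmented with two pure-noise columns.
Each feature is removed in turn, the whole significance pipeline is rerun,
and the absolute Spearman concordance with the primary labels is reported:
1.0 means the partition is untouched, low values flag load-bearing features.
"""

import numpy as np

from sepsig import CohortSpec, CohortTable, PhenotypeSpec, generate_cohort, lofo_table, standardize

p = 10
spec = CohortSpec(
    n_patients=80, n_features=p,
    phenotypes=[
        PhenotypeSpec(0, 0.5, np.full(p, -3.0), np.ones(p)),
        PhenotypeSpec(1, 0.5, np.full(p, +3.0), np.ones(p)),
    ],
    seed=2,
)
table, _ = generate_cohort(spec)

rng = np.random.default_rng(2)
values = np.hstack([table.values, rng.standard_normal((80, 2))])
names = np.array(list(table.feature_names) + ["noiseA", "noiseB"], dtype=object)
std, _ = standardize(CohortTable(table.patient_ids, names, values))

results = lofo_table(std, alpha=0.004, reps=10, seed=2)
print("feature        clusters_without  |rho|")
for r in results[:3] + results[-3:]:
    print(f"{r.feature_name:<14} {r.n_clusters_without:^16d} {r.concordance_abs:.3f}")
# every concordance is 1.0 here because the signal is shared by ten
# biomarkers: no single feature is indispensable, noise columns least of all
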