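"""Outcome adjudication and a clinical-style two-group comparison table.

Phenotype-linked outcomes are adjudicated into early death / chronic
critical illness (CCI) / non-CCI, 28-day ICU-free days are computed with
death censoring, and the groups are compared with exact and rank tests.
"""

from collections import Counter

import numpy as np
import pandas as pd

from sepsig import (
    CohortSpec,
    PhenotypeSpec,
    classify_cci,
    compare_groups,
    free_days,
    generate_cohort,
    generate_outcomes,
)

p = 8
spec = CohortSpec(
    n_patients=157, n_features=p,
    phenotypes=[
        PhenotypeSpec(0, 18 / 157, np.full(p, -1.5), np.ones(p),
                      mortality_14d=0.3, icu_los_mean=15.0, sofa_persist_prob=0.6),
        PhenotypeSpec(1, 139 / 157, np.full(p, +1.5), np.ones(p),
                      mortality_14d=0.02, icu_los_mean=6.0, sofa_persist_prob=0.2),
    ],
    seed=3,
)
_, truth = generate_cohort(spec)
records = generate_outcomes(truth, spec)

by_group = {0: Counter(), 1: Counter()}
icu_free = []
for rec, g in zip(records, truth):
    by_group[g][classify_cci(rec)] += 1
    icu_free.append(free_days(rec.icu_los, rec.death_day))
print("adjudication, high-risk phenotype:", dict(by_group[0]))
print("adjudication, low-risk phenotype:", dict(by_group[1]))

data = pd.DataFrame(
    {
        "icu_free_days": icu_free,
        "rrt_any": [r.rrt_days > 0 for r in records],
    }
)
for row in compare_groups(data, truth):
    print(f"{row.variable}: {row.group_summaries}  [{row.test}] p={row.p_value:.2g}")
# the high-risk phenotype loses most of its 28 ICU-free days and carries
# the CCI/early-death burden, mirroring the outcome contrast between
# clusters in real sepsis cohorts
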