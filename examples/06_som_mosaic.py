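"""Self-organizing-map biomarker mosaics for two phenotypes.

Biomarkers are arranged on a small 2-D grid so that correlated markers
share or neighbor tiles; coloring each tile by a cluster's mean
standardized value gives that cluster's visual signature (red = above the
cohort mean, green = near it, blue = below).
"""

import numpy as np

from sepsig import (
    ClusterAssignment,
    CohortSpec,
    PhenotypeSpec,
    cluster_mosaic,
    generate_cohort,
    standardize,
    train_som,
)

p = 16
spec = CohortSpec(
    n_patients=120, n_features=p,
    phenotypes=[
        PhenotypeSpec(0, 0.3, np.full(p, -2.0), np.ones(p)),
        PhenotypeSpec(1, 0.7, np.full(p, +2.0), np.ones(p)),
    ],
    seed=4,
)
table, truth = generate_cohort(spec)
std, _ = standardize(table)

grid = train_som(std, rows=4, cols=4, epochs=50, seed=4)
assign = ClusterAssignment(truth + 1)

whole = cluster_mosaic(grid, std, None)
print(f"grid {grid.rows}x{grid.cols}; cohort mosaic mean {np.nanmean(whole):+.3f}")
for c in (1, 2):
    mosaic = cluster_mosaic(grid, std, assign, c)
    print(f"cluster {c} mosaic (tile means):")
    with np.printoptions(precision=2, suppress=True):
        print(mosaic)
# the two mosaics are near mirror images: one phenotype sits uniformly
# above the cohort mean (all-red), the other below (all-blue)
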