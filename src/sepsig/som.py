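"""Self-organizing-map biomarker mosaics.

Each biomarker's standardized patient profile (a length-n vector) is one
training item; a small 2-D grid of prototypes is trained with the classic
batch SOM update so that correlated biomarkers land on nearby tiles.  A
per-cluster "mosaic" then colors each tile by the mean standardized value
of its biomarkers over the patients of that cluster — red above the cohort
mean, green near it, blue below — giving a compact visual signature per
phenotype.

The batch formulation (recompute all best-matching units, then replace
every prototype by its neighborhood-weighted mean of items) is fully
deterministic given the seed; the Gaussian neighborhood radius decays
linearly from max(rows, cols)/2 to 0.5 over the epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cohort import ClusterAssignment, CohortTable

__all__ = ["SOMGrid", "train_som", "cluster_mosaic", "quantization_error"]

COLOR_SCALE = {"positive": "red", "zero": "green", "negative": "blue"}


class SOMError(ValueError):
    pass


@dataclass
class SOMGrid:
    rows: int
    cols: int
    prototypes: np.ndarray          # (rows*cols, n_patients)
    feature_tiles: np.ndarray       # tile index per feature
    feature_names: np.ndarray
    seed: int
    epochs: int

    def tile_of(self, feature_name: str) -> tuple[int, int]:
        j = int(np.nonzero(self.feature_names == feature_name)[0][0])
        t = int(self.feature_tiles[j])
        return divmod(t, self.cols)

    def tile_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {t: [] for t in range(self.rows * self.cols)}
        for name, t in zip(self.feature_names, self.feature_tiles):
            out[int(t)].append(str(name))
        return out

    def color_scale_json(self, path=None):
        payload = {"color_scale": COLOR_SCALE, "rows": self.rows, "cols": self.cols}
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload


def default_grid_shape(n_features: int) -> tuple[int, int]:
    """Smallest near-square grid with at least one tile per feature."""
    r = max(1, int(np.floor(np.sqrt(n_features))))
    c = int(np.ceil(n_features / r))
    if r * c < 2:
        c = 2
    return r, c


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def quantization_error(items: np.ndarray, prototypes: np.ndarray) -> float:
    """Mean Euclidean distance of items to their best-matching prototype."""
    d = np.linalg.norm(items[:, None, :] - prototypes[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def train_som(
    table: CohortTable,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 50,
    seed: int = 0,
) -> SOMGrid:
    """Train a batch SOM over the feature profiles of a standardized table."""
    if table.has_missing:
        raise SOMError("SOM training requires an imputed table")
    if rows is None or cols is None:
        rows, cols = default_grid_shape(table.n_features)
    if rows * cols < 2:
        raise SOMError("grid must have at least 2 tiles")
    items = table.values.T.copy()              # (p, n): one item per feature
    n_tiles = rows * cols
    coords = _grid_coords(rows, cols)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(items.shape[0], size=n_tiles, replace=items.shape[0] < n_tiles)
    prototypes = items[init_idx].astype(float) + 1e-9 * rng.standard_normal((n_tiles, items.shape[1]))

    r0 = max(rows, cols) / 2.0
    r_final = 0.5
    for epoch in range(epochs):
        frac = epoch / max(1, epochs - 1)
        radius = r0 + (r_final - r0) * frac
        d = np.linalg.norm(items[:, None, :] - prototypes[None, :, :], axis=2)
        bmu = d.argmin(axis=1)
        h = np.exp(-grid_d2[:, bmu] / (2.0 * radius**2))   # (tiles, items)
        weights = h.sum(axis=1, keepdims=True)
        prototypes = (h @ items) / weights

    d = np.linalg.norm(items[:, None, :] - prototypes[None, :, :], axis=2)
    bmu = d.argmin(axis=1)
    return SOMGrid(rows, cols, prototypes, bmu, table.feature_names.copy(), seed, epochs)


def cluster_mosaic(
    grid: SOMGrid,
    table: CohortTable,
    labels: ClusterAssignment | np.ndarray | None,
    cluster_id: int | None = None,
) -> np.ndarray:
    """Tile-intensity matrix for one cluster (or the whole cohort).

    intensity(tile) = mean standardized value over the tile's features and
    the cluster's patients; tiles without features are NaN (flagged empty).
    With ``labels=None`` the mosaic covers the whole cohort.
    """
    if labels is None:
        patient_mask = np.ones(table.n_patients, dtype=bool)
    else:
        y = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels)
        patient_mask = y == cluster_id
        if not patient_mask.any():
            raise SOMError(f"cluster {cluster_id} is empty")
    name_to_col = {n: j for j, n in enumerate(table.feature_names)}
    out = np.full((grid.rows, grid.cols), np.nan)
    for t, members in grid.tile_members().items():
        if not members:
            continue
        cols = [name_to_col[m] for m in members]
        out[divmod(t, grid.cols)] = table.values[np.ix_(patient_mask, cols)].mean()
    return out
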