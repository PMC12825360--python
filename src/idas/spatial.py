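"""Spatial nearest-neighbor correlation features.

For spatially resolved expression, the per-sample, per-gene feature is the
Pearson correlation between each cell's expression and the expression of
its single nearest spatial neighbor (nnCorrelation). Collected across
samples with a two-factor sample design, the feature matrix can be fed to
the two-way classifier exactly like a pseudobulk matrix: genes whose
spatial coherence depends on a factor (or on the interaction of two
factors) come out in the corresponding category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .classify import ThresholdPolicy, classify_two_way
from .datatypes import (
    GeneClassification,
    ObservationDesign,
    PseudobulkMatrix,
    SingleCellDataset,
)

logger = logging.getLogger(__name__)


@dataclass
class SpatialFeatureMatrix:
    """Genes x samples matrix of nnCorrelation values.

    Entries are in [-1, 1] or NaN where the correlation is undefined
    (zero-variance expression); NaN is an explicit "undefined" marker and
    is never silently zeroed.
    """

    values: np.ndarray
    gene_ids: list[str]
    design: ObservationDesign

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        defined = self.values[np.isfinite(self.values)]
        if defined.size and (defined.min() < -1 - 1e-9 or defined.max() > 1 + 1e-9):
            raise ValueError("defined nnCorrelation values must lie in [-1, 1]")

    def to_pseudobulk(self) -> PseudobulkMatrix:
        return PseudobulkMatrix(values=self.values, gene_ids=list(self.gene_ids),
                                design=self.design)


def nearest_neighbor(coords: np.ndarray) -> np.ndarray:
    """Index of each cell's closest other cell (Euclidean; self excluded).

    Distance ties are broken by the smallest cell index so results are
    deterministic on lattices. Duplicate coordinates are valid (distance 0
    to another cell).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("nearest neighbors require >= 2 cells")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    tree = cKDTree(coords)
    k = min(n, 8)
    dist, idx = tree.query(coords, k=k)
    nn = np.empty(n, dtype=int)
    for i in range(n):
        d, j = dist[i], idx[i]
        keep = j != i
        d, j = d[keep], j[keep]
        if len(d) == 0:  # all k hits were self-duplicates; fall back
            d = np.linalg.norm(coords - coords[i], axis=1)
            d[i] = np.inf
            nn[i] = int(np.argmin(d))
            continue
        dmin = d.min()
        ties = j[np.isclose(d, dmin, rtol=0.0, atol=1e-12)]
        # guard: dmin could tie with neighbors beyond the k queried
        if k < n and np.isclose(dist[i][-1], dmin, rtol=0.0, atol=1e-12):
            dall = np.linalg.norm(coords - coords[i], axis=1)
            dall[i] = np.inf
            ties = np.flatnonzero(np.isclose(dall, dall.min(), rtol=0.0, atol=1e-12))
        nn[i] = int(ties.min())
    return nn


def nn_correlation(values: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Per-gene Pearson correlation between own and nearest-neighbor expression.

    ``values`` is genes x cells. Uses directed pairs (i, nn(i)) for every
    cell i. Genes whose own or neighbor vector has zero variance get NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 3:
        raise ValueError("nnCorrelation requires >= 3 cells")
    nn = nearest_neighbor(coords)
    own = values
    nbr = values[:, nn]
    own_c = own - own.mean(axis=1, keepdims=True)
    nbr_c = nbr - nbr.mean(axis=1, keepdims=True)
    denom = np.sqrt((own_c ** 2).sum(axis=1) * (nbr_c ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (own_c * nbr_c).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))


def nn_correlation_dataset(ds: SingleCellDataset) -> np.ndarray:
    """nnCorrelation column for one sample's dataset carrying x/y coordinates."""
    if not ds.has_coordinates:
        raise ValueError("dataset has no x/y coordinates")
    coords = ds.cell_meta[["x", "y"]].to_numpy(float)
    return nn_correlation(ds.values, coords)


def build_feature_matrix(per_sample: dict[str, SingleCellDataset],
                         design: ObservationDesign) -> SpatialFeatureMatrix:
    """Assemble the genes x samples nnCorrelation matrix in design order."""
    first = next(iter(per_sample.values()))
    gene_ids = list(first.gene_ids)
    cols = []
    for obs in design.obs_ids:
        if obs not in per_sample:
            raise ValueError(f"no spatial data for sample {obs!r}")
        ds = per_sample[obs]
        if list(ds.gene_ids) != gene_ids:
            raise ValueError("samples disagree on the gene set")
        cols.append(nn_correlation_dataset(ds))
    return SpatialFeatureMatrix(values=np.column_stack(cols), gene_ids=gene_ids,
                                design=design)


def spatial_idas(features: SpatialFeatureMatrix, policy: ThresholdPolicy,
                 max_undefined: float = 0.2) -> GeneClassification:
    """Two-way classification with nnCorrelation as the per-gene response.

    Genes undefined in at least ``max_undefined`` of the samples are
    excluded before classification (logged); remaining NaN entries are
    dropped per gene inside the fits.
    """
    frac_undef = np.mean(~np.isfinite(features.values), axis=1)
    keep = frac_undef < max_undefined
    dropped = [g for g, k in zip(features.gene_ids, keep) if not k]
    if dropped:
        logger.warning("excluding %d gene(s) with >= %.0f%% undefined "
                       "nnCorrelation: %s%s", len(dropped), 100 * max_undefined,
                       dropped[:5], "..." if len(dropped) > 5 else "")
    if not keep.any():
        raise ValueError("no genes with sufficiently defined nnCorrelation")
    pb = PseudobulkMatrix(
        values=features.values[keep],
        gene_ids=[g for g, k in zip(features.gene_ids, keep) if k],
        design=features.design,
    )
    return classify_two_way(pb, policy)


def feature_frame(features: SpatialFeatureMatrix) -> pd.DataFrame:
    """Genes x samples frame with NaN as the undefined marker."""
    return pd.DataFrame(features.values,
                        index=pd.Index(features.gene_ids, name="gene_id"),
                        columns=features.design.obs_ids)
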