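"""Pseudobulk aggregation of single-cell expression.

One observation per (sample, cell state[, timepoint]) group: the mean of
the cell values on their input scale, then log2(mean + pseudocount).
Aggregating to pseudobulk trades cell-level resolution for approximate
normality, which is what lets the downstream Gaussian ANOVA machinery
apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ObservationDesign, PseudobulkMatrix, SingleCellDataset

logger = logging.getLogger(__name__)

VALID_GROUP_KEYS = ("sample_id", "state", "timepoint")


def aggregate(ds: SingleCellDataset, group_keys: tuple[str, ...] = ("sample_id", "state"),
              pseudocount: float = 1.0, min_cells: int = 1) -> PseudobulkMatrix:
    """Aggregate cells into log2 pseudobulk observations.

    The design attached to the result maps ``state`` to f1 and the
    sample-level ``phenotype`` to f2; when ``timepoint`` is grouped it
    becomes f1 and the cell state becomes f3, with the sample's subject id
    (or sample id) as the random-intercept grouping — mirroring a
    longitudinal pre/on-treatment design.

    Groups with fewer than ``min_cells`` cells are dropped (logged);
    a sample whose cells disagree on phenotype is an error.
    """
    if not set(group_keys) <= set(VALID_GROUP_KEYS):
        raise ValueError(f"group_keys must be among {VALID_GROUP_KEYS}")
    if not {"sample_id", "state"} <= set(group_keys):
        raise ValueError("group_keys must include sample_id and state")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    meta = ds.cell_meta
    for key in group_keys:
        if key not in meta.columns:
            raise ValueError(f"metadata has no column {key!r}")

    # phenotype is a sample-level attribute: conflicting cells are an error
    pheno_per_sample = meta.groupby("sample_id")["phenotype"].nunique()
    bad = pheno_per_sample[pheno_per_sample > 1]
    if len(bad):
        raise ValueError(
            f"samples with conflicting per-cell phenotype: {list(bad.index[:5])}")
    sample_pheno = meta.groupby("sample_id")["phenotype"].first()

    keys = [meta[k].astype(str) for k in group_keys]
    group_frame = pd.DataFrame({k: v for k, v in zip(group_keys, keys)})
    obs_values, obs_meta = [], []
    for name, idx in sorted(group_frame.groupby(list(group_keys)).groups.items()):
        n = len(idx)
        if n < min_cells:
            logger.info("dropping group %s with %d cell(s) < min_cells=%d",
                        name, n, min_cells)
            continue
        pos = meta.index.get_indexer(idx)
        mean = ds.values[:, pos].mean(axis=1)
        obs_values.append(np.log2(mean + pseudocount))
        rec = dict(zip(group_keys, name if isinstance(name, tuple) else (name,)))
        obs_meta.append(rec)
    if not obs_values:
        raise ValueError("no groups survive min_cells filtering")

    om = pd.DataFrame(obs_meta)
    om["phenotype"] = om["sample_id"].map(sample_pheno).astype(str)
    obs_ids = ["|".join(row[k] for k in (*group_keys,)) for _, row in om.iterrows()]
    three_way = "timepoint" in group_keys
    if three_way:
        subject = (meta.groupby("sample_id")["subject_id"].first()
                   if "subject_id" in meta.columns else None)
        design = ObservationDesign(
            obs_ids=obs_ids,
            f1=om["timepoint"].to_numpy(),
            f2=om["phenotype"].to_numpy(),
            f3=om["state"].to_numpy(),
            subject=(om["sample_id"].map(subject).to_numpy()
                     if subject is not None else om["sample_id"].to_numpy()),
        )
    else:
        design = ObservationDesign(
            obs_ids=obs_ids,
            f1=om["state"].to_numpy(),
            f2=om["phenotype"].to_numpy(),
        )
    return PseudobulkMatrix(
        values=np.column_stack(obs_values),
        gene_ids=list(ds.gene_ids),
        design=design,
    )


@dataclass
class DesignSummary:
    """Replication structure of a pseudobulk design."""

    counts: pd.Series  # observations per factor-level combination
    missing: list[tuple]  # combinations with zero observations
    under_replicated: list[tuple]  # combinations with < 2 observations
    saturated: bool  # every combination has exactly one observation

    def __str__(self) -> str:
        lines = [f"{len(self.counts)} factor-level combinations"]
        if self.missing:
            lines.append(f"missing: {self.missing}")
        if self.under_replicated:
            lines.append(f"< 2 replicates: {self.under_replicated}")
        if self.saturated:
            lines.append("full model saturated: zero residual degrees of freedom")
        return "\n".join(lines)


def design_summary(pb: PseudobulkMatrix) -> DesignSummary:
    """Count observations per factor-level combination and flag starved cells.

    A design where every combination has exactly one observation leaves the
    full factorial model with zero residual df, which makes the stage
    F-tests undefined — flagged as saturated.
    """
    design = pb.design
    factors = design.factors()
    frame = pd.DataFrame({k: v.astype(str) for k, v in factors.items()})
    observed = frame.value_counts()
    full_index = pd.MultiIndex.from_product(
        [design.levels(k) for k in factors], names=list(factors))
    counts = observed.reindex(full_index, fill_value=0)
    missing = [tuple(ix) for ix, c in counts.items() if c == 0]
    under = [tuple(ix) for ix, c in counts.items() if c == 1]
    saturated = bool((counts <= 1).all())
    if missing:
        logger.warning("factor-level combinations with no observations: %s", missing)
    if saturated:
        logger.warning("every combination has <= 1 observation: "
                       "full model saturated")
    return DesignSummary(counts=counts, missing=missing,
                         under_replicated=under, saturated=saturated)
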