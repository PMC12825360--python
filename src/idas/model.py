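"""Model/Results interface over the staged classifier.

``IDASModel`` is built from a pseudobulk matrix (or constructed from a
single-cell dataset or plain dataframes); ``fit()`` runs the staged
nested-ANOVA classification and returns an ``IDASResults`` carrying the
per-gene categories and stage p-values, with the post-hoc differential
expression analyses and diagnostics as methods.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import posthoc
from .classify import ThresholdPolicy, classify_two_way, classify_three_way
from .datatypes import (
    GeneClassification,
    ObservationDesign,
    PseudobulkMatrix,
    SingleCellDataset,
)
from .pseudobulk import DesignSummary, aggregate, design_summary


class IDASModel:
    """Staged factorial classification model for a pseudobulk matrix.

    Parameters
    ----------
    pseudobulk
        Genes x observations log2 expression with its factor design.
    policy
        Threshold policy for the stage tests (default: BH-adjusted
        p <= 0.05 at every stage).
    three_way
        Force the two-way or three-way route; by default inferred from
        whether the design carries a third factor.

    Examples
    --------
    >>> from idas import IDASModel, simulate_two_way
    >>> pb, truth = simulate_two_way(n_per_category=20, seed=1)
    >>> res = IDASModel(pb).fit()
    >>> res.category_counts["F1"] > 0
    True
    """

    def __init__(self, pseudobulk: PseudobulkMatrix,
                 policy: Optional[ThresholdPolicy] = None,
                 three_way: Optional[bool] = None):
        self.pseudobulk = pseudobulk
        self.policy = policy or ThresholdPolicy()
        self.three_way = (pseudobulk.design.is_three_way
                          if three_way is None else bool(three_way))
        if self.three_way and not pseudobulk.design.is_three_way:
            raise ValueError("three_way=True but the design has no f3 factor")

    @classmethod
    def from_single_cell(cls, ds: SingleCellDataset,
                         group_keys: tuple[str, ...] = ("sample_id", "state"),
                         pseudocount: float = 1.0, min_cells: int = 1,
                         policy: Optional[ThresholdPolicy] = None) -> "IDASModel":
        """Aggregate a single-cell dataset to pseudobulk and build the model."""
        pb = aggregate(ds, group_keys=group_keys, pseudocount=pseudocount,
                       min_cells=min_cells)
        return cls(pb, policy=policy)

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, design: pd.DataFrame,
                       policy: Optional[ThresholdPolicy] = None) -> "IDASModel":
        """Build from a genes x observations frame and a design frame.

        ``design`` is indexed by observation id with columns f1, f2
        (optional f3, subject), matching the values columns.
        """
        od = ObservationDesign.from_frame(design.loc[values.columns])
        pb = PseudobulkMatrix(values=values.to_numpy(float),
                              gene_ids=list(values.index.astype(str)), design=od)
        return cls(pb, policy=policy)

    def design_summary(self) -> DesignSummary:
        return design_summary(self.pseudobulk)

    def fit(self) -> "IDASResults":
        if self.three_way:
            gc = classify_three_way(self.pseudobulk, self.policy)
        else:
            gc = classify_two_way(self.pseudobulk, self.policy)
        return IDASResults(self, gc)


class IDASResults:
    """Fitted classification: categories, stage p-values, and post-hoc DE."""

    def __init__(self, model: IDASModel, classification: GeneClassification):
        self.model = model
        self.classification = classification

    @property
    def table(self) -> pd.DataFrame:
        return self.classification.table

    @property
    def category_counts(self) -> pd.Series:
        return self.classification.counts()

    def genes_in(self, category: str) -> list[str]:
        return self.classification.genes_in(category)

    def summary(self) -> str:
        gc = self.classification
        lines = [
            "iDAS classification",
            "===================",
            f"genes:            {len(gc.table)}",
            f"design:           {'three-way (random intercept)' if self.model.three_way else 'two-way (fixed effects)'}",
            f"threshold:        {gc.threshold_mode} at {gc.level}"
            f" on {'adjusted' if gc.use_adjusted else 'raw'} p",
            "",
            "category counts",
            "---------------",
        ]
        for cat, n in self.category_counts.items():
            lines.append(f"{cat:>16}  {n}")
        n_flagged = len(gc.reasons)
        if n_flagged:
            lines.append("")
            lines.append(f"{n_flagged} gene(s) carried a routing reason "
                         "(zero variance / untestable / ambiguous)")
        return "\n".join(lines)

    # ---- post-hoc differential expression -------------------------------

    def cellstate_markers(self, category: str = "F1", **kwargs):
        """One-vs-rest cell-state markers for the main-effect genes."""
        return posthoc.cellstate_markers(self.model.pseudobulk,
                                         self.genes_in(category), **kwargs)

    def phenotype_signature(self, category: str = "F2", **kwargs):
        """Signed phenotype contrast for the phenotype main-effect genes."""
        return posthoc.phenotype_signature(self.model.pseudobulk,
                                           self.genes_in(category), **kwargs)

    def interaction_markers(self, category: str = "F1xF2", top_k: int = 10, **kwargs):
        """Cell-state-specific phenotype markers from the interaction genes."""
        return posthoc.interaction_markers(self.model.pseudobulk,
                                           self.genes_in(category),
                                           top_k=top_k, **kwargs)

    # ---- output ----------------------------------------------------------

    def save(self, path) -> None:
        from .io import write_classification
        write_classification(self.classification, path)

    def plot_category_counts(self, ax=None):
        """Bar chart of genes per category (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        counts = self.category_counts
        ax.bar(range(len(counts)), counts.to_numpy(), color="#4878d0")
        ax.set_xticks(range(len(counts)))
        ax.set_xticklabels(counts.index, rotation=45, ha="right")
        ax.set_ylabel("genes")
        ax.set_title("iDAS categories")
        return ax
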