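"""Shared domain types for the iDAS pipeline.

The central containers are :class:`SingleCellDataset` (cells with metadata,
optionally spatial coordinates and a differential-abundance selection flag),
:class:`ObservationDesign` (the factor structure of pseudobulk observations),
:class:`PseudobulkMatrix` (genes x observations, log2 scale), and the two
result containers :class:`GeneClassification` and :class:`DEResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TWO_WAY_CATEGORIES = ("F1", "F2", "F1xF2", "F1+F2", "non-sig")
THREE_WAY_CATEGORIES = (
    "F1",
    "F2",
    "F3",
    "F1xF2",
    "F2xF3",
    "F1xF3",
    "two-way-combine",
    "additive",
    "F1xF2xF3",
    "non-sig",
)

REQUIRED_CELL_META = ("sample_id", "state", "phenotype")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).loc[pd.Series(ids).duplicated()].unique()
        raise ValueError(f"duplicate {what}: {list(dupes[:5])}")
    return ids


@dataclass
class SingleCellDataset:
    """Expression values (genes x cells) plus per-cell metadata.

    ``cell_meta`` is indexed by cell id and must carry ``sample_id``,
    ``state`` and ``phenotype`` columns; ``timepoint``, ``subject_id``,
    ``x``/``y`` coordinates and a ``da_selected`` flag are optional.
    ``da_selected`` may be boolean or a signed group label (any non-null
    value marks the cell as selected by the upstream DA method).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        missing = [c for c in REQUIRED_CELL_META if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell metadata missing required column(s): {missing}")
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta.index = pd.Index(self.cell_ids, name="cell_id")
        for col in REQUIRED_CELL_META:
            if self.cell_meta[col].isna().any():
                bad = self.cell_meta.index[self.cell_meta[col].isna()][:5]
                raise ValueError(f"missing '{col}' for cells {list(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, mask: np.ndarray) -> "SingleCellDataset":
        mask = np.asarray(mask, dtype=bool)
        ids = [c for c, keep in zip(self.cell_ids, mask) if keep]
        return SingleCellDataset(
            values=self.values[:, mask],
            gene_ids=list(self.gene_ids),
            cell_ids=ids,
            cell_meta=self.cell_meta.loc[mask],
        )

    @property
    def has_coordinates(self) -> bool:
        return {"x", "y"}.issubset(self.cell_meta.columns)

    @classmethod
    def from_anndata(cls, adata, layer: Optional[str] = None) -> "SingleCellDataset":
        """Thin adapter from an AnnData object (cells x genes convention)."""
        X = adata.layers[layer] if layer else adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return cls(
            values=np.asarray(X).T,
            gene_ids=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            cell_meta=adata.obs.copy(),
        )


@dataclass
class ObservationDesign:
    """Factor-level assignment of pseudobulk observations.

    ``f1``/``f2`` (and optional ``f3``) are the crossed factors of interest;
    ``subject`` is the optional random-intercept grouping required by the
    three-way random-effect model. Replication is implicit: multiple
    observations sharing a factor-level combination are replicates.
    """

    obs_ids: list[str]
    f1: np.ndarray
    f2: np.ndarray
    f3: Optional[np.ndarray] = None
    subject: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.obs_ids = _check_unique(self.obs_ids, "observation ids")
        n = len(self.obs_ids)
        self.f1 = np.asarray(self.f1, dtype=object)
        self.f2 = np.asarray(self.f2, dtype=object)
        for name, arr in (("f1", self.f1), ("f2", self.f2)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} observations")
        if self.f3 is not None:
            self.f3 = np.asarray(self.f3, dtype=object)
            if len(self.f3) != n:
                raise ValueError("f3 length mismatch")
        if self.subject is not None:
            self.subject = np.asarray(self.subject, dtype=object)
            if len(self.subject) != n:
                raise ValueError("subject length mismatch")
        # single-level factors are tolerated in the container (e.g. a
        # pseudobulk built from one phenotype); classification requires >= 2
        # levels per factor and checks at fit time

    def require_two_levels(self) -> None:
        for name, arr in self.factors().items():
            if len(np.unique(arr.astype(str))) < 2:
                raise ValueError(f"factor {name} must have >= 2 levels")

    def factors(self) -> dict[str, np.ndarray]:
        out = {"f1": self.f1, "f2": self.f2}
        if self.f3 is not None:
            out["f3"] = self.f3
        return out

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    @property
    def is_three_way(self) -> bool:
        return self.f3 is not None

    def levels(self, factor: str) -> list[str]:
        arr = self.factors()[factor]
        return sorted({str(v) for v in arr})

    def subset(self, mask: np.ndarray) -> "ObservationDesign":
        mask = np.asarray(mask, dtype=bool)
        return ObservationDesign(
            obs_ids=[o for o, k in zip(self.obs_ids, mask) if k],
            f1=self.f1[mask],
            f2=self.f2[mask],
            f3=None if self.f3 is None else self.f3[mask],
            subject=None if self.subject is None else self.subject[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"f1": self.f1.astype(str), "f2": self.f2.astype(str)}
        if self.f3 is not None:
            data["f3"] = self.f3.astype(str)
        if self.subject is not None:
            data["subject"] = self.subject.astype(str)
        return pd.DataFrame(data, index=pd.Index(self.obs_ids, name="obs_id"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservationDesign":
        return cls(
            obs_ids=list(df.index.astype(str)),
            f1=df["f1"].to_numpy(),
            f2=df["f2"].to_numpy(),
            f3=df["f3"].to_numpy() if "f3" in df.columns else None,
            subject=df["subject"].to_numpy() if "subject" in df.columns else None,
        )


@dataclass
class PseudobulkMatrix:
    """Genes x observations matrix of log2-scale expression with its design.

    NaN entries are allowed and mean "this gene is undefined in this
    observation" (used by the spatial front end); they are dropped per gene
    at fit time. Infinite values are invalid.
    """

    values: np.ndarray
    gene_ids: list[str]
    design: ObservationDesign

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        if self.values.shape != (len(self.gene_ids), self.design.n_obs):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.design.n_obs} observations"
            )
        if np.isinf(self.values).any():
            raise ValueError("pseudobulk values must be finite (NaN allowed for missing)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.design.obs_ids,
        )


@dataclass
class GeneClassification:
    """Per-gene category assignment plus every stage p-value the gene saw.

    ``table`` is indexed by gene id with a ``category`` column and paired
    ``<stage>.p`` / ``<stage>.padj`` columns (NaN where a gene never entered
    that stage). ``reasons`` records why a gene was routed without testing
    (zero variance, untestable design, ambiguous main-effect pattern).
    """

    table: pd.DataFrame
    threshold_mode: str
    level: float
    use_adjusted: bool
    categories: tuple[str, ...] = TWO_WAY_CATEGORIES
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cats = set(self.table["category"])
        unknown = cats - set(self.categories)
        if unknown:
            raise ValueError(f"unknown categories {unknown}")

    def genes_in(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])

    def counts(self) -> pd.Series:
        return (
            self.table["category"]
            .value_counts()
            .reindex(self.categories, fill_value=0)
        )


@dataclass
class DEResult:
    """Moderated-t differential-expression results for named contrasts.

    One row per (gene, contrast): log2 fold change, ordinary residual
    variance ``s2`` on ``df`` degrees of freedom, moderated variance
    ``s2_post``, moderated t, raw and BH-adjusted p.
    """

    table: pd.DataFrame

    REQUIRED = ("gene_id", "contrast", "log2fc", "s2", "df", "s2_post", "t", "p", "padj")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"DEResult table missing columns {missing}")

    def significant(self, p_cut: float = 0.001, fc_cut: float = np.log2(1.5),
                    use_adjusted: bool = False) -> pd.DataFrame:
        p = self.table["padj"] if use_adjusted else self.table["p"]
        mask = (p < p_cut) & (self.table["log2fc"].abs() > fc_cut)
        return self.table.loc[mask]
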