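"""Readers and writers for the formats the tool touches.

Expression comes in as MatrixMarket (.mtx with features/barcodes sidecars)
or dense CSV/TSV with a header row of cell ids; metadata, pseudobulk,
design, classification and DE tables are plain CSV/TSV. Missing values are
written as "NA".
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import mmread

from .datatypes import (
    REQUIRED_CELL_META,
    GeneClassification,
    ObservationDesign,
    PseudobulkMatrix,
    SingleCellDataset,
)

logger = logging.getLogger(__name__)

NA = "NA"


def _read_table(path: str | Path, sep: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0, na_values=[NA],
                       float_precision="round_trip")


def read_single_cell(matrix_path: str | Path, meta_path: str | Path,
                     format: str = "csv", orientation: str = "genes_by_cells",
                     features_path: Optional[str | Path] = None,
                     barcodes_path: Optional[str | Path] = None) -> SingleCellDataset:
    """Load an expression matrix plus cell metadata into a SingleCellDataset.

    ``format`` is "mtx" (MatrixMarket triplets with features/barcodes
    sidecars) or "csv"/"tsv" (dense, gene ids as the index column, cell ids
    in the header). ``orientation`` declares whether rows are genes
    (default, the MatrixMarket single-cell convention) or cells
    ("cells_by_genes"). Cells present in the matrix but absent from the
    metadata are an error.
    """
    if format not in ("mtx", "csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if format == "mtx":
        if features_path is None or barcodes_path is None:
            raise ValueError("mtx format requires features_path and barcodes_path")
        values = np.asarray(mmread(str(matrix_path)).todense(), dtype=float)
        gene_ids = [l.split("\t")[0].strip() for l in
                    Path(features_path).read_text().splitlines() if l.strip()]
        cell_ids = [l.strip() for l in
                    Path(barcodes_path).read_text().splitlines() if l.strip()]
    else:
        df = _read_table(matrix_path, sep="\t" if format == "tsv" else ",")
        values = df.to_numpy(dtype=float)
        gene_ids = list(df.index.astype(str))
        cell_ids = list(df.columns.astype(str))
    if orientation == "cells_by_genes":
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids

    meta = _read_table(meta_path)
    meta.index = meta.index.astype(str)
    missing_cols = [c for c in REQUIRED_CELL_META if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required column(s): {missing_cols}")
    absent = [c for c in cell_ids if c not in meta.index]
    if absent:
        raise ValueError(
            f"{len(absent)} cell(s) in the matrix have no metadata, e.g. {absent[:5]}")
    meta = meta.loc[cell_ids]
    return SingleCellDataset(values=values, gene_ids=gene_ids, cell_ids=cell_ids,
                             cell_meta=meta)


def filter_da_cells(ds: SingleCellDataset, mode: str = "flag") -> SingleCellDataset:
    """Keep the cells selected by the upstream differential-abundance method.

    ``mode="flag"`` keeps cells whose ``da_selected`` entry is truthy or a
    non-null label; ``mode="all"`` is the identity. The DA label itself is
    never used as a factor downstream.
    """
    if mode == "all":
        return ds
    if mode != "flag":
        raise ValueError(f"unknown mode {mode!r}")
    if "da_selected" not in ds.cell_meta.columns:
        raise ValueError("metadata has no 'da_selected' column (required for mode='flag')")
    col = ds.cell_meta["da_selected"]
    if col.dtype == bool:
        mask = col.to_numpy()
    else:
        mask = col.notna().to_numpy() & ~col.astype(str).str.lower().isin(
            ["false", "0", "", "none", "na"]).to_numpy()
    if not mask.any():
        raise ValueError("no cells selected by the DA flag")
    return ds.subset_cells(mask)


def write_pseudobulk(pb: PseudobulkMatrix, values_path: str | Path,
                     design_path: str | Path, float_format: str = "%.17g") -> None:
    pb.to_frame().to_csv(values_path, sep="\t", na_rep=NA, float_format=float_format)
    pb.design.to_frame().to_csv(design_path, sep="\t", na_rep=NA)


def read_pseudobulk(values_path: str | Path, design_path: str | Path) -> PseudobulkMatrix:
    vals = _read_table(values_path, sep="\t")
    design = ObservationDesign.from_frame(_read_table(design_path, sep="\t").astype(str))
    if list(vals.columns) != list(design.obs_ids):
        raise ValueError("pseudobulk columns do not match design observations")
    return PseudobulkMatrix(values=vals.to_numpy(float),
                            gene_ids=list(vals.index.astype(str)), design=design)


def write_classification(gc: GeneClassification, path: str | Path) -> None:
    """Classification table as TSV, ordered by gene id (bit-stable).

    Stage p-value cells a gene never entered are empty (NA).
    """
    table = gc.table.sort_index()
    table = table.copy()
    table["reason"] = pd.Series(gc.reasons).reindex(table.index)
    table.to_csv(path, sep="\t", na_rep=NA, float_format="%.12g")


def read_classification(path: str | Path, threshold_mode: str = "alpha",
                        level: float = 0.05, use_adjusted: bool = True,
                        categories=None) -> GeneClassification:
    table = _read_table(path, sep="\t")
    table.index = table.index.astype(str)
    reasons = {}
    if "reason" in table.columns:
        reasons = table["reason"].dropna().to_dict()
        table = table.drop(columns=["reason"])
    if categories is None:
        from .datatypes import THREE_WAY_CATEGORIES, TWO_WAY_CATEGORIES
        cats = set(table["category"])
        categories = (THREE_WAY_CATEGORIES
                      if cats - set(TWO_WAY_CATEGORIES) else TWO_WAY_CATEGORIES)
    return GeneClassification(table=table, threshold_mode=threshold_mode,
                              level=level, use_adjusted=use_adjusted,
                              categories=categories, reasons=reasons)


def write_de(de, path: str | Path) -> None:
    de.table.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.12g")


def write_feature_matrix(features, path: str | Path) -> None:
    from .spatial import feature_frame
    feature_frame(features).to_csv(path, sep="\t", na_rep=NA, float_format="%.10g")
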