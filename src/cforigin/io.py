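"""Plain-text readers/writers for the pipeline's standard formats.

Atlases travel as MatrixMarket MTX (cells x genes) plus genes.tsv and
cells.tsv (columns cell_id, cell_type, compartment, tissue, assay); count
matrices and metadata as TSV. Everything is text so fixtures and outputs stay
inspectable and diff-able.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .normalization import GeneCountMatrix


def write_atlas(adata: ad.AnnData, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(directory / "matrix.mtx", X, field="integer")
    adata.var.rename_axis("gene").to_csv(directory / "genes.tsv", sep="\t")
    adata.obs.rename_axis("cell_id").to_csv(directory / "cells.tsv", sep="\t")


def read_atlas(directory: str | Path) -> ad.AnnData:
    directory = Path(directory)
    X = sp.csr_matrix(mmread(directory / "matrix.mtx"))
    var = pd.read_csv(directory / "genes.tsv", sep="\t", index_col=0).fillna({"marker_of": ""})
    if "marker_of" in var.columns:
        var["marker_of"] = var["marker_of"].fillna("").astype(str)
    obs = pd.read_csv(directory / "cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def write_counts(counts: GeneCountMatrix, counts_path, meta_path) -> None:
    counts.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    counts.meta.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_counts(counts_path, meta_path=None) -> GeneCountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
    else:
        meta = pd.DataFrame(
            {"plasma_ml": np.nan, "batch": "batch0", "bio_replicate": counts.columns},
            index=counts.columns,
        )
    return GeneCountMatrix(counts=counts, meta=meta)
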