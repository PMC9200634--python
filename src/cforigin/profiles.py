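"""Cell-type-specific gene profiles in whole-body context.

A gene belongs to a cell type's profile when it is (1) differentially
expressed for that type within its tissue's single-cell atlas (Wilcoxon
rank-sum vs all other types, BH-adjusted p < 0.01, fold change >= 1.5,
in-group fraction >= 0.2, out-group fraction <= 0.5, and the highest
per-other-type out-group expression fraction under half the in-group
fraction) and (2) tissue-specific in whole-body context: Gini coefficient of
its expression across a tissue consensus table >= 0.6, listed as specific to
the cell type's native tissue, with an enriched/enhanced specificity
category. Restricting to cell types unique to one tissue lets bulk tissue
data certify whole-body specificity that a single-tissue atlas cannot.

Specificity indices over a vector x of expression across n tissues:

* Gini = (n+1)/n - 2 * sum_i (n+1-i) x_(i) / (n * sum x), x sorted
  ascending; 0 for uniform, (n-1)/n for one-hot.
* Tau = sum_i (1 - x_i / max x) / (n - 1); 0 for uniform, 1 for one-hot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas_basis import _dense, rank_test

SPECIFIC_CATEGORIES = ("Tissue enriched", "Group enriched", "Tissue enhanced")

DE_DEFAULTS = {
    "alpha": 0.01,
    "min_fold_change": 1.5,
    "min_in_group_fraction": 0.2,
    "max_out_group_fraction": 0.5,
    "max_out_in_ratio": 0.5,
}


@dataclass
class TissueExpressionTable:
    """Consensus expression (genes x tissues, NX-like units) with categories.

    ``category`` assigns each gene a tissue-specificity class; genes in an
    enriched/enhanced class list their specific tissues in
    ``specific_tissues`` ("/"-joined tissue names, empty otherwise).
    """

    nx: pd.DataFrame
    category: pd.Series
    specific_tissues: pd.Series

    def __post_init__(self) -> None:
        if self.nx.shape[1] < 2:
            raise ValueError("tissue table needs at least 2 tissues")
        self.category = self.category.reindex(self.nx.index)
        self.specific_tissues = self.specific_tissues.reindex(self.nx.index).fillna("")

    @property
    def tissues(self) -> pd.Index:
        return self.nx.columns

    def to_tsv(self, path) -> None:
        out = self.nx.copy()
        out["category"] = self.category
        out["specific_tissues"] = self.specific_tissues
        out.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TissueExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        cat = df.pop("category")
        spec = df.pop("specific_tissues").fillna("")
        return cls(nx=df, category=cat, specific_tissues=spec)


@dataclass
class CellTypeProfile:
    """A cell type's specific gene set with per-gene statistics."""

    cell_type: str
    native_tissue: str
    genes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.genes.empty:
            raise ValueError(
                f"empty profile for {self.cell_type!r}; review DE/Gini thresholds"
            )

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes.index)

    def __len__(self) -> int:
        return len(self.genes)


def gini(x) -> float:
    """Gini inequality index of a non-negative vector (order-invariant)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("gini needs at least 2 values")
    if (x < 0).any():
        raise ValueError("gini is defined for non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini undefined for an all-zero vector")
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float((n + 1) / n - 2 * np.sum((n + 1 - i) * xs) / (n * total))


def tau(x) -> float:
    """Tau specificity index: mean shortfall from the maximum tissue."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("tau needs at least 2 values")
    m = x.max()
    if m <= 0:
        raise ValueError("tau undefined when max(x) <= 0")
    return float(np.sum(1 - x / m) / (n - 1))


def single_cell_de(
    adata: ad.AnnData,
    target_type: str,
    label: str = "cell_type",
    alpha: float = DE_DEFAULTS["alpha"],
    min_fold_change: float = DE_DEFAULTS["min_fold_change"],
    min_in_group_fraction: float = DE_DEFAULTS["min_in_group_fraction"],
    max_out_group_fraction: float = DE_DEFAULTS["max_out_group_fraction"],
    max_out_in_ratio: float = DE_DEFAULTS["max_out_in_ratio"],
) -> pd.DataFrame:
    """Marker-gene statistics for ``target_type`` vs all other cells.

    Counts are depth-normalized to 1e4 per cell and log(1+x) transformed;
    the Wilcoxon rank-sum test compares target cells against the rest. Fold
    change is the ratio of expm1 group means of the logged values (an
    expression-space ratio). Returns the full per-gene table with a
    ``selected`` column applying all filters.
    """
    mask = (adata.obs[label] == target_type).values
    if mask.sum() < 3:
        raise ValueError(f"cell type {target_type!r} has fewer than 3 cells")
    X = _dense(adata).astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    logX = np.log1p(X / lib * 1e4)

    p, z = rank_test(logX, mask)
    q = multipletests(p, method="fdr_bh")[1]
    mean_in = np.expm1(logX[mask].mean(axis=0))
    mean_out = np.expm1(logX[~mask].mean(axis=0))
    eps = 1e-9
    fold = (mean_in + eps) / (mean_out + eps)
    frac_in = (X[mask] > 0).mean(axis=0)
    frac_out = (X[~mask] > 0).mean(axis=0)

    other_types = [t for t in pd.unique(adata.obs[label]) if t != target_type]
    frac_by_other = np.vstack(
        [(X[(adata.obs[label] == t).values] > 0).mean(axis=0) for t in other_types]
    )
    max_other = frac_by_other.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out_in_ratio = np.where(frac_in > 0, max_other / frac_in, np.inf)

    table = pd.DataFrame(
        {
            "pval": p,
            "qval": q,
            "z": z,
            "fold_change": fold,
            "in_group_fraction": frac_in,
            "out_group_fraction": frac_out,
            "max_out_in_ratio": out_in_ratio,
        },
        index=adata.var_names,
    )
    table["selected"] = (
        (table["qval"] < alpha)
        & (table["fold_change"] >= min_fold_change)
        & (table["in_group_fraction"] >= min_in_group_fraction)
        & (table["out_group_fraction"] <= max_out_group_fraction)
        & (table["max_out_in_ratio"] < max_out_in_ratio)
        & (table["z"] > 0)
    )
    return table


def derive_profile(
    de_stats: pd.DataFrame,
    tissue_table: TissueExpressionTable,
    cell_type: str,
    native_tissue: str,
    gini_min: float = 0.6,
) -> CellTypeProfile:
    """Intersect DE-passing genes with whole-body tissue specificity.

    Keeps genes with tissue-table Gini >= ``gini_min``, listed as specific to
    the native tissue, and categorized enriched/enhanced. Genes absent from
    the tissue table are dropped.
    """
    de_genes = de_stats.index[de_stats["selected"]]
    present = de_genes.intersection(tissue_table.nx.index)
    rows = []
    for gene in present:
        x = tissue_table.nx.loc[gene].values
        if x.sum() == 0:
            continue
        g = gini(x)
        cat = tissue_table.category.loc[gene]
        listed = set(str(tissue_table.specific_tissues.loc[gene]).split("/"))
        if g >= gini_min and cat in SPECIFIC_CATEGORIES and native_tissue in listed:
            rec = de_stats.loc[gene].to_dict()
            rec.update({"gene": gene, "gini": g, "tau": tau(x), "hpa_category": cat})
            rows.append(rec)
    if not rows:
        raise ValueError(
            f"no gene survives the whole-body specificity filter for {cell_type!r}; "
            "review gini_min or the DE thresholds"
        )
    genes = pd.DataFrame(rows).set_index("gene")
    return CellTypeProfile(cell_type=cell_type, native_tissue=native_tissue, genes=genes)


def profile_foldchange_check(
    profile: CellTypeProfile,
    bulk_log: pd.DataFrame,
    tissue_of_sample: pd.Series,
) -> float:
    """Native-tissue signature score vs mean score in other tissues.

    ``bulk_log`` holds log(counts-per-ten-thousand + 1) values (genes x bulk
    samples); ``tissue_of_sample`` maps each column to its tissue. The score
    of a sample is the sum of profile-gene values. Returns the median score
    in the native tissue divided by the mean of per-tissue mean scores
    elsewhere.
    """
    genes = [g for g in profile.gene_set if g in bulk_log.index]
    if not genes:
        raise ValueError("no profile gene present in the bulk table")
    scores = bulk_log.loc[genes].sum(axis=0)
    by_tissue = scores.groupby(tissue_of_sample.reindex(scores.index))
    native = profile.native_tissue
    if native not in by_tissue.groups:
        raise ValueError(f"native tissue {native!r} absent from bulk table")
    native_median = by_tissue.median()[native]
    other_means = by_tissue.mean().drop(native)
    denom = other_means.mean()
    if denom == 0:
        return np.inf
    return float(native_median / denom)


def intersect_profiles(a: CellTypeProfile, b: CellTypeProfile) -> CellTypeProfile:
    """Gene-set intersection of the same cell type derived from two atlases."""
    if a.cell_type != b.cell_type:
        raise ValueError("profiles are for different cell types")
    shared = sorted(a.gene_set & b.gene_set)
    if not shared:
        raise ValueError(f"profiles for {a.cell_type!r} share no genes")
    genes = a.genes.loc[shared].join(
        b.genes.loc[shared], lsuffix="_a", rsuffix="_b", how="inner"
    )
    return CellTypeProfile(
        cell_type=a.cell_type, native_tissue=a.native_tissue, genes=genes
    )
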