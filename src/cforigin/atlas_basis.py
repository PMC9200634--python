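"""Basis-matrix construction from a labeled single-cell atlas.

The basis matrix ``A`` (genes x cell types, CPM scale) holds the mean
expression profile of each (possibly coarse-grained) cell type over a
discriminatory "barcode" gene set. Construction follows four steps:

1. ``apply_exclusions`` — drop ambiguous cell-type labels, tissues and genes.
2. ``coarse_grain`` — per organ compartment, merge transcriptionally similar
   cell types by cutting a complete-linkage dendrogram (built on per-type
   mean profiles in PC space) at a fraction of its maximum node height; the
   endothelial compartment collapses to a single column and the immune
   compartment keeps a curated label list, merging erythrocytes with
   erythroid progenitors.
3. ``subsample_cells`` — at most ``n_max`` (default 30) cells per grouped
   type, to equalize the weight of abundant and rare types.
4. ``build_signature_matrix`` — per type, a two-sided rank test of that
   type's cells against all others with a half-sampling stability check;
   genes with BH q below threshold and positive enrichment are ranked by
   fold change, and the per-type top-gene count is swept over a range,
   selecting the candidate matrix with the smallest 2-norm condition number
   kappa (subject to a cap). Small kappa means the cell-type columns are
   close to linearly independent, which is what downstream regression needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, spearmanr
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

DEFAULT_CUT_FRACTION = {"epithelial": 0.20, "stromal": 0.10}
ENDOTHELIAL_LABEL = "endothelial cell"
ERYTHROID_MERGE = ("erythrocyte", "erythroid progenitor")


@dataclass
class BasisMatrix:
    """Basis matrix with per-gene selection provenance.

    ``matrix``: genes x grouped-cell-type mean CPM expression.
    ``gene_stats``: per selected gene, the type it barcodes, BH q-value and
    fold change from the rank test. ``members`` maps each grouped column to
    its original atlas labels. ``kappa`` is the 2-norm condition number.
    """

    matrix: pd.DataFrame
    gene_stats: pd.DataFrame
    members: dict[str, list[str]] = field(default_factory=dict)
    kappa: float = np.nan

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def cell_types(self) -> pd.Index:
        return self.matrix.columns

    def to_tsv(self, path) -> None:
        self.matrix.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "BasisMatrix":
        m = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=m, gene_stats=pd.DataFrame(index=m.index), kappa=float(np.linalg.cond(m.values)))


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def apply_exclusions(
    adata: ad.AnnData,
    drop_labels: list[str] = (),
    drop_tissues: list[str] = (),
    drop_genes: list[str] = (),
) -> ad.AnnData:
    """Remove listed cell-type labels, tissues and genes from the atlas."""
    keep_cells = ~(
        adata.obs["cell_type"].isin(list(drop_labels))
        | adata.obs["tissue"].isin(list(drop_tissues))
    )
    keep_genes = ~adata.var_names.isin(list(drop_genes))
    out = adata[keep_cells, keep_genes].copy()
    if out.n_obs == 0 or out.n_vars == 0:
        raise ValueError("atlas empty after exclusions")
    return out


def _cpm_log(X: np.ndarray) -> np.ndarray:
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(X / lib * 1e6)


def coarse_grain(
    adata: ad.AnnData,
    cut_fraction: dict[str, float] | None = None,
    immune_keep: list[str] | None = None,
    n_pcs: int = 50,
    seed: int = 0,
) -> ad.AnnData:
    """Merge similar cell types per compartment; adds obs['grouped_type'].

    Epithelial/stromal (and any other unlisted) compartments are merged by
    cutting the complete-linkage dendrogram of per-type mean PC profiles at
    ``cut_fraction[compartment]`` (default 0.20 epithelial / 0.10 stromal;
    compartments without an entry pass through ungrouped). Endothelial
    collapses to one column. Immune keeps only ``immune_keep`` labels (all,
    when None) and merges the erythroid pair.
    """
    cut_fraction = dict(DEFAULT_CUT_FRACTION if cut_fraction is None else cut_fraction)
    grouped = pd.Series(index=adata.obs_names, dtype=object)
    keep_mask = np.ones(adata.n_obs, dtype=bool)
    logX = _cpm_log(_dense(adata))

    for compartment in pd.unique(adata.obs["compartment"]):
        in_comp = (adata.obs["compartment"] == compartment).values
        labels = adata.obs.loc[in_comp, "cell_type"]
        if compartment == "endothelial":
            grouped[labels.index] = ENDOTHELIAL_LABEL
            continue
        if compartment == "immune":
            if immune_keep is not None:
                drop = ~labels.isin(immune_keep)
                keep_mask[np.flatnonzero(in_comp)[drop.values]] = False
                labels = labels[~drop.values]
            merged = labels.where(
                ~labels.isin(ERYTHROID_MERGE), "/".join(sorted(ERYTHROID_MERGE))
            )
            grouped[merged.index] = merged
            continue
        types = sorted(labels.unique())
        if len(types) < 2 or compartment not in cut_fraction:
            grouped[labels.index] = labels
            continue
        X = logX[in_comp]
        k = int(min(n_pcs, X.shape[0] - 1, X.shape[1], len(types) * 10))
        pcs = PCA(n_components=max(k, 1), svd_solver="full", random_state=seed).fit_transform(X)
        means = np.vstack([pcs[(labels == t).values].mean(axis=0) for t in types])
        Z = linkage(means, method="complete")
        # merges at exactly the cut height are included (cut_tree is exclusive)
        height = cut_fraction[compartment] * Z[:, 2].max() * (1 + 1e-9)
        assignment = cut_tree(Z, height=height).ravel()
        for cluster in np.unique(assignment):
            members = [types[i] for i in np.flatnonzero(assignment == cluster)]
            name = "/".join(sorted(members))
            grouped[labels.index[labels.isin(members)]] = name

    out = adata[keep_mask].copy()
    out.obs["grouped_type"] = grouped.loc[out.obs_names].astype(str)
    return out


def subsample_cells(
    adata: ad.AnnData, n_max: int = 30, seed: int = 0, label: str = "grouped_type"
) -> ad.AnnData:
    """Keep at most ``n_max`` cells per grouped type (all cells when fewer)."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for _, members in adata.obs.groupby(label, observed=True).groups.items():
        members = np.asarray(members)
        if len(members) > n_max:
            members = rng.choice(members, size=n_max, replace=False)
        keep.extend(members)
    return adata[sorted(keep)].copy()


def _ranksum_z(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorized two-sample Wilcoxon rank-sum z per gene (tie-corrected)."""
    from scipy.stats import rankdata

    n1, n = int(mask.sum()), X.shape[0]
    n2 = n - n1
    ranks = rankdata(X, axis=0, method="average")
    r1 = ranks[mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # tie correction
    var = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie = (counts**3 - counts).sum()
        var[j] = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    var[var <= 0] = np.nan
    with np.errstate(invalid="ignore"):
        z = (r1 - mu) / np.sqrt(var)
    return np.where(np.isnan(z), 0.0, z)


def rank_test(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum p-values and z per gene for mask-vs-rest."""
    z = _ranksum_z(X, mask)
    p = 2 * norm.sf(np.abs(z))
    return p, z


def build_signature_matrix(
    adata: ad.AnnData,
    qval: float = 0.01,
    barcode_range: tuple[int, int] = (50, 150),
    kappa_limit: float = 999.0,
    replicates: int = 5,
    sampling: float = 0.5,
    seed: int = 0,
    label: str = "grouped_type",
) -> BasisMatrix:
    """Select barcode genes and assemble the minimum-kappa basis matrix.

    ``barcode_range = (gmin, gmax)`` sweeps the number of top genes taken per
    cell type; for each candidate count the matrix of per-type mean CPM over
    the union of selected genes is scored by its 2-norm condition number, and
    the smallest-kappa candidate with kappa <= ``kappa_limit`` wins (the
    global minimum, with a warning, if none is under the cap). Genes must
    pass BH q < ``qval``, positive enrichment, and a direction-consistency
    check over ``replicates`` random half-samples of cells at rate
    ``sampling``. Ties in fold change break by ascending q then gene id.
    """
    if label not in adata.obs:
        label = "cell_type"
    types = sorted(pd.unique(adata.obs[label]))
    if len(types) < 2:
        raise ValueError("need at least 2 grouped cell types")
    gmin, gmax = barcode_range
    if not (1 <= gmin <= gmax):
        raise ValueError("invalid barcode_range")

    X = _dense(adata).astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    cpm = X / lib * 1e6
    genes = adata.var_names.to_numpy()
    rng = np.random.default_rng(seed)

    mean_by_type = pd.DataFrame(
        {t: cpm[(adata.obs[label] == t).values].mean(axis=0) for t in types},
        index=genes,
    )

    ranked: dict[str, pd.DataFrame] = {}
    for t in types:
        mask = (adata.obs[label] == t).values
        p, _ = rank_test(cpm, mask)
        q = multipletests(p, method="fdr_bh")[1]
        mean_in = cpm[mask].mean(axis=0)
        mean_out = cpm[~mask].mean(axis=0)
        direction = mean_in > mean_out
        stable = np.ones(len(genes), dtype=bool)
        for _ in range(replicates):
            sub_in = rng.choice(
                np.flatnonzero(mask), size=max(2, int(sampling * mask.sum())), replace=False
            )
            sub_out = rng.choice(
                np.flatnonzero(~mask), size=max(2, int(sampling * (~mask).sum())), replace=False
            )
            stable &= cpm[sub_in].mean(axis=0) > cpm[sub_out].mean(axis=0)
        eps = 1e-9
        fc = (mean_in + eps) / (mean_out + eps)
        cand = pd.DataFrame(
            {"gene": genes, "qval": q, "fold_change": fc},
        )
        cand = cand[(q < qval) & direction & stable]
        if cand.empty:
            raise ValueError(f"no gene passes q < {qval} for cell type {t!r}")
        cand = cand.sort_values(
            ["fold_change", "qval", "gene"], ascending=[False, True, True]
        ).reset_index(drop=True)
        ranked[t] = cand

    best: tuple[float, pd.Index] | None = None
    swept: list[tuple[int, float]] = []
    for k in range(gmin, gmax + 1):
        union = pd.Index(
            sorted(set().union(*(ranked[t]["gene"].head(k) for t in types)))
        )
        candidate = mean_by_type.loc[union]
        with np.errstate(divide="ignore"):
            kappa = float(np.linalg.cond(candidate.values))
        swept.append((k, kappa))
        if best is None or kappa < best[0]:
            best = (kappa, union)
    kappa, union = best
    if kappa > kappa_limit:
        warnings.warn(
            f"no candidate satisfies kappa <= {kappa_limit}; returning minimum-kappa "
            f"matrix (kappa = {kappa:.3g})",
            stacklevel=2,
        )

    stats_rows = []
    for t in types:
        sub = ranked[t][ranked[t]["gene"].isin(union)]
        for _, row in sub.iterrows():
            stats_rows.append(
                {"gene": row["gene"], "cell_type": t, "qval": row["qval"], "fold_change": row["fold_change"]}
            )
    gene_stats = pd.DataFrame(stats_rows)
    members = {t: t.split("/") for t in types}
    return BasisMatrix(
        matrix=mean_by_type.loc[union],
        gene_stats=gene_stats,
        members=members,
        kappa=kappa,
    )


def basis_similarity(basis: BasisMatrix) -> pd.DataFrame:
    """Spearman correlation of basis columns, ordered by complete linkage on 1-rho."""
    if basis.matrix.shape[1] < 2:
        raise ValueError("need at least 2 cell-type columns")
    rho, _ = spearmanr(basis.matrix.values)
    rho = np.atleast_2d(rho)
    labels = list(basis.matrix.columns)
    d = squareform(1 - rho, checks=False)
    order_idx = _leaf_order(linkage(d, method="complete"), len(labels))
    ordered = [labels[i] for i in order_idx]
    return pd.DataFrame(rho, index=labels, columns=labels).loc[ordered, ordered]


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    from scipy.cluster.hierarchy import leaves_list

    return list(leaves_list(Z)) if n > 1 else [0]
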