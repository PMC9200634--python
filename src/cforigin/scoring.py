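"""Signature scores, cohort comparisons and permutation machinery.

A cell type's signature score in a sample is the sum of the log-transformed
CPM-TMM counts over the cell type's specific gene profile; profile genes the
sample did not detect contribute zero, keeping scores comparable across
samples. Cohorts are compared with a Mann-Whitney U test (exact enumeration
for small tie-free groups, tie-corrected normal approximation otherwise) and
the resulting p-values can be calibrated against a label-permutation null.

All permutation procedures share one convention: the statistic is recomputed
under ``n_perm`` random label shuffles and

    p = max(#{permuted statistic >= observed}, 1) / (n_perm + 1)

The +1 denominator counts the unpermuted comparison itself; the numerator
clamp keeps p in (0, 1]. When every score is equal, every permuted statistic
ties the observed zero and p = n_perm / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from .atlas_basis import BasisMatrix
from .normalization import NormalizedCounts
from .profiles import CellTypeProfile, TissueExpressionTable, gini

#: Largest per-group size at which the exact U distribution is enumerated.
EXACT_MAX_N = 8


@dataclass
class CohortComparison:
    group_a: str
    group_b: str
    scores_a: np.ndarray
    scores_b: np.ndarray
    U: float
    p: float
    sidedness: str
    alternative: str
    method: str
    permutation_p: float | None = None
    n_permutations: int = 0


def signature_score(
    matrix: NormalizedCounts, profile: CellTypeProfile | set[str]
) -> pd.Series:
    """Per-sample signature score: sum of logged values over profile genes.

    Requires the ``log_cpm_tmm`` stage. Missing profile genes contribute 0.
    """
    if matrix.stage != "log_cpm_tmm":
        raise ValueError(
            f"signature scores need stage 'log_cpm_tmm', got {matrix.stage!r}"
        )
    genes = profile.gene_set if isinstance(profile, CellTypeProfile) else set(profile)
    present = matrix.values.index.intersection(sorted(genes))
    if len(present) == 0:
        import warnings

        warnings.warn("no profile gene detected in the matrix; scores are 0", stacklevel=2)
        return pd.Series(0.0, index=matrix.values.columns, name="signature_score")
    return matrix.values.loc[present].sum(axis=0).rename("signature_score")


def dropout_filter(
    profile: CellTypeProfile, cohort_a: pd.DataFrame, cohort_b: pd.DataFrame
) -> CellTypeProfile:
    """Keep profile genes with >= 1 non-zero measurement in BOTH cohorts."""
    keep = [
        g
        for g in profile.genes.index
        if g in cohort_a.index
        and g in cohort_b.index
        and (cohort_a.loc[g] > 0).any()
        and (cohort_b.loc[g] > 0).any()
    ]
    if not keep:
        raise ValueError("dropout filter removed every profile gene")
    return CellTypeProfile(
        cell_type=profile.cell_type,
        native_tissue=profile.native_tissue,
        genes=profile.genes.loc[keep],
    )


def compare_cohorts(
    scores_a,
    scores_b,
    alternative: str = "two-sided",
    group_a: str = "A",
    group_b: str = "B",
) -> CohortComparison:
    """Mann-Whitney U test between two score vectors.

    ``alternative`` follows scipy ('two-sided', 'less', 'greater'; one-sided
    alternatives state the direction of group A relative to group B). Exact
    enumeration is used for tie-free groups of <= 8 each, otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 scores")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= EXACT_MAX_N and not ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method)
    return CohortComparison(
        group_a=group_a,
        group_b=group_b,
        scores_a=a,
        scores_b=b,
        U=float(res.statistic),
        p=float(res.pvalue),
        sidedness="two" if alternative == "two-sided" else "one",
        alternative=alternative,
        method=method,
    )


def _permutation_p(count_ge: int, n_perm: int) -> float:
    return max(count_ge, 1) / (n_perm + 1)


def calibrate_pvalues(
    scores,
    labels,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the difference in group mean scores.

    ``labels`` is a boolean mask (or two-valued vector) splitting samples
    into the two groups; the statistic is mean(group True) - mean(group
    False). Labels are shuffled ``n_perm`` times; returns (permutation p,
    null statistic distribution). Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    values = np.unique(labels)
    if len(values) != 2:
        raise ValueError("labels must contain exactly 2 groups")
    mask = labels == values[-1]
    n1 = int(mask.sum())
    observed = scores[mask].mean() - scores[~mask].mean()

    rng = np.random.default_rng(seed)
    n = len(scores)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    perm_sums = scores[idx].sum(axis=1)
    total = scores.sum()
    null = perm_sums / n1 - (total - perm_sums) / (n - n1)
    count = int(np.sum(null >= observed))
    return _permutation_p(count, n_perm), null


def hypergeom_overlap(deg_set, profile_genes, universe_size: int) -> float:
    """Upper-tail hypergeometric p of >= observed overlap between gene sets."""
    deg = set(deg_set)
    prof = set(profile_genes)
    if len(deg) > universe_size or len(prof) > universe_size:
        raise ValueError("gene sets larger than the universe")
    k = len(deg & prof)
    return float(hypergeom.sf(k - 1, universe_size, len(prof), len(deg)))


def tissue_specific_only_set(B, C, U, D) -> set[str]:
    """Tissue-specific genes that moved in disease but are not cell-type-specific.

    T = (B & U) | (B & D) - C, where B is the initial tissue-specific set, C
    the union of cell-type-specific genes (a subset of B), and U/D the up-
    and down-regulated DEG sets.
    """
    B, C, U, D = set(B), set(C), set(U), set(D)
    if not C <= B:
        raise ValueError("cell-type-specific genes must be a subset of the tissue set")
    return ((B & U) | (B & D)) - C


def gini_permutation_test(
    ct_genes,
    tissue_genes,
    mean_expr_by_celltype: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Are cell-type-profile genes more cell-type-specific than tissue genes?

    Per gene, a Gini coefficient is computed across cell types from
    ``mean_expr_by_celltype`` (genes x cell types, mean log counts-per-ten-
    thousand). The observed statistic is mean Gini(cell-type genes) - mean
    Gini(tissue genes); group labels are permuted ``n_perm`` times and p
    follows the shared >= / (n_perm + 1) convention.
    """
    ct = [g for g in ct_genes if g in mean_expr_by_celltype.index]
    ts = [g for g in tissue_genes if g in mean_expr_by_celltype.index]
    if not ct or not ts:
        raise ValueError("both gene groups must be non-empty and present in the table")
    ginis = np.array(
        [gini(mean_expr_by_celltype.loc[g].values) for g in ct + ts]
    )
    n_ct = len(ct)
    observed = ginis[:n_ct].mean() - ginis[n_ct:].mean()
    rng = np.random.default_rng(seed)
    n = len(ginis)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_ct]
    perm_ct = ginis[idx].mean(axis=1)
    total = ginis.sum()
    perm_ts = (total - perm_ct * n_ct) / (n - n_ct)
    count = int(np.sum(perm_ct - perm_ts >= observed))
    return {
        "p": _permutation_p(count, n_perm),
        "observed_diff": float(observed),
        "n_cell_type": n_ct,
        "n_tissue": len(ts),
        "n_permutations": n_perm,
    }


def uncaptured_tissue_genes(
    cpm: NormalizedCounts,
    basis: BasisMatrix,
    tissue_table: TissueExpressionTable,
    min_cpm: float = 1.0,
    min_nx: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue-specific genes detected in cfRNA but absent from the basis rows.

    Per sample j: (G_j - R) & HPA tallied per tissue, where G_j is the set of
    genes at CPM >= ``min_cpm``, R the basis row space, and HPA the genes in
    an enriched/enhanced category with peak NX >= ``min_nx``. Returns the
    tissues x samples count table and a mean/sd summary per tissue.
    """
    if cpm.stage != "cpm_ml":
        raise ValueError(f"uncaptured-gene tally expects stage 'cpm_ml', got {cpm.stage!r}")
    from .profiles import SPECIFIC_CATEGORIES

    hpa_mask = tissue_table.category.isin(SPECIFIC_CATEGORIES) & (
        tissue_table.nx.max(axis=1) >= min_nx
    )
    hpa_genes = tissue_table.nx.index[hpa_mask]
    tissue_of_gene = tissue_table.specific_tissues.loc[hpa_genes].str.split("/")
    R = set(basis.genes)

    tissues = list(tissue_table.tissues)
    counts = pd.DataFrame(0, index=tissues, columns=cpm.values.columns)
    for sample in cpm.values.columns:
        detected = set(cpm.values.index[cpm.values[sample] >= min_cpm])
        eligible = (detected - R) & set(hpa_genes)
        for gene in eligible:
            for t in tissue_of_gene.loc[gene]:
                if t in counts.index:
                    counts.loc[t, sample] += 1
    summary = pd.DataFrame({"mean": counts.mean(axis=1), "sd": counts.std(axis=1)})
    return counts, summary


def detect_markers(
    matrix: NormalizedCounts,
    marker_db: pd.DataFrame,
    min_sensitivity: float = 0.9,
    max_specificity: float = 0.2,
    species: str = "Hs",
    show_threshold: float = 5.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Count detected cell-type markers per sample from a marker database.

    ``marker_db`` columns: cell_type, gene, sensitivity, specificity,
    species. Markers are filtered to the given species, sensitivity >=
    ``min_sensitivity`` and specificity <= ``max_specificity`` (specificity
    here is the rate at which the marker appears in OTHER cell types, so low
    is specific). A marker counts in a sample when its logged expression is
    > 0. Cell types whose mean detected-marker count across samples exceeds
    ``show_threshold`` are reported.
    """
    if matrix.stage != "log_cpm_tmm":
        raise ValueError("marker detection uses the log_cpm_tmm stage")
    db = marker_db[
        (marker_db["species"] == species)
        & (marker_db["sensitivity"] >= min_sensitivity)
        & (marker_db["specificity"] <= max_specificity)
    ]
    cell_types = sorted(db["cell_type"].unique())
    counts = pd.DataFrame(0, index=cell_types, columns=matrix.values.columns)
    for ct, group in db.groupby("cell_type"):
        genes = matrix.values.index.intersection(group["gene"])
        if len(genes) == 0:
            continue
        counts.loc[ct] = (matrix.values.loc[genes] > 0).sum(axis=0)
    shown = [ct for ct in cell_types if counts.loc[ct].mean() > show_threshold]
    return counts, shown
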