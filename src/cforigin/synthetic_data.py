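"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the data shapes the pipeline consumes
in production: a labeled single-cell atlas (negative-binomial counts with
planted disjoint marker blocks per cell type), cfRNA mixtures formed as
known non-negative combinations of basis-matrix columns plus optional noise,
htseq-style per-exon count tables with controllable 3' bias / ribosomal /
intronic fractions, an HPA-style tissue consensus table whose planted
markers are high only in their native tissue, a PanglaoDB-style marker
database, and two-cohort count matrices with a planted log fold change in a
gene profile. Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atlas_basis import BasisMatrix
from .normalization import GeneCountMatrix
from .profiles import CellTypeProfile, TissueExpressionTable
from .qc import ReadCategorySummary

NOISE_MODELS = ("none", "poisson", "lognormal-multiplicative")


@dataclass
class AtlasSpec:
    """Design of a synthetic labeled single-cell atlas.

    Marker genes of cell type k have mean expression ``marker_fold_change *
    base_mean`` in type k and ``base_mean`` elsewhere; marker sets of
    distinct types are disjoint. Counts are negative-binomial with
    ``var = mu + nb_dispersion * mu**2`` (scRNA-seq-typical overdispersion).
    """

    n_cell_types: int = 10
    n_genes: int = 500
    cells_per_type: int = 50
    markers_per_type: int = 20
    marker_fold_change: float = 8.0
    nb_dispersion: float = 0.3
    base_mean: float = 0.4
    compartment_of_type: dict[str, str] = field(default_factory=dict)
    tissue_of_type: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.n_genes, self.cells_per_type, self.markers_per_type) < 1:
            raise ValueError("all size parameters must be positive")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                "infeasible spec: markers_per_type * n_cell_types exceeds n_genes "
                "(marker sets must be disjoint)"
            )
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")
        names = self.cell_type_names
        for k, name in enumerate(names):
            self.compartment_of_type.setdefault(name, "epithelial")
            self.tissue_of_type.setdefault(name, f"tissue_{k:02d}")

    @property
    def cell_type_names(self) -> list[str]:
        return [f"type_{k:02d}" for k in range(self.n_cell_types)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_atlas(spec: AtlasSpec) -> ad.AnnData:
    """Sparse cells x genes atlas with cell type / compartment / tissue labels.

    ``var['marker_of']`` records which type each planted marker barcodes
    (empty string for background genes). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    types = spec.cell_type_names
    genes = [f"gene_{i:04d}" for i in range(spec.n_genes)]
    marker_of = np.full(spec.n_genes, "", dtype=object)
    mu_by_type = np.full((spec.n_cell_types, spec.n_genes), spec.base_mean)
    for k in range(spec.n_cell_types):
        block = slice(k * spec.markers_per_type, (k + 1) * spec.markers_per_type)
        marker_of[block] = types[k]
        mu_by_type[k, block] *= spec.marker_fold_change

    n_cells = spec.n_cell_types * spec.cells_per_type
    X = np.empty((n_cells, spec.n_genes), dtype=np.int64)
    obs_type = []
    for k, t in enumerate(types):
        rows = slice(k * spec.cells_per_type, (k + 1) * spec.cells_per_type)
        mu = np.broadcast_to(mu_by_type[k], (spec.cells_per_type, spec.n_genes))
        X[rows] = _nb_draw(rng, mu, spec.nb_dispersion)
        obs_type.extend([t] * spec.cells_per_type)

    obs = pd.DataFrame(
        {
            "cell_type": obs_type,
            "compartment": [spec.compartment_of_type[t] for t in obs_type],
            "tissue": [spec.tissue_of_type[t] for t in obs_type],
            "assay": "10x",
        },
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame({"marker_of": marker_of}, index=pd.Index(genes, name="gene"))
    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    adata.uns["spec_seed"] = spec.seed
    return adata


@dataclass
class MixtureTruth:
    """Ground truth for one simulated cfRNA mixture."""

    theta_true: np.ndarray
    depth: float = 5e6
    noise_model: str = "none"
    noise_scale: float = 0.0

    def __post_init__(self) -> None:
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        if (self.theta_true < 0).any():
            raise ValueError("theta_true must be non-negative")
        if abs(self.theta_true.sum() - 1.0) > 1e-9:
            raise ValueError("theta_true must sum to 1 within 1e-9")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class MixtureSample:
    """One simulated cfRNA sample's gene counts plus its ground truth."""

    counts: pd.Series
    sample_id: str
    plasma_ml: float
    truth: MixtureTruth


def generate_mixture(
    basis: BasisMatrix,
    truth: MixtureTruth,
    plasma_ml: float = 1.0,
    seed: int = 0,
    sample_id: str | None = None,
) -> MixtureSample:
    """Counts with expectation proportional to ``basis @ theta_true``.

    Noise models: 'none' (exact expected counts, real-valued), 'poisson'
    (counts ~ Poisson(expected)), 'lognormal-multiplicative' (expected *
    lognormal(sd=noise_scale), mean-one).
    """
    if basis.matrix.shape[1] != len(truth.theta_true):
        raise ValueError("theta_true length must match basis columns")
    rng = np.random.default_rng(seed)
    expected = basis.matrix.values @ truth.theta_true
    expected = expected / expected.sum() * truth.depth
    if truth.noise_model == "none":
        counts = expected
    elif truth.noise_model == "poisson":
        counts = rng.poisson(expected).astype(float)
    else:
        s = truth.noise_scale
        factors = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=len(expected))
        counts = expected * factors
    return MixtureSample(
        counts=pd.Series(counts, index=basis.genes, name=sample_id or f"mix_{seed}"),
        sample_id=sample_id or f"mix_{seed}",
        plasma_ml=plasma_ml,
        truth=truth,
    )


def mixtures_to_counts(samples: list[MixtureSample]) -> GeneCountMatrix:
    """Assemble mixtures into a GeneCountMatrix for the normalization pipeline."""
    counts = pd.DataFrame({s.sample_id: s.counts for s in samples})
    meta = pd.DataFrame(
        {
            "plasma_ml": [s.plasma_ml for s in samples],
            "batch": "synthetic",
            "bio_replicate": [s.sample_id for s in samples],
        },
        index=[s.sample_id for s in samples],
    )
    return GeneCountMatrix(counts=counts, meta=meta)


def generate_exon_table(
    n_genes: int,
    frac_three_prime_only: float,
    ribo_frac: float,
    intron_exon_ratio: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, ReadCategorySummary]:
    """Exon count table + read-category summary with planted QC metrics.

    Exactly ``round(frac_three_prime_only * n_genes)`` genes carry all reads
    on their highest-numbered exon; intronic/exonic matches
    ``intron_exon_ratio`` up to integer rounding and ribosomal/total matches
    ``ribo_frac`` likewise.
    """
    if not 0 <= frac_three_prime_only <= 1:
        raise ValueError("frac_three_prime_only must be in [0, 1]")
    if not 0 <= ribo_frac < 1:
        raise ValueError("ribo_frac must be in [0, 1)")
    if intron_exon_ratio < 0:
        raise ValueError("intron_exon_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    n_biased = int(round(frac_three_prime_only * n_genes))
    rows = []
    for i in range(n_genes):
        gene = f"gene_{i:04d}"
        n_exons = int(rng.integers(2, 6))
        if i < n_biased:
            rows.append((gene, n_exons, int(rng.integers(5, 100))))
        else:
            # reads on the first exon guarantee the gene is not 3'-only
            rows.append((gene, 1, int(rng.integers(5, 100))))
            for e in range(2, n_exons + 1):
                if rng.random() < 0.7:
                    rows.append((gene, e, int(rng.integers(0, 50))))
    table = pd.DataFrame(rows, columns=["gene_id", "exon_number", "count"])
    exonic = int(table["count"].sum())
    intronic = int(round(intron_exon_ratio * exonic))
    mapped = exonic + intronic
    ribosomal = int(round(ribo_frac / (1 - ribo_frac) * mapped)) if ribo_frac > 0 else 0
    summary = ReadCategorySummary(
        ribosomal_reads=ribosomal,
        total_reads=mapped + ribosomal,
        intronic_reads=intronic,
        exonic_reads=exonic,
    )
    return table, summary


def generate_tissue_table(
    atlas: ad.AnnData, n_extra_tissues: int = 3, seed: int = 0
) -> TissueExpressionTable:
    """HPA-style gene x tissue NX table consistent with the atlas' markers.

    Planted markers get a high NX in their cell type's native tissue and zero
    elsewhere (category 'Tissue enriched'); background genes get a uniform
    housekeeping level across all tissues ('Low tissue specificity').
    Categories are assigned by rule — top tissue >= 4x the second ->
    enriched, flat row -> low specificity, otherwise enhanced — so the
    category filter downstream is genuinely exercised.
    """
    rng = np.random.default_rng(seed)
    tissues = sorted(atlas.obs["tissue"].unique()) + [
        f"extra_{i:02d}" for i in range(n_extra_tissues)
    ]
    genes = atlas.var_names
    native_tissue = {}
    for t in pd.unique(atlas.obs["cell_type"]):
        native_tissue[t] = atlas.obs.loc[atlas.obs["cell_type"] == t, "tissue"].iloc[0]

    nx = np.zeros((len(genes), len(tissues)))
    marker_of = atlas.var["marker_of"].values
    for i, gene in enumerate(genes):
        if marker_of[i]:
            col = tissues.index(native_tissue[marker_of[i]])
            nx[i, col] = rng.uniform(30, 60)
        else:
            nx[i, :] = rng.uniform(5, 20)
    nx_df = pd.DataFrame(nx, index=genes, columns=tissues)

    category, specific = {}, {}
    for gene, row in nx_df.iterrows():
        vals = np.sort(row.values)[::-1]
        if vals[0] <= 0 or vals[0] - vals[-1] < 1e-9 * max(vals[0], 1):
            category[gene] = "Low tissue specificity"
            specific[gene] = ""
        elif vals[1] == 0 or vals[0] >= 4 * vals[1]:
            category[gene] = "Tissue enriched"
            specific[gene] = row.idxmax()
        else:
            category[gene] = "Tissue enhanced"
            specific[gene] = "/".join(row.index[row >= 2 * row.mean()])
    return TissueExpressionTable(
        nx=nx_df, category=pd.Series(category), specific_tissues=pd.Series(specific)
    )


def generate_cohorts(
    profile: CellTypeProfile | list[str],
    n_per_group: int = 20,
    log_effect: float = 0.0,
    seed: int = 0,
    n_background_genes: int = 400,
    base_depth_mean: float = 50.0,
    nb_dispersion: float = 0.3,
) -> tuple[GeneCountMatrix, GeneCountMatrix]:
    """Two-cohort count matrices with a planted effect in the profile genes.

    Group B's profile genes have their mean shifted by a factor
    ``exp(log_effect)`` relative to group A; background genes share the same
    mean in both groups (exchangeable under the null). Counts are negative
    binomial around per-gene lognormal means.
    """
    genes = sorted(profile.gene_set) if isinstance(profile, CellTypeProfile) else sorted(profile)
    if not genes:
        raise ValueError("profile is empty")
    rng = np.random.default_rng(seed)
    bg = [f"bg_{i:04d}" for i in range(n_background_genes)]
    all_genes = genes + bg
    mu = rng.lognormal(mean=np.log(base_depth_mean), sigma=1.0, size=len(all_genes))

    def _cohort(prefix: str, shift: float) -> GeneCountMatrix:
        mu_g = mu.copy()
        mu_g[: len(genes)] *= np.exp(shift)
        counts = _nb_draw(
            rng, np.broadcast_to(mu_g, (n_per_group, len(all_genes))), nb_dispersion
        ).T
        ids = [f"{prefix}_{i:02d}" for i in range(n_per_group)]
        meta = pd.DataFrame(
            {"plasma_ml": 1.0, "batch": prefix, "bio_replicate": ids}, index=ids
        )
        return GeneCountMatrix(
            counts=pd.DataFrame(counts, index=all_genes, columns=ids), meta=meta
        )

    return _cohort("A", 0.0), _cohort("B", log_effect)


def generate_marker_db(
    atlas: ad.AnnData, seed: int = 0, n_decoys: int = 20
) -> pd.DataFrame:
    """PanglaoDB-style marker table matching the atlas' planted markers.

    Planted markers get sensitivity ~0.95 and specificity ~0.05 (detectable
    after the standard >= 0.9 / <= 0.2 filter); decoy rows fail one of the
    two filters or carry a non-human species tag.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, ct in atlas.var["marker_of"].items():
        if ct:
            rows.append(
                {
                    "cell_type": ct,
                    "gene": gene,
                    "sensitivity": rng.uniform(0.9, 1.0),
                    "specificity": rng.uniform(0.0, 0.2),
                    "species": "Hs",
                }
            )
    background = [g for g, ct in atlas.var["marker_of"].items() if not ct]
    for gene in rng.choice(background, size=min(n_decoys, len(background)), replace=False):
        fail = rng.integers(3)
        rows.append(
            {
                "cell_type": "decoy cell",
                "gene": gene,
                "sensitivity": rng.uniform(0.2, 0.8) if fail == 0 else rng.uniform(0.9, 1.0),
                "specificity": rng.uniform(0.4, 0.9) if fail == 1 else rng.uniform(0.0, 0.2),
                "species": "Mm" if fail == 2 else "Hs",
            }
        )
    return pd.DataFrame(rows)
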