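"""Normalization of cfRNA gene counts.

Counts are first scaled to counts per million per milliliter of plasma
(``eta_ij = 1e6 * Gene_ij / (LibrarySize_j * plasma_ml_j)``), then optionally
divided by a trimmed-mean-of-M-values (TMM) scaling factor per sample, and
finally ``log(1 + x)`` transformed for scoring analyses. Deconvolution
consumes the linear CPM-per-mL stage directly (replicate-averaged, never
TMM-divided or logged); signature scoring consumes the log CPM-TMM stage.

The TMM factor follows the published trimmed weighted-mean procedure: per
gene, M = log2 expression ratio against a reference sample and A = average
log2 abundance; genes with a zero in either sample are dropped; the M values
are trimmed 30% two-sided and the A values 5% two-sided; the factor is
2**(precision-weighted mean of the retained M), and factors are mean-centered
in log space so they multiply to 1. The reference sample is the one whose
upper-quartile expression fraction is closest to the mean upper quartile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("cpm_ml", "cpm_ml_tmm", "log_cpm_tmm")

#: Two-sided trim fraction on M (log ratio) values.
TRIM_M = 0.30
#: Two-sided trim fraction on A (log abundance) values.
TRIM_A = 0.05
#: Nominal library size used for precision weights at the CPM stage.
NOMINAL_LIBRARY = 1e6

REQUIRED_META = ("plasma_ml", "batch", "bio_replicate")


@dataclass
class GeneCountMatrix:
    """Raw gene counts (genes x samples) with per-sample metadata.

    ``meta`` is indexed by sample id with columns plasma_ml (real > 0), batch
    (label) and bio_replicate (grouping of technical replicates).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        self.meta = self.meta.loc[list(self.counts.columns)].copy()
        if "plasma_ml" not in self.meta.columns or self.meta["plasma_ml"].isna().any():
            warnings.warn(
                "missing plasma volume; assuming 1 mL per sample", stacklevel=2
            )
            vols = self.meta.get("plasma_ml", pd.Series(np.nan, index=self.meta.index))
            self.meta["plasma_ml"] = vols.fillna(1.0)
        if (self.meta["plasma_ml"] <= 0).any():
            raise ValueError("plasma_ml must be positive")
        for col, default in (("batch", "batch0"), ("bio_replicate", None)):
            if col not in self.meta.columns:
                self.meta[col] = self.meta.index if default is None else default


@dataclass
class NormalizedCounts:
    """Normalized expression values (genes x samples) with a stage tag."""

    values: pd.DataFrame
    stage: str
    meta: pd.DataFrame
    tmm: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


def cpm_per_ml(counts: GeneCountMatrix) -> NormalizedCounts:
    """Scale counts to CPM per mL of plasma.

    Column j becomes ``1e6 * counts[:, j] / (library_size_j * plasma_ml_j)``,
    so column sums equal ``1e6 / plasma_ml_j``.
    """
    lib = counts.counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    vol = counts.meta["plasma_ml"]
    values = counts.counts * (1e6 / (lib * vol))
    return NormalizedCounts(values=values, stage="cpm_ml", meta=counts.meta.copy())


def _q75(fractions: np.ndarray) -> float:
    return float(np.quantile(fractions, 0.75))


def _choose_reference(frac: pd.DataFrame) -> str:
    q = frac.apply(lambda col: _q75(col.values), axis=0)
    return (q - q.mean()).abs().idxmin()


def _tmm_one(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float
) -> float:
    """Trimmed weighted mean of M values of one sample against the reference.

    ``obs`` and ``ref`` are expression fractions (sum to 1 over genes).
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return np.nan
    o, r = obs[keep], ref[keep]
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # Delta-method precision weights at nominal depth.
    yo, yr = o * NOMINAL_LIBRARY, r * NOMINAL_LIBRARY
    w = (NOMINAL_LIBRARY - yo) / (NOMINAL_LIBRARY * yo) + (
        NOMINAL_LIBRARY - yr
    ) / (NOMINAL_LIBRARY * yr)
    n = len(m)
    lo_m = int(np.floor(trim_m * n))
    lo_a = int(np.floor(trim_a * n))
    order_m = np.argsort(m, kind="stable")
    order_a = np.argsort(a, kind="stable")
    keep_m = np.zeros(n, dtype=bool)
    keep_m[order_m[lo_m : n - lo_m]] = True
    keep_a = np.zeros(n, dtype=bool)
    keep_a[order_a[lo_a : n - lo_a]] = True
    sel = keep_m & keep_a
    if not sel.any() or w[sel].sum() <= 0:
        return np.nan
    return float(2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])))


def tmm_factors(
    cpm: NormalizedCounts,
    reference: str | None = None,
    trim_m: float = TRIM_M,
    trim_a: float = TRIM_A,
) -> pd.Series:
    """Per-sample TMM scaling factors, mean-centered in log space.

    Factors multiply to 1 across samples; dividing each column by its factor
    removes residual composition bias between libraries. A sample sharing no
    expressed genes with the reference gets factor 1 with a warning.
    """
    if cpm.stage != "cpm_ml":
        raise ValueError(f"tmm_factors expects stage 'cpm_ml', got {cpm.stage!r}")
    if cpm.values.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    frac = cpm.values / cpm.values.sum(axis=0)
    ref_id = reference if reference is not None else _choose_reference(frac)
    ref = frac[ref_id].values
    factors = {}
    for sample in frac.columns:
        f = _tmm_one(frac[sample].values, ref, trim_m, trim_a)
        if np.isnan(f):
            warnings.warn(
                f"sample {sample!r} shares no usable genes with reference; factor set to 1",
                stacklevel=2,
            )
            f = 1.0
        factors[sample] = f
    out = pd.Series(factors, name="tmm_factor")
    out /= np.exp(np.log(out).mean())  # geometric-mean centering
    return out


def apply_tmm(cpm: NormalizedCounts, factors: pd.Series) -> NormalizedCounts:
    """Divide each sample column by its TMM factor (stage -> cpm_ml_tmm)."""
    if cpm.stage != "cpm_ml":
        raise ValueError(f"apply_tmm expects stage 'cpm_ml', got {cpm.stage!r}")
    if (factors <= 0).any():
        raise ValueError("TMM factors must be positive")
    values = cpm.values / factors.reindex(cpm.values.columns)
    return NormalizedCounts(
        values=values, stage="cpm_ml_tmm", meta=cpm.meta.copy(), tmm=factors.copy()
    )


def average_replicates(matrix: NormalizedCounts) -> NormalizedCounts:
    """Average technical replicates of each biological replicate.

    Arithmetic mean on the current stage's (linear) scale; for scoring,
    averaging is done at cpm_ml_tmm before the log transform.
    """
    if matrix.stage == "log_cpm_tmm":
        raise ValueError("average replicates on the linear scale, before log transform")
    groups = matrix.meta["bio_replicate"]
    if groups.isna().any():
        raise ValueError("bio_replicate missing for some samples")
    cols, meta_rows = {}, []
    for group, members in groups.groupby(groups).groups.items():
        members = list(members)
        cols[group] = matrix.values[members].mean(axis=1)
        row = matrix.meta.loc[members[0]].copy()
        row.name = group
        meta_rows.append(row)
    values = pd.DataFrame(cols)
    meta = pd.DataFrame(meta_rows)
    meta["bio_replicate"] = meta.index
    tmm = None
    if matrix.tmm is not None:
        tmm = pd.Series(
            {g: matrix.tmm[list(m)].mean() for g, m in groups.groupby(groups).groups.items()},
            name="tmm_factor",
        )
    return NormalizedCounts(values=values, stage=matrix.stage, meta=meta, tmm=tmm)


def log_transform(matrix: NormalizedCounts) -> NormalizedCounts:
    """log(1 + x); only defined at the cpm_ml_tmm stage."""
    if matrix.stage != "cpm_ml_tmm":
        raise ValueError(
            f"log transform applies at stage 'cpm_ml_tmm', got {matrix.stage!r}"
        )
    return replace(matrix, values=np.log1p(matrix.values), stage="log_cpm_tmm")


def scoring_pipeline(counts: GeneCountMatrix) -> NormalizedCounts:
    """CPM-per-mL -> TMM -> replicate averaging -> log(1+x), the scoring input."""
    cpm = cpm_per_ml(counts)
    tmm = apply_tmm(cpm, tmm_factors(cpm))
    return log_transform(average_replicates(tmm))


def deconvolution_pipeline(counts: GeneCountMatrix) -> NormalizedCounts:
    """CPM-per-mL -> replicate averaging: the linear-scale deconvolution input."""
    return average_replicates(cpm_per_ml(counts))
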