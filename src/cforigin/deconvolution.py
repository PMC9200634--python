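"""Nu-SVR deconvolution of cfRNA mixtures into cell-type fractions.

The measured plasma transcriptome is modelled as ``A @ theta = b`` where
``A`` is the basis matrix (genes x cell types, CPM), ``theta`` the vector of
fractional cell-type contributions and ``b`` the sample's CPM-per-mL values.
``theta`` is learned by linear-kernel nu-support-vector regression over a
grid of (nu, C); the support vectors are the genes used to fit the weights.
Per candidate fit, negative weights are zeroed and the remainder normalized
to sum to one; the candidate whose reconstruction ``A @ theta`` (rescaled to
the measured library total, since fractions carry no abundance scale) has
the smallest RMSE against the measured values is selected. RMSE is reported
in units of the sample's expression standard deviation.

Only genes at CPM >= 1 in the mixture enter ``b``; neither ``b`` nor ``A``
is log-transformed — the log's concavity would break the linearity of the
mixture model and bias ``theta`` downward. Both are centered/scaled before
fitting (``b`` by its own mean/sd, ``A`` globally as one matrix, preserving
between-column magnitude differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.svm import NuSVR

from .atlas_basis import BasisMatrix
from .normalization import NormalizedCounts

NU_GRID = (0.05, 0.1, 0.15, 0.25, 0.5, 0.75)
C_GRID = (0.1, 0.5, 0.75, 1, 10)

#: Solver settings: libsvm does not terminate on parts of the grid at very
#: tight tolerances, so fits run at 1e-4 with a hard iteration cap; a capped
#: fit is flagged as non-converged on its candidate rather than hidden.
SOLVER_TOL = 1e-4
SOLVER_MAX_ITER = 50_000

MIN_MIXTURE_CPM = 1.0


@dataclass
class Candidate:
    """One (nu, C) grid point's raw fit."""

    nu: float
    C: float
    raw_weights: np.ndarray
    support_vector_count: int
    converged: bool


@dataclass
class DeconvolutionResult:
    theta: pd.Series
    nu: float
    C: float
    rmse: float
    pearson_r: float
    n_genes_used: int
    support_vector_count: int
    degenerate: bool = False


def prepare_mixture(
    sample: NormalizedCounts | pd.Series,
    basis: BasisMatrix,
    sample_id: str | None = None,
    min_cpm: float = MIN_MIXTURE_CPM,
) -> tuple[pd.Series, pd.DataFrame]:
    """Align a CPM-scale sample with the basis rows, keeping genes >= 1 CPM.

    Accepts a NormalizedCounts at stage ``cpm_ml`` (with ``sample_id``) or a
    bare CPM Series. Logged or TMM-divided stages are rejected: the mixture
    model is linear in CPM space.
    """
    if isinstance(sample, NormalizedCounts):
        if sample.stage != "cpm_ml":
            raise ValueError(
                f"deconvolution input must be stage 'cpm_ml', got {sample.stage!r}"
            )
        if sample_id is None:
            raise ValueError("sample_id required with a NormalizedCounts input")
        vector = sample.values[sample_id]
    else:
        vector = sample
    common = basis.genes.intersection(vector.index)
    b = vector.loc[common]
    b = b[b >= min_cpm]
    if len(b) < 2:
        raise ValueError("fewer than 2 basis genes at CPM >= 1 in the mixture")
    A = basis.matrix.loc[b.index]
    return b, A


def standardize(
    b: pd.Series, A: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Center/scale b (own mean/sd) and A (global mean/sd, one matrix)."""
    bv, Av = b.values.astype(float), A.values.astype(float)
    b_sd, A_sd = bv.std(), Av.std()
    if b_sd == 0 or A_sd == 0:
        raise ValueError("zero variance in mixture or basis; cannot standardize")
    params = {"b_mean": bv.mean(), "b_sd": b_sd, "A_mean": Av.mean(), "A_sd": A_sd}
    return (bv - params["b_mean"]) / b_sd, (Av - params["A_mean"]) / A_sd, params


def fit_grid(
    b_std: np.ndarray,
    A_std: np.ndarray,
    nu_grid: tuple[float, ...] = NU_GRID,
    c_grid: tuple[float, ...] = C_GRID,
    tol: float = SOLVER_TOL,
    max_iter: int = SOLVER_MAX_ITER,
) -> list[Candidate]:
    """One linear nu-SVR fit per (nu, C); returns raw coefficient vectors."""
    if not nu_grid or not c_grid:
        raise ValueError("empty hyperparameter grid")
    candidates = []
    for nu in nu_grid:
        for C in c_grid:
            model = NuSVR(kernel="linear", nu=nu, C=C, tol=tol, max_iter=max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(A_std, b_std)
            converged = model.n_iter_ < max_iter
            candidates.append(
                Candidate(
                    nu=nu,
                    C=C,
                    raw_weights=model.coef_.ravel().copy(),
                    support_vector_count=len(model.support_),
                    converged=bool(converged),
                )
            )
    return candidates


def normalize_weights(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Zero negative weights and renormalize to the simplex.

    Returns (fractions, degenerate). When every weight is <= 0 the zero
    vector is returned with the degenerate flag set.
    """
    w = np.asarray(raw, dtype=float).copy()
    w[w < 0] = 0.0
    total = w.sum()
    if total <= 0:
        return np.zeros_like(w), True
    return w / total, False


def select_model(
    candidates: list[Candidate],
    b: pd.Series,
    A: pd.DataFrame,
    cell_types: pd.Index | None = None,
) -> DeconvolutionResult:
    """Pick the candidate whose reconstruction has the smallest RMSE.

    The reconstruction uses the simplex-normalized weights: predicted
    expression = ``A @ theta``, rescaled to the measured library total
    (fractions carry no overall-abundance information, so the predicted and
    measured totals are matched before comparison). RMSE is the root mean
    squared residual in units of the sample's expression standard deviation,
    making it comparable across samples; Pearson r is computed on the same
    pair. Ties break by smaller nu, then smaller C.
    """
    bv = b.values.astype(float)
    Av = A.values.astype(float)
    b_sd = bv.std()
    if b_sd == 0:
        raise ValueError("constant mixture; RMSE undefined")
    if cell_types is None:
        cell_types = A.columns
    best = None
    for cand in candidates:
        theta, degenerate = normalize_weights(cand.raw_weights)
        if degenerate:
            continue
        pred = Av @ theta
        total = pred.sum()
        if total <= 0:
            continue
        pred = pred * (bv.sum() / total)
        rmse = float(np.sqrt(np.mean((pred - bv) ** 2)) / b_sd)
        r = float(pearsonr(pred, bv)[0]) if np.std(pred) > 0 else np.nan
        key = (rmse, cand.nu, cand.C)
        if best is None or key < best[0]:
            best = (key, theta, cand, r)
    if best is None:
        raise ValueError("all candidate fits degenerate (no positive weights)")
    key, theta, cand, r = best
    return DeconvolutionResult(
        theta=pd.Series(theta, index=cell_types, name="fraction"),
        nu=cand.nu,
        C=cand.C,
        rmse=key[0],
        pearson_r=r,
        n_genes_used=len(bv),
        support_vector_count=cand.support_vector_count,
    )


def deconvolve(
    sample: NormalizedCounts | pd.Series,
    basis: BasisMatrix,
    sample_id: str | None = None,
    nu_grid: tuple[float, ...] = NU_GRID,
    c_grid: tuple[float, ...] = C_GRID,
) -> DeconvolutionResult:
    """Full per-sample pipeline: align, standardize, grid fit, select."""
    b, A = prepare_mixture(sample, basis, sample_id=sample_id)
    b_std, A_std, _ = standardize(b, A)
    candidates = fit_grid(b_std, A_std, nu_grid, c_grid)
    return select_model(candidates, b, A, basis.cell_types)


def deconvolve_cohort(
    matrix: NormalizedCounts,
    basis: BasisMatrix,
    nu_grid: tuple[float, ...] = NU_GRID,
    c_grid: tuple[float, ...] = C_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deconvolve every sample; returns a long results table + batch summary.

    The long table has one row per (sample, cell type) with the fraction and
    the selected model's (nu, C, rmse, pearson_r). The summary holds mean
    fractions per batch.
    """
    rows = []
    for sample_id in matrix.values.columns:
        res = deconvolve(matrix, basis, sample_id=sample_id, nu_grid=nu_grid, c_grid=c_grid)
        batch = matrix.meta.loc[sample_id, "batch"]
        for cell_type, frac in res.theta.items():
            rows.append(
                {
                    "sample": sample_id,
                    "batch": batch,
                    "cell_type": cell_type,
                    "fraction": frac,
                    "nu": res.nu,
                    "C": res.C,
                    "rmse": res.rmse,
                    "pearson_r": res.pearson_r,
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.pivot_table(index="batch", columns="cell_type", values="fraction", aggfunc="mean")
    )
    return table, summary
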