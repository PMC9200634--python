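# cforigin

Cell-types-of-origin analysis of the plasma cell-free transcriptome.

Cell-free RNA (cfRNA) in blood plasma is a mixture of transcripts shed by
cells across the whole body. `cforigin` resolves that mixture into
fractional **cell-type** contributions — a finer readout than the
tissue-level deconvolution most liquid-biopsy analyses stop at — and
quantifies disease-driven shifts in specific cell types (e.g. proximal
tubule loss in kidney disease, hepatocyte signal in fatty liver disease)
through signature scores. It is aimed at computational biologists working
with cfRNA-seq count data plus a labeled single-cell reference atlas.

## The model

A plasma sample's expression vector `b` (CPM per mL of plasma) is modelled
as a non-negative linear combination of cell-type reference profiles:

```
A θ = b,    θ ≥ 0,  Σ θ = 1
```

* `A` — the **basis matrix** (genes × cell types, CPM scale), built from a
  labeled single-cell atlas by coarse-graining transcriptionally similar
  cell types (dendrogram cutting per organ compartment), subsampling to
  ≤ 30 cells per type, and selecting a discriminatory "barcode" gene set
  that minimizes the matrix's condition number κ subject to per-gene
  rank-test significance.
* `θ` — fractions learned per sample by linear-kernel **nu-SVR** over a grid
  of (ν, C); negative weights are zeroed and the rest renormalized to the
  simplex; the grid candidate whose reconstruction `Aθ` has the smallest
  RMSE against the measured values is selected.

Around the core sit sample QC (3′ bias / ribosomal fraction / intron-exon
ratio with strict exclusion thresholds 0.4 / 0.2 / 3), CPM-per-mL + TMM
normalization, whole-body cell-type-specific gene profiles (single-cell DE
combined with Gini ≥ 0.6 tissue specificity against a consensus tissue
table), and cohort comparisons of signature scores (Mann-Whitney U with
permutation-test calibration). A bundled synthetic-data generator produces
every input with known ground truth, so the entire pipeline is testable
offline.

## Worked example

Simulate an atlas, build a basis matrix, simulate one plasma mixture with
Poisson counting noise, and deconvolve it:

```python
import numpy as np
from cforigin import synthetic_data as sd, atlas_basis as ab
from cforigin import normalization as nz, deconvolution as dc

spec = sd.AtlasSpec(n_cell_types=5, n_genes=200, cells_per_type=40,
                    markers_per_type=10, seed=1)
atlas = sd.generate_atlas(spec)
grouped = ab.coarse_grain(atlas, seed=0)
sub = ab.subsample_cells(grouped, n_max=30, seed=0)
basis = ab.build_signature_matrix(sub, barcode_range=(2, 8), seed=0)
print(f"basis: {basis.matrix.shape[0]} genes x "
      f"{basis.matrix.shape[1]} cell types, kappa = {basis.kappa:.2f}")

theta_true = np.random.default_rng(3).dirichlet(np.ones(5))
truth = sd.MixtureTruth(theta_true=theta_true, noise_model="poisson")
mix = sd.generate_mixture(basis, truth, seed=7, sample_id="plasma_01")
cpm = nz.deconvolution_pipeline(sd.mixtures_to_counts([mix]))
res = dc.deconvolve(cpm, basis, sample_id="plasma_01")
for ct, frac, true in zip(res.theta.index, res.theta.values, theta_true):
    print(f"{ct}: estimated {frac:.3f}  (true {true:.3f})")
print(f"selected nu={res.nu}, C={res.C}, RMSE={res.rmse:.4f}, r={res.pearson_r:.4f}")
```

Output:

```
basis: 15 genes x 5 cell types, kappa = 1.72
type_00: estimated 0.025  (true 0.025)
type_01: estimated 0.088  (true 0.088)
type_02: estimated 0.315  (true 0.315)
type_03: estimated 0.495  (true 0.495)
type_04: estimated 0.077  (true 0.077)
selected nu=0.05, C=10, RMSE=0.0016, r=1.0000
```

The basis builder selected 15 barcode genes whose per-type mean profiles are
nearly linearly independent (κ = 1.72; κ near 1 is ideal, large κ means
collinear cell types the regression cannot separate). The five estimated
fractions match the planted mixture to the third decimal even under Poisson
noise, and the chosen grid point reconstructs the measured expression almost
perfectly (RMSE in units of the sample's expression sd).

The same steps are scriptable from a shell — see `cforigin --help`
(`simulate`, `qc`, `normalize`, `build-basis`, `deconvolve`, `profile`,
`score`, `compare`, `coverage`, `markers`).

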