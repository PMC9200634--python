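# Methods

## The mixture model

Plasma cell-free RNA (cfRNA) is modelled as a non-negative linear mixture of
the expression profiles of the cell types shedding RNA into the circulation:

    A @ theta = b

where `A` is a genes × cell-types **basis matrix** of CPM-scale reference
profiles, `b` is one sample's CPM-per-mL expression vector, and `theta` is
the vector of fractional cell-type contributions (non-negative, summing to
one). Everything in the package either builds the inputs of this equation
(QC, normalization, basis construction), solves it (nu-SVR deconvolution),
or works around the limits of the basis (cell-type gene profiles and
signature scores for cell types the basis cannot carry).

## Sample QC

Three per-sample metrics proxy the dominant cfRNA failure modes, each
computed from tabular inputs (an htseq-style per-exon count table and a
read-category summary):

| metric | definition | exclude when |
|---|---|---|
| 3' bias fraction | detected genes with all reads on their highest-numbered exon / detected genes | > 0.4 |
| ribosomal fraction | ribosomal reads / total reads | > 0.2 |
| intron/exon ratio | intronic reads / exonic reads | > 3 |

Comparisons are strict: a sample exactly at a threshold is retained.
Duplicated (gene, exon) rows are summed before the all-on-last-exon test,
and genes with zero total reads are not "detected". Exon numbers are assumed
transcript-ordered (strand handled upstream by the annotation), so the
3'-most exon is the highest exon number. Alignment-level work (trimming,
mapping, duplicate marking, read-category assignment) is upstream of this
package; the metrics are defined on its tabular outputs.

## Normalization

Counts are scaled to CPM per mL of plasma:
`eta_ij = 1e6 * Gene_ij / (LibrarySize_j * plasma_ml_j)`. Samples with no
recorded plasma volume get 1 mL with a warning. Deconvolution consumes this
linear stage directly, after technical replicates of a biological replicate
are averaged (arithmetic mean on the linear scale). For scoring analyses the
CPM values are additionally divided by a per-sample TMM factor, replicate-
averaged, and then log(1 + x) transformed; the stage tag on the container
(`cpm_ml`, `cpm_ml_tmm`, `log_cpm_tmm`) is enforced at every entry point so
linear- and log-scale stages cannot be swapped.

TMM factors follow the trimmed-mean-of-M-values procedure: against a
reference sample (the one whose upper-quartile expression fraction is
closest to the cohort mean), per-gene M = log2 ratio and A = mean log2
abundance are computed over genes expressed in both samples; M is trimmed
30% two-sided and A 5% two-sided; the factor is 2 to the precision-weighted
mean of the surviving M values, and factors are geometric-mean-centered so
they multiply to one. Precision weights use the delta-method variance at a
nominal library size of 1e6, since the module operates on CPM-scale values.
Counts in `b` and `A` are never log-transformed before deconvolution: the
log's concavity breaks the linearity of the mixture model and biases
`theta` downward.

## Basis-matrix construction

From a labeled cell atlas (AnnData; droplet assay, decontaminated counts
assumed upstream):

1. **Exclusions** — ambiguous cell-type labels, unwanted tissues, and listed
   genes (e.g. dissociation-stress genes) are removed.
2. **Coarse-graining** — per organ compartment, cells are CPM-normalized and
   logged, projected to the first 50 principal components, and per-type mean
   profiles are clustered (complete linkage, Euclidean distance in PC
   space). The dendrogram is cut at 20% (epithelial) / 10% (stromal) of its
   maximum node height, and merged labels become "/"-joined group names. The
   endothelial compartment collapses to a single column; the immune
   compartment keeps a curated label list with erythrocytes and erythroid
   progenitors merged. Cutting per-type means (rather than cell-level
   linkage) is the implemented reading; a cell-level variant would differ
   only in tie regions.
3. **Subsampling** — at most 30 cells per grouped type (all cells when fewer),
   so abundant types do not dominate the signature selection.
4. **Signature selection** — per grouped type, a two-sided Wilcoxon rank-sum
   test (vectorized, tie-corrected normal approximation) of that type's
   cells against the rest; genes need BH q < 0.01, positive enrichment, and
   a stability check (direction consistent across 5 random half-samples of
   cells at rate 0.5 — an explicit stand-in for the replicate/sampling
   stabilization of signature-matrix tools, whose exact scheme is not
   public). Candidates are ranked by fold change (ties: ascending q, then
   gene id, for determinism). The per-type top-gene count is swept over a
   configurable range; for each count the candidate matrix of per-type mean
   CPM over the union of selected genes is scored by its 2-norm condition
   number kappa, and the smallest-kappa candidate with kappa <= 999 wins
   (the global minimum with a warning when none is under the cap). Small
   kappa means nearly linearly independent columns, which is what the
   regression downstream needs. At production scale the sweep corresponds
   to a few thousand total barcode genes; synthetic tests scale it down.

## Nu-SVR deconvolution

Per sample: genes at CPM >= 1 that are present in the basis rows form `b`;
the basis rows are subset to match. `b` is centered/scaled by its own
mean/sd and `A` globally as one matrix — per-column standardization would
erase between-column magnitude differences that carry cell-type abundance
signal. A linear-kernel nu-SVR is fitted for every point of the grid
nu ∈ {0.05, 0.1, 0.15, 0.25, 0.5, 0.75} × C ∈ {0.1, 0.5, 0.75, 1, 10}
(support vectors are genes). Per candidate, negative coefficients are zeroed
and the rest renormalized to the simplex; an all-non-positive fit is flagged
degenerate and excluded from selection.

**Model selection.** Predicted expression is `A @ theta` in CPM space,
rescaled to the measured library total (fractions carry no overall-abundance
scale), and RMSE is the root mean squared residual in units of the sample's
expression sd; Pearson r is computed on the same pair. The smallest-RMSE
candidate wins; ties break toward smaller nu, then smaller C (sparser
support). Comparing instead in the standardized fit space was tried and
rejected: the simplex renormalization discards the fitted scale there, so
exact-recovery candidates can score *worse* than underfit ones — on
noiseless synthetic mixtures that variant selects wrong models (L1 error
~0.4) while the library-matched CPM-space comparison recovers `theta`
essentially exactly.

**Solver settings.** libsvm's NuSVR does not terminate on parts of the grid
at very tight tolerances, so fits run at tol 1e-4 with a 50,000-iteration
cap; a capped fit is flagged as non-converged on its candidate rather than
hidden. At these settings noiseless recovery error is ~1e-5 in L1, so
nothing is lost relative to tighter tolerances.

## Cell-type gene profiles and specificity indices

For cell types unique to one tissue, a profile gene must pass (1)
within-atlas differential expression — counts normalized to 1e4 per cell,
log1p, Wilcoxon rank-sum vs all other types with BH q < 0.01, fold change
>= 1.5 (ratio of expm1 group means of logged values), in-group detection
fraction >= 0.2, out-group fraction <= 0.5, and the highest per-other-type
detection fraction under half the in-group fraction — and (2) whole-body
tissue specificity in a consensus tissue table: Gini >= 0.6, an
enriched/enhanced specificity category, and the native tissue among the
gene's listed specific tissues. Genes absent from the tissue table are
dropped, not imputed.

The indices, over a gene's expression x across n tissues:

* Gini = (n+1)/n − 2·Σᵢ (n+1−i)·x₍ᵢ₎ / (n·Σx), x sorted ascending — 0 for a
  uniform gene, (n−1)/n for a one-hot gene; equivalent to the mean-absolute-
  difference form, which the tests use as an independent oracle.
* Tau = Σᵢ (1 − xᵢ/max x) / (n−1) — 0 uniform, 1 one-hot.

Both are scale- and permutation-invariant; Gini never decreases when mass
moves from a low entry to a high entry. Tissues with many correlated
subregions (brain-like tables) depress Gini mechanically; the threshold is
deliberately kept global rather than per-tissue.

`profile_foldchange_check` validates a derived profile against bulk data on
the log counts-per-ten-thousand scale: the median summed profile expression
in the native tissue over the mean of per-tissue means elsewhere must
exceed 1.

## Signature scoring and cohort statistics

A sample's signature score for a cell type is the sum of its log CPM-TMM
values over the profile genes; undetected genes contribute 0 so scores stay
comparable across samples (a dropout filter — keep genes non-zero at least
once in *both* cohorts — is available for shallow cohorts). Cohorts are
compared with a Mann-Whitney U test: exact enumeration for tie-free groups
of <= 8, tie-corrected normal approximation otherwise.

All permutation procedures share one convention: statistic recomputed under
n_perm label shuffles and p = max(#{permuted >= observed}, 1)/(n_perm + 1).
The +1 counts the unpermuted comparison; the clamp keeps p in (0, 1]. When
all scores are equal every permuted statistic ties the observed zero and
p = n_perm/(n_perm + 1). The same machinery drives p-value calibration
(statistic: difference in group mean scores) and the Gini permutation test
(statistic: mean Gini of cell-type-profile genes minus mean Gini of
tissue-specific-only genes, computed across cell types from mean log
counts-per-ten-thousand).

Gene-set overlaps (disease DEGs vs a profile) use the upper-tail
hypergeometric probability. Tissue contributions the basis cannot capture
are tallied as `(G_j − R) ∩ HPA`: genes detected at >= 1 CPM in a
sample, absent from the basis rows, and tissue-specific in the consensus
table (enriched/enhanced category, peak NX >= 10), counted per tissue.
Marker detection filters a PanglaoDB-style table to human markers with
sensitivity >= 0.9 and specificity <= 0.2 (specificity is an off-target
expression rate, so low is specific), counts markers with logged expression
> 0, and reports cell types averaging more than 5 detected markers.

## The synthetic-data generator

The generator produces every input with known ground truth:

* **Atlas** — negative-binomial counts (var = mu + 0.3·mu²) with disjoint
  marker blocks: markers at 8× the base mean in their own type, base mean
  elsewhere. The default base mean is 0.4 counts/cell so off-target markers
  are detected in ~25-30% of cells — without that sparsity every gene is
  ubiquitously detected and the DE fraction filters reject all markers, as
  they would on real scRNA-seq only for housekeeping genes.
* **Mixtures** — expected counts proportional to `A @ theta_true` at a depth
  of 5e6 (a realistic exome-enriched cfRNA library), with noise menu none /
  Poisson / mean-one lognormal-multiplicative.
* **Exon tables** — exactly round(frac·n) genes 3'-only; ribosomal and
  intronic counts matching requested fractions to integer rounding.
* **Tissue table** — markers high only in their native tissue (one-hot rows,
  Gini exactly (n−1)/n), housekeeping genes flat (Gini 0); categories
  assigned by rule (top >= 4× second → Tissue enriched; flat → Low tissue
  specificity; else Tissue enhanced) so the category filter is exercised.
* **Cohorts** — NB counts around lognormal per-gene means; group B's profile
  genes shifted by exp(log_effect); background genes exchangeable under the
  null.
* **Marker database** — planted markers pass the sensitivity/specificity
  filters; decoys each fail exactly one filter.

Every generator is a pure function of its seed. What the generator does
*not* emulate: ambient-RNA contamination, batch effects, doublets, gene-gene
correlation beyond the planted blocks, fragment-level biases, and realistic
transcriptome dimensionality — so green tests certify the algorithmic
contracts (recovery, calibration, threshold behavior), not performance on
real plasma libraries.

## Problem sizes and numerical choices

Test and benchmark scales were chosen for desk-scale determinism: 5-type ×
200-gene atlases for unit tests; a 10-type × 500-gene all-marker atlas
(kappa ≈ 2.4) for the recovery benchmark (100 noiseless + 200 noisy
mixtures); 2000 replicates × 1000 permutations for the calibration check;
100 cohort simulations at n = 20/group for power. Deconvolution recovery at
these conditions: 100% of noiseless trials under 0.05 L1 error (mean
~1e-5); median L1 rises monotonically to ~0.07 at 20% multiplicative noise;
planted-effect power 1.0 at log-effect −1.

Degenerate inputs are errors, not silent results: zero library sizes,
constant mixtures, all-zero Gini vectors, empty profiles, and empty
permutation groups all raise with the offending sample or type named.
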