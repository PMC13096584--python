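# Methods

## The analysis model

The liver lobule is functionally zonated along the central-vein (CV) →
portal-vein (PV) axis. The package treats zonation not as a geometric
problem but as a scoring problem: every spatial spot gets a **region
score** (CV signature score − PV signature score), and space is collapsed
to nine per-sample equal-count quantile bins ("layers") of that score.
All downstream spatial statistics — density profiles, correlations, the
permutation colocalization test — operate on spots, layers, or both, and
are therefore insensitive to the actual lobule geometry. This is the key
simplification the synthetic generator exploits (below).

### Module scores

The score of gene set *S* on observation *i* is

    score(i) = mean_{g in S} x_ig − mean_{g in C} x_ig

where *x* is log1p library-size-normalized expression and *C* is a pooled
control set: genes are ranked by dataset-wide average expression and cut
into `nbins` equal-count bins; for every signature gene, `nctrl` controls
are drawn from its bin (without replacement within the bin, signature
genes excluded). Defaults `nbins=24`, `nctrl=100` follow the convention of
the widely used control-matched scoring method; both are parameters and
are recorded in run metadata. Zero-expression genes participate in
binning (lowest bin). Numerically, both means are computed after
subtracting the first signature gene's value per observation — an exact
no-op algebraically that keeps the score identically zero on
observation-constant input instead of ~1e-16.

Marker signatures are built per label as the top 30 one-vs-rest genes by
log2 fold-change (ties by adjusted p, then gene id), then made mutually
disjoint: a gene claimed by several labels stays with the label with the
larger fold-change (exact ties: lexicographically first label).

### Layers

Within each sample, spots are sorted by region score descending (ties
broken by observation id) and split into nine contiguous blocks whose
sizes differ by at most one, the larger blocks taking lower layer
numbers. The sorted-block construction (rather than interpolated
quantile cut-points) guarantees the size property and makes assignment
invariant to any strictly increasing transform of the score. Layers 1–3
are reported as CV zone, 4–6 intermediate, 7–9 PV zone.

### Ro/e enrichment

For type X over an explicit universe of cells, the 2×2 table
(X / not-X) × (old / young) gives expected_old_X = old_total ×
type_total / grand_total, Ro/e = observed/expected, and a Pearson
chi-square statistic (df=1). No continuity correction by default (Yates
available by flag); expected cells below 1 set a `reliable=False` flag
but values are still reported. Per-type p-values are reported raw, with a
BH-adjusted column alongside. The universe is an explicit argument
because restricting it (e.g. to immune cells) changes every denominator;
defaulting silently would hide a scientific choice. Cells are pooled
across samples within group; the sample-level mean-proportion
fold-change (`log2fc_proportion`, with pseudocount 1e-4) is the companion
view that respects sample structure.

### Bhattacharyya divergence

Between two groups of a cell type, in a reduced embedding:

    D = 1/8 (μ1−μ2)ᵀ Σ̄⁻¹ (μ1−μ2) + 1/2 ln( det Σ̄ / √(det Σ1 det Σ2) ),
    Σ̄ = (Σ1+Σ2)/2

with ridge 1e-6·I added to each covariance for stability at n=250, d=10.
The embedding is PCA on centered, unit-scaled top-2000-variance genes,
with component signs fixed (largest-magnitude loading positive) for
determinism. The Gaussian closed form and the 10-dimensional space are
design choices — the distance is named, not fully specified, by its
common usage — so only rank-order statements across cell types are
treated as meaningful, never absolute distance values. Subsampling (250
cells per group, 100 repetitions, without replacement; with-replacement
fallback is flagged) removes the dependence of the finite-sample bias on
group size, making medians comparable across types.

### Colocalization permutation test

Observed statistic: Pearson correlation of the two types' per-spot
densities within each sample, averaged across samples. Null: the second
type's densities are permuted across spots independently within each
sample, which preserves each sample's density distribution while
destroying spatial pairing, so sample-level abundance differences cannot
masquerade as colocalization. One-sided (≥) add-one p-value
p = (1 + #{null ≥ obs}) / (n_perm + 1), never zero by construction.
A non-correlation overlap statistic (`min_product`: spot-mean of the
pointwise minimum of mean-scaled densities) is available via `stat=`.

### Differential expression

Two-sided Wilcoxon rank-sum per gene on normalized values with BH
adjustment; log2 fold-change on de-logged normalized group means with
ε=1e-9. The rank-sum test stands in for hurdle-model DE engines: the
package's claims are threshold-based recovery of planted effects, not
p-value replication of any particular engine. Genes are called up/down
when |log2FC| clears the threshold (strict 1, lenient 0.25) and adjusted
p < 0.05; the three-way intersection keeps genes consistently up (or
down) in all three comparisons.

## The synthetic generator

`simulate_spatial` places spots on a grid with a latent zonation
coordinate z ∈ [0,1] (0 = CV, 1 = PV) varying as a sinusoid with two full
periods across columns, so every sample spans both zones — mimicking the
statistical structure of a field of lobules once space is collapsed to
score quantiles, without modelling hexagonal geometry (downstream
statistics depend only on the distribution of z). CV markers have
negative-binomial counts with mean base·exp(−β·z), PV markers
base·exp(+β·z), background genes constant means drawn once per run.
Cell-type abundance surfaces are logistic in z (slope 8), scaled by
per-group amplitudes, optionally with group-specific profiles (the
Tex-like default: flat in young, PV-graded in old, matching the biology
the pipeline is meant to detect); the observed abundance matrix
multiplies the truth by gamma noise with 10% coefficient of variation,
standing in for deconvolution uncertainty.

`simulate_single_cell` draws cells per group from a multinomial
composition; each type has disjoint elevated marker genes (default 5 per
type at +3 log2), and configured effect genes are shifted by their log2
fold in old-group cells of one type.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| `n_spots` / samples | 2,000 over 2 young + 2 old | spot-level study scale; four samples as in a small spatial cohort |
| `n_genes` | 1,000 | large enough that the 24 expression bins hold useful control pools; module scoring degrades artificially below a few hundred genes |
| `n_cv_markers`, `n_pv_markers` | 30 each | the field's top-30-per-class signature convention |
| `base_mean` | 20 counts/gene | bin-aggregated spots pool many cells, so marker counts are tens, not ones |
| `nb_dispersion` (NB size) | 10 | mild overdispersion; pooling cells into spots pushes counts toward Poisson |
| `zonation_beta` | 1.0 | e-fold expression change across the axis — a conservative zonation gradient |
| abundance noise CV | 10% | typical spread of deconvolution posteriors |
| `sc_n_cells_per_group` | 2,000 | small two-group single-cell study |

All randomness flows from a single `numpy.random.Generator` seeded by
`cfg.seed`; identical configs give identical outputs. The serialized
`SynthTruth` (latent z, noise-free abundances, marker/effect-gene maps,
compositions) is sufficient to verify every downstream claim without
regenerating the data.

What the generator does **not** emulate: batch effects, per-gene
dispersion variation, segmentation/spillover artifacts, spatially
correlated noise, doublets, and ambient RNA. Passing tests therefore
demonstrate that the statistics recover the structure they are designed
for under idealized sampling noise — not robustness to the technical
artifacts of real spatial data.

## Numerical and degenerate-input choices

- QC comparisons are strict (`>` / `<`): boundary observations are
  retained; mito genes are matched case-insensitively by prefix (default
  `mt-`), computed on raw UMIs; a matrix with no mito genes skips the
  rule with a recorded warning rather than failing.
- Zero-total observations normalize to all-zero rows.
- Equal-count splits (expression bins, layers) are sorted-block
  partitions with deterministic id tie-breaks.
- Zero-variance vectors: correlations are reported as missing with a
  reason (layer profiles), or the sample is excluded with a warning
  (permutation test); z-scoring guards sd = 0 to 0.
- Rank-sum p-values that are undefined (constant gene in both groups)
  are set to 1.
- The pipeline fans one global seed out to stages by hashing the stage
  name (SHA-256, reduced below 2^31), so adding a stage never perturbs
  the randomness of earlier ones.

## Validation problem sizes

The statistical validation suite runs the chain at the default study
conditions (2,000 spots; 1,400–3,000 cells per group for recovery
scenarios) and uses 100 simulated replicates for recovery-rate claims and
200 for null-calibration claims; the permutation test is calibrated at
999 permutations in replicated runs and exercised at the full 10,000 in
single runs. The acceptance script uses 30–50 replicates per rate, a
choice that keeps a full from-scratch reproduction under a minute while
holding Monte-Carlo error on reported rates near the percent level.

## Known limitations

- The Gaussian Bhattacharyya estimator is biased upward at finite n; only
  medians under equal subsampling are compared, never raw values.
- Ro/e pools cells across samples within a group, so per-sample
  correlation structure is not modelled (the companion sample-level
  fold-change view partially compensates).
- The permutation test's within-sample shuffle null does not preserve
  spatial autocorrelation; with strongly autocorrelated abundance noise
  it would be anticonservative. The generator's noise is independent
  across spots, so the calibration shown holds under that assumption.
- Layer allocation requires at least nine spots per sample and is
  score-based only; no histology-derived vein positions are used.
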