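# Methods

This note documents the models and procedures implemented in `tumorhet`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic generators do and do not emulate, and the package's known
limitations.

## Genotype calling from in-situ signals

Each nucleus record holds four nonnegative integer signal counts: FISH spot
counts for *ERBB2* and the CEP17 centromeric reference, and in-situ PCR
counts for the mutant and wild-type *PIK3CA* H1047R allele. Calling is a
deterministic two-axis rule:

- **Amplification axis.** Amplified iff ERBB2:CEP17 ≥ `amp_ratio_threshold`
  (default 2.0, the clinical FISH convention for *ERBB2*), or — when no
  CEP17 signal was detected — iff the absolute ERBB2 count reaches
  `amp_copy_fallback` (default 6). The ratio boundary is inclusive.
- **Mutation axis.** Mutant iff the mutant-allele count reaches
  `min_total_pik3ca_signals` (default 1); otherwise wild-type iff the
  wild-type count reaches it; otherwise the axis is undetermined. A mutant
  signal takes precedence over a co-detected wild-type signal: a
  heterozygous cell carries the mutation regardless of the remaining
  wild-type allele.

The cross of the two axes yields WT, Amp (amplified with undetermined
*PIK3CA*), Mut, WT-Amp, and Mut-Amp; nuclei undetermined on both axes are
`Undetermined` and excluded from all frequencies (numerator and
denominator). Mapping "amplified + undetermined *PIK3CA*" to Amp is a
documented assumption — the distinction between Amp and WT-Amp is not
observable any other way from these signals — and every threshold is a
config parameter recorded in the run log.

**Aggregation.** Image-level frequencies pool the image's determinate
cells. Sample- and patient-level frequencies are the arithmetic mean of
image-level frequency vectors rather than a pooled cell count: biopsies
vary widely in the number of quantifiable nuclei, and averaging images
keeps one unusually cell-rich image from dominating a patient. Images with
zero determinate cells are flagged and excluded from the mean.

**Frequency change.** Per genotype, the per-patient delta is the
posttreatment minus pretreatment patient-level frequency; the two-sided
Wilcoxon signed-rank test asks whether deltas center on zero. Zeros are
dropped before ranking (Wilcoxon's original treatment), ties get midranks,
and for n ≤ 25 nonzero deltas the null is exact: the distribution of the
positive-rank sum over all 2ⁿ sign assignments, computed by convolution on
doubled ranks so midrank ties stay exact. All deltas zero gives p = 1 by
convention; fewer than 3 patients gives no p-value. No multiplicity
correction is applied by default (a Benjamini-Hochberg helper is available)
— the five genotype tests are reported raw.

## Spatial statistics

All distances are Euclidean on 2-D nuclear centroids in micrometers
(image convention: origin top-left, y down; every statistic here is
isometry-invariant, so only consistency matters).

**Fixed-radius proximity.** For a type pair (A, B), the count of B cells
within `radius_um` (default 75 μm) of each A cell, with an inclusive
boundary and self-pairs excluded when A = B (a cell is not its own
neighbor; the alternative convention would add a constant 1). The query
uses a k-d tree whose output is required — and tested — to be bit-identical
to an all-pairs scan; the tree is an optimization, not a semantic.

**Shannon entropy.** H = −Σ pᵢ log pᵢ over category frequencies,
renormalized internally, 0·log 0 = 0, natural log by default (bits
optional). Used per case for tumor receptor composition (HER2 / ER /
HER2+ER+ / DN) and immune composition (B cell / CD4 T / CD8 T /
macrophage).

**k-means dispersion.** "Is this labeled subpopulation spatially clumped?"
is answered with a declared, fully parameterized statistic: fit k-means
(k = 3 by default, k-means++ seeding, 10 restarts, best inertia) to the
labeled cells' coordinates and take w = the mean distance of those cells to
their assigned centroid. The null draws `n_permutations` subsets of the
same size uniformly without replacement from all cells in the unit and
recomputes w. The score is w_obs / mean(w_null) (≈ 1 under random labels,
< 1 when clumped; translation-, rotation- and scale-invariant since the
scale cancels), and p_clustered = (1 + #{null ≤ obs}) / (n_permutations +
1) — the add-one estimator, one-sided for clustering, never exactly zero.
Units with fewer labeled cells than `min_cells_per_label` (default 20) or
than k are flagged not-evaluable. The k-means solver is a compact seeded
Lloyd implementation (k-means++ init, vectorized distance updates): the
permutation null evaluates the statistic tens of thousands of times on
small point sets, where per-call overhead dominates; its optima are
cross-checked against scikit-learn's KMeans in the test suite.

## CycIF phenotyping

**Thresholding.** Default `gmm2`: a two-component Gaussian mixture fitted
to log(1 + intensity); the threshold is the posterior-0.5 crossing between
the component means (found by root-bisection on the log-odds), mapped back
to the intensity scale, and clamped strictly inside the observed range.
Otsu (between-class variance on a 256-bin histogram) and manual values are
alternatives. Automatic methods require ≥ 50 values and reject constant
input. Binarization is inclusive: intensity ≥ threshold is positive.

**Gating.** A gating tree is an ordered list of rules, each demanding a set
of markers be positive/negative. Lineage rules are evaluated in document
order, first match wins; subtype rules apply only within their parent
lineage, again first match wins; unmatched cells stay `unassigned`. The
shipped default tree covers tumor (CK+CD45−), immune (CD45+) with B-cell,
CD4 T, CD8 T, FoxP3+CD8+ T, macrophage and granzyme-B+ macrophage
subtypes, endothelial (CD31+) and vimentin+ stromal cells; since published
gating strategies are study-specific, the tree is fully externalizable to a
YAML config and the default is only a sensible starting point. Tumor cells
receive a receptor category from the HER2/ER binaries. In composition
summaries, granzyme-positive macrophages and FoxP3+CD8+ T cells fold into
their parent categories so the immune axis stays the canonical four.

**Case grouping.** Tumor receptor 4-vectors are clustered with Ward
linkage on Euclidean distance and cut into `n_patient_groups` groups; a
group is labeled by its mean-dominant receptor category when that mean
frequency is ≥ 0.5, else "mixed". Linkage choice and the 0.5 dominance
cutoff are conventions, both configurable.

## Cohort statistics

- **Rank-sum** (Mann-Whitney): exact p for combined n ≤ 20 without ties;
  otherwise the normal approximation with midrank tie correction and *no*
  continuity correction, so identical samples give p = 1 exactly.
- **Kruskal-Wallis**: midrank tie correction, χ² reference; the fully
  tie-degenerate case returns H = 0, p = 1 instead of dividing by zero. An
  exact permutation-enumeration p is available for total n ≤ 10, where the
  χ² approximation is poor.
- **χ² independence / mosaic residuals**: Pearson χ² without continuity
  correction; Pearson residuals r = (O−E)/√E satisfy Σr² = χ²
  (tested to 1e-9); per-cell two-sided p-values use the standard-normal
  tail 2(1−Φ(|r|)) — the conventional mosaic-plot approximation. Positive
  residuals mean enrichment over the independence expectation. Tables must
  be at least 2×2 with no all-zero margin.
- **Patient clustering**: Ward/Euclidean agglomerative clustering of
  frequency vectors, deterministic, groups renumbered by first appearance.

## Xenograft read deconvolution

Reads mapping uniquely to both the human and mouse genomes are kept only if
their human-minus-mouse alignment-score difference reaches a data-driven
threshold d\*. For each candidate d on an ascending grid (default 0, 5, …,
50): the eligible set is reads with difference ≥ d; R (50) random samples
of m (100) eligible reads are drawn without replacement; each is tested
with a paired two-sided t test of human vs mouse score; the candidate
"confidently" shows species bias when ≥ 95% (`confidence_frac`) of samples
have p ≤ 0.01. d\* is the smallest qualifying candidate; reads with
difference ≥ d\* (inclusive) are retained. Candidates with fewer eligible
reads than m are recorded not-evaluable, and if no candidate qualifies the
sentinel "none" retains nothing from the ambiguous set — the conservative
choice, logged prominently. Zero-variance paired differences give p = 1 by
convention (identical scores carry no species evidence). The pairing, m,
R, and the 95% criterion are operational choices exposed as config; the
procedure runs per sample.

## Synthetic-data generators

The generators produce inputs with the statistical structure each stage
assumes, with ground truth attached; they are bit-reproducible from their
seed and their outputs pass the package's own table validators.

- **STAR-FISH cohorts.** Ten patients, pre and post samples, three images
  per sample, negative-binomial cell counts per image (mean 300,
  dispersion 20). Genotypes are drawn from a 5-simplex (default WT 0.55,
  Amp 0.20, WT-Amp 0.10, Mut 0.05, Mut-Amp 0.10); the posttreatment
  mixture applies `treatment_delta` (default Mut-Amp +0.07) additively on
  the frequency scale with the unshifted genotypes rescaled
  proportionally (a logit-scale variant is available). Signal counts are
  generated *relative to the calling rule* — amplified cells get
  ERBB2 = 2·CEP17 plus Poisson extras, mutant cells ≥ 1 mutant signal, and
  so on — guaranteeing that calling recovers the planted genotype for
  every determinate cell; a 5% `undetermined_rate` plants uncallable
  nuclei. Cells are placed uniformly on a 1×1 mm field, except genotypes
  marked `clustered`, which follow a parent-offspring (Neyman-Scott-style)
  process: 3 uniform parents per image with Gaussian offspring scatter
  (σ = 40 μm). The generator therefore exercises the pipeline's logic, not
  FISH optics: no spot-detection noise, no segmentation error, no spatial
  correlation between genotype and cell density.
- **CycIF cohorts.** Twenty cases of 1,000 cells; cell types from a fixed
  mix (55% tumor, 21% immune across six subtypes, 12% stromal, 5%
  endothelial); case receptor mixes Dirichlet around (HER2 0.40, ER 0.25,
  HER2+ER+ 0.10, DN 0.25) with concentration 8. Marker intensities are
  log-normal, exp(N(3.0, 0.3)) for a cell's positive markers and
  exp(N(1.0, 0.3)) otherwise — a two-log-unit separation at which the GMM
  threshold misclassifies well under 5% of cells. pCR is Bernoulli with
  logit = −7.4 + 14·(HER2+ tumor fraction) + 4·(CD8 fraction): the
  intercept centers the response rate near 50% at the cohort-mean
  fractions, and the slope was fixed by an a-priori power calculation so a
  20-case rank-sum comparison of HER2+ fraction by response detects the
  effect with power ≈ 0.9 at α = 0.05. Not emulated: spatial organization
  of phenotypes, marker spillover/autofluorescence, segmentation doublets,
  batch variation across staining rounds — so passing tests demonstrate
  the pipeline's statistical machinery, not robustness to imaging
  artifacts.
- **Read scores.** A fraction (default 0.8) of reads are human:
  primary ~ N(100, 5), secondary ~ N(60, 5); mouse reads mirror this. The
  default 40-point mean gap at σ = 5 is an 8σ difference signal — a clear
  two-population regime in which the threshold procedure should saturate
  at the smallest grid candidate.
- **Cluster × treatment tables.** Multinomial counts from the product of
  the two marginals, with one optional cell multiplied by a planted factor
  and renormalized. Note a structural fact used by the recovery tests:
  with only two columns, inflating one cell forces complementary
  deviations of comparable size in the rest of the table (margins are
  fixed), so "the planted cell carries the top residual" is only a fair
  expectation for tables with ≥ 3 columns where the complement spreads
  thin; the recovery scenario uses a 4×3 table.

## Numerical choices and degenerate inputs

- Exact signed-rank enumeration switches to the tie-corrected normal
  approximation above n = 25 (the DP stays exact with midranks below
  that); the exact rank-sum path requires tie-free pooled samples.
- Permutation p-values always use the add-one estimator.
- k-means restarts are seeded from one generator stream per call, so a
  fixed `random_seed` makes dispersion results bit-reproducible.
- Readers coerce integral float counts ("2.0") and reject fractional ones;
  duplicate keys, non-finite coordinates/scores and negative intensities
  are row-level validation errors reported with 1-based row numbers,
  either raising (default) or splitting valid/rejected rows
  (`errors="collect"`).
- Degenerate statistical inputs (constant thresholding input, all-zero
  frequency vectors, 1×2 contingency tables, empty samples) raise typed
  errors rather than returning NaN.

## Problem sizes

The shipped tests and the acceptance script use desk-scale sizes chosen to
make the statistical claims testable on one CPU in minutes: 200 null units
× 99 permutations for dispersion calibration, 500 replicates for mosaic
and Kruskal-Wallis calibration, 50 instances × 2,000 cells for the
neighbor-count oracle, 10 seeds × 4,000 reads for deconvolution recovery,
and the generator defaults above for the end-to-end recoveries. All sizes
are parameters of the respective functions and scale up directly.

## Known limitations

- The genotype caller cannot distinguish true *PIK3CA*-undetermined
  amplified cells (Amp) from assay dropouts; both land in Amp.
- The dispersion statistic conditions on the observed cell positions; it
  measures label clumping relative to the unit's own density, not absolute
  density structure.
- Per-cell mosaic p-values use the normal reference for Pearson residuals,
  which is anti-conservative for cells with small expected counts.
- The gating engine is strictly binary and hierarchical; continuous or
  probabilistic gating is out of scope.
- The deconvolution threshold assumes the paired t test is meaningful on
  alignment-score differences; heavy-tailed score distributions would
  call for a rank-based variant, not implemented.
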