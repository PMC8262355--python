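# tumorhet

Single-cell heterogeneity analysis for HER2+ breast cancer under targeted
therapy. The package provides a tested, reusable implementation of four
analysis families that recur in studies combining in-situ genotyping,
multiplexed imaging, and xenograft sequencing:

1. **STAR-FISH genotyping** — each segmented nucleus carries FISH spot
   counts for *ERBB2* and the chromosome-17 centromere (CEP17) plus in-situ
   PCR counts for the mutant and wild-type *PIK3CA* H1047R allele. A nucleus
   is *amplified* when ERBB2:CEP17 ≥ 2 (clinical FISH convention) and
   *mutant* when any mutant-allele signal is present; crossing the two axes
   assigns one of five genotypes (WT, Amp, Mut, WT-Amp, Mut-Amp). Genotype
   frequencies are aggregated per image, sample and patient (patient level =
   mean of image-level frequencies, so unequal image sizes weigh equally),
   and the pre- vs post-treatment change per genotype is tested with a
   two-sided Wilcoxon signed-rank test of per-patient deltas against 0
   (exact null for n ≤ 25).
2. **CycIF phenotyping** — per-cell marker intensities are binarized with a
   two-component Gaussian-mixture (or Otsu) threshold, an ordered gating
   tree assigns lineages and subtypes, tumor cells get a receptor category
   from HER2/ER positivity, and per-case heterogeneity is summarized with
   composition vectors and Shannon entropy H = −Σ pᵢ log pᵢ.
3. **Spatial statistics** — fixed-radius neighborhood counts (the number of
   type-B cells within 75 μm of each type-A cell, Euclidean distance on
   nuclear centroids, inclusive boundary) and a k-means dispersion score:
   the mean distance of a labeled population to its assigned k-means
   centroids, normalized by a label-permutation null, with a one-sided
   permutation p-value for spatial clustering.
4. **Cohort statistics and read deconvolution** — Ward-linkage patient
   grouping on genotype/receptor frequency vectors, Kruskal-Wallis /
   rank-sum / χ² association tests, contingency-table Pearson residuals
   (O−E)/√E with per-cell normal-tail p-values ("mosaic" enrichment
   analysis), and a resampling-based threshold for retaining
   patient-derived-xenograft reads: the minimum human-minus-mouse
   alignment-score difference at which repeated random samples are
   confidently species-biased (paired t test, P ≤ 0.01).

Every stage has a synthetic-data generator with attached ground truth
(`tumorhet.simulate`), so the full pipeline is testable without any
external download.

## Worked example

Simulate a 10-patient pre/post cohort with a planted +0.07 Mut-Amp
frequency shift, call genotypes, and test the frequency change:

```python
import tumorhet as th
from tumorhet.simulate import StarfishSimParams, simulate_starfish_cohort

nuclei, truth = simulate_starfish_cohort(StarfishSimParams(seed=42))
called = th.call_genotypes(nuclei)
patient = th.genotype_frequencies(called, "patient")
summary, deltas = th.frequency_change(patient[patient.timepoint == "pre"],
                                      patient[patient.timepoint == "post"])
print(summary[["genotype", "mean_delta", "p_value"]])
```

```
  genotype  mean_delta   p_value
0       WT   -0.041651  0.001953
1      Amp   -0.017728  0.130859
2      Mut   -0.004840  0.193359
3   WT-Amp   -0.008050  0.013672
4  Mut-Amp    0.072268  0.001953
```

The Mut-Amp row recovers the planted +0.07 enrichment (estimate 0.0723);
its exact signed-rank p of 2/1024 reflects all ten patients shifting in the
same direction, and the compensatory decrease is spread over the other
genotypes.

The same pipeline is scriptable from the shell (`tumorhet simulate
starfish-cohort --seed 42 --out-dir sim/`, then `tumorhet starfish-cohort
sim/nuclei.csv --out-dir out/`); each subcommand writes CSV result tables
and a `run_log.json` with the parameters and seed.

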