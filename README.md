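# radqc

Genotype QC for RADseq population-genomic datasets, and a hierarchical
Bayesian length-at-age model — built around a cautionary case study in
which both of a study's headline findings (temporal genetic change and
region-specific growth decline in harvested walleye populations)
dissolve once the data are filtered and modelled carefully.

The package has two arms:

**Population genomics.** Weir–Cockerham (1984) F-statistics from
variance components (per-locus and ratio-of-sums multilocus θ), pooled
two-sample F_IS screening, Fisher exact tests of genic differentiation,
missingness profiling, mean-imputed individual PCA, HDplot
(heterozygosity vs read-ratio deviation) for paralog detection, and an
ordered, audited filter cascade. Two bioinformatic artifacts are
first-class citizens, each with a synthetic generator and a
demonstration:

* *population-specific missing data* — under mean imputation, a
  population missing most of its genotypes is displaced in PC space
  away from the population it is actually panmictic with, fabricating
  "structure" that a per-population locus-missingness filter removes;
* *undersplit (merged-paralog) loci* — collapsed duplicates appear as
  near-fixed heterozygotes in one sample, producing jointly extreme
  F_ST (>0.2) and pooled F_IS (<−0.2), inflating temporal θ until a
  pooled-F_IS filter removes them.

**Growth.** A Bayesian hierarchical model of total length,

    length ~ N(μ, σ²)
    μ = β₀ + u₀ⱼ + β₂ⱼ·male + (β₁ + u₁ⱼ)·age
        + β₃·south + β₄·contemporary + β₅·south·contemporary

with correlated river-level random intercepts and age slopes
(u₀ⱼ, u₁ⱼ) ~ N₂(0, Σ), river-level sex effects β₂ⱼ ~ N(μ_β₂, σ_β₂),
vague data-scaled normal priors on means, half-Cauchy priors on scales
and a uniform correlation prior, sampled by a blocked Gibbs/slice MCMC
written for this model. Derived quantities: predicted age-11 length per
location × period, the period declines, and the south-minus-north
difference in declines (the difference-in-differences that tests for
region-specific change).

A synthetic-data module generates genotype panels (Balding–Nichols
divergence with a target F_ST, configurable missingness and
under/oversplit artifact loci, negative-binomial read depths) and
growth datasets from the hierarchical model, with full ground truth, so
every stage is testable without any download.

## Layout

* `src/radqc/` — the library: `genotype_io` (genepop + tabular I/O),
  `synthetic_data`, `popgen_stats`, `qc_filters`, `structure_analysis`,
  `growth_model`, `pipeline`, `plots`, and a `radqc` CLI
  (`simulate-geno`, `simulate-growth`, `qc`, `filter`, `pca`, `fst`,
  `fst-dist`, `exact-test`, `growth-fit`, `run-all`).
* `analysis/` — numbered drivers that run the study end to end on
  synthetic data and write tables/figures under `results/`.
* `analysis/08_dryad_reproduction.py` — optional rerun against the
  original Mistassini Lake walleye deposit
  (doi:10.5061/dryad.5tb2rbp1z) after a one-time manual download.

## Worked example

```bash
python analysis/01_simulate_data.py
python analysis/05_filter_cascade_fst.py
```

prints the filter cascade for a *temporal* population pair (two samples
of one panmictic population, 4% of loci undersplit in the first
sample) next to a genuinely diverged control pair:

```
temporal pair (true theta = 0):
                  dataset  n_loci     theta             p  significant
            d1_unfiltered    2000  0.017744 1.847341e-168         True
d2_individual_missingness    2000  0.017744 1.847341e-168         True
          d3_fis_minus0.2    1872  0.001382  1.000000e+00        False
                 d4_fis_0     950 -0.000036  1.000000e+00        False

diverged control pair:
                  dataset  n_loci    theta             p  significant
            d1_unfiltered    2000 0.039785  0.000000e+00         True
          d3_fis_minus0.2    1872 0.040324  0.000000e+00         True
                 d4_fis_0     950 0.041052 3.824452e-277         True
```

The unfiltered temporal pair looks strongly, "significantly"
differentiated (θ = 0.018) purely because of 80 merged-paralog loci;
each pooled-F_IS filter step pulls θ back toward its true value of
zero and the exact test back to non-significance, while the truly
diverged pair is untouched. `python analysis/07_growth_model.py` fits
the growth model to data simulated with a 24 mm age-11 decline in the
north and 40 mm in the south and recovers declines of 22.2 and 41.2 mm
and a south-minus-north contrast of 19.0 mm (CI 13.0–25.1; truth
16 mm).

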