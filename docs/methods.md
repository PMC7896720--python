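# Methods

## Estimators

**Weir–Cockerham variance components.** For a biallelic locus observed
in two samples (sizes n₁, n₂ diploids, B-allele frequencies p₁, p₂,
observed heterozygote proportions h₁, h₂) we compute the 1984
analysis-of-variance components a (among populations), b (among
individuals within populations) and c (within individuals) with the
r = 2 formulas, per-locus θ = a/(a+b+c), and multilocus θ as the ratio
of sums Σa/Σ(a+b+c) — the ratio-of-averages convention that the cited
estimator defines; a mean of per-locus ratios is biased and is not
used. Loci genotyped in fewer than two individuals in either sample,
or monomorphic across both, are flagged undefined and excluded from
multilocus ratios; negative estimates are reported as computed, never
truncated at zero.

**Pooled-pair F_IS.** The undersplit-locus diagnostic pools the two
samples of a pair into one sample of size n with pooled frequency p and
mean observed heterozygosity h, and computes the single-sample
Weir–Cockerham F_IS = 1 − c/(b+c) with
b = n/(n−1)·[p(1−p) − (2n−1)/(4n)·h], c = h/2 — i.e. one minus the
ratio of observed to small-sample-corrected expected heterozygosity.
Pooling is deliberate: a locus that is a near-fixed heterozygote in one
of the two samples drives the pooled statistic strongly negative, which
is the signature being screened for. A sample of 2n individuals all
heterozygous gives exactly −1.

**Exact tests.** Differentiation per locus is tested with a two-sided
Fisher exact test on the 2×2 allele-count table; because the panel is
strictly biallelic the hypergeometric null is enumerated exactly and
Monte-Carlo sampling is never required (the `n_mc`/`seed` arguments are
accepted for interface stability). Loci monomorphic across the pair get
p = 1 by convention and are excluded from the across-locus Fisher
combination. This replaces the Markov-chain exact test of the Genepop
program, whose chain parameters are not part of this package's
contract; the α = 0.01 significance threshold for pairwise tables is
the default.

**HDplot.** Per locus, H is the fraction of genotyped individuals
called heterozygous; over heterozygotes only, the allele ratio is
Σa/(Σa+Σb) and the deviation D = (Σa − N/2)/√(N/4) is the binomial
z-score of the A-read count around an even split (N = total
heterozygote reads). The variance convention (binomial around 0.5) is
pinned here. Heterozygotes with zero total depth are dropped from the
sums and counted; loci with no usable heterozygotes are undefined and
are never removed by an HDplot filter step.

**PCA.** Missing dosages are imputed with the locus mean over genotyped
individuals, columns are centred (variance scaling is off by default,
behind a switch), and scores come from the SVD of the centred matrix.
Mean imputation is the default *because* it is the standard workflow
whose failure mode the package demonstrates: individuals missing many
loci are pulled jointly toward the grand centroid. Cluster separation
in tests is quantified as the silhouette score of known labels on the
retained components (2 by default), with 0.25 used as the "clearly
separated" threshold — the visual judgement replaced by a number.

## The filter cascade

Steps run strictly in their listed order and every statistic is
recomputed on the current matrix, because the cascade's semantics
depend on it (individual missingness filtering precedes F_IS
screening). Removal inequalities are strict (`F_IS < t` removes);
loci whose statistic is undefined at a step are retained by that step
and the report says so. Every removal carries the statistic value that
triggered it, and step counts telescope, so the audit trail reconstructs
the cascade exactly. The deliberately flawed k-of-n genotype-rate rule
(retain a locus genotyped at ≥ r in at least k of n populations) is
provided to demonstrate its consequence: loci 100% missing in up to
n−k populations survive.

## The synthetic generator

**Genotypes.** Clean loci follow the Balding–Nichols model: ancestral
frequency p ~ Uniform(0.1, 0.9) by default, population frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, freq). F may be
set per population; populations with F = 0 sit exactly at the ancestral
frequencies and therefore form a panmictic cluster — the configuration
needed to emulate a temporal sample pair or a reference cluster next to
diverged populations. Multilocus θ between two populations each at
divergence F calibrates to F (checked at F ∈ {0, 0.02, 0.05} over
20-seed sweeps against 3 standard errors).

**Undersplit loci** model a collapsed duplicate: one copy fixed, the
other segregating only in the affected population(s) with latent
alternate frequency q ~ Uniform(0.7, 0.95) by default, an individual
being scored heterozygous whenever the latent copy carries the
alternate allele. This yields apparent heterozygosity 1−(1−q)² ≈
0.91–0.9975 in the affected population (the "nearly fixed heterozygote"
signature), trace variation elsewhere, pooled-pair F_IS below −0.25,
and pair F_ST above 0.2. The default range is deliberately at the
strong end: it reproduces the signature that the −0.2 F_IS screen is
designed to catch, and at these effect sizes the screen removes ≥95% of
injected loci while discarding ≤5% of clean loci. The four-dataset
demonstration instead uses q ~ Uniform(0.35, 0.95), so that part of
the artifact mass falls between F_IS −0.2 and 0 and is caught only by
the stricter filter — the "bias extends below the threshold" situation
that makes the stepwise cascade informative. Heterozygote read depths
at undersplit loci are drawn with allele ratio 0.75 (three of the four
haplotype copies carry one allele), which is what HDplot flags.

**Oversplit loci** get allele-specific dropout: heterozygotes become
homozygotes for the retained allele with the dropout probability, and
homozygotes for the dropped allele become missing.

**Missingness** is applied after artifact injection: a base
per-individual rate, plus per-population dropout (a fraction of loci
receives a per-locus missing rate drawn from a configurable range,
applied to that population only; rate 1.0 is whole-locus dropout).
After everything, allele polarity is canonicalized to the genepop
reader's convention (allele A = first code encountered in file order),
so parsing an emitted file recovers the generated matrix bit-for-bit;
the flipped loci are recorded in the ground truth (a flipped undersplit
locus shows allele ratio 0.25 rather than 0.75, exactly as real HDplots
mirror around 0.5).

**Depths** are negative-binomial totals (mean 40, dispersion 5 by
default) with a binomial allele split. **What the generator does not
emulate:** linkage, selection or drift over time, read-level sequence
error, library/lane batch effects, and allele-frequency spectra of real
RAD panels. Tests passing on these panels show the estimators and
filters behave as designed under the stated mechanisms, not that any
particular real dataset is clean.

**Growth.** Records are drawn from exactly the hierarchical model the
fitter assumes. Defaults describe the study system it mimics: four
rivers (one northern reference), β₀ = 225 mm, β₁ = 25 mm/yr (age-11
fish ≈ 500 mm, realistic for walleye), β₃ = 10 mm, β₄ = −24 mm
(reference-location period decline), β₅ = −16 mm (extra southern
decline, so the south declines ≈ 40 mm), male effect −40 ± 10 mm,
river scales τ₀ = 20 mm, τ₁ = 3 mm/yr, ρ = −0.2, σ = 30 mm; ages
uniform on 3–18 years; 25 fish per river × period × sex cell by default
(125 in the recovery studies, i.e. 500 per river). River effects are
redrawn from the hierarchy per seed unless pinned, so repeated
simulation is a proper Bayesian coverage experiment.

## The growth model fit

Priors: Normal(0, (10·SD(length))²) on β₀, β₃, β₄, β₅ and μ_β₂ (the age
slope uses 10·SD(length)/SD(age)); half-Cauchy(0, 5·SD(length)) on σ,
σ_β₂, τ₀ and τ₁; uniform on the intercept–slope correlation ρ (the 2×2
case of a concentration-1 correlation prior), composed with the scales
by the scale×correlation decomposition. All hyperparameters are echoed
in the fit object.

Sampling is a blocked Gibbs sampler. All location parameters — the five
fixed effects, the river intercept/slope deviations and the river sex
effects — are drawn *jointly* from their multivariate normal full
conditional (one 17-parameter Cholesky solve per iteration with four
rivers). The joint block matters: with few rivers the grand mean and
slope are nearly confounded with the river deviations, and
one-parameter-at-a-time updates crawl along that ridge (effective
sample sizes of ~10 in early experiments; ~4,000 for the same run
length with the joint block). σ² and σ_β₂² are conjugate
inverse-gamma updates using the auxiliary-variable representation of
the half-Cauchy; τ₀, τ₁ (on the log scale) and ρ are updated by
stepping-out slice sampling, with three sweeps per iteration because
the fixed-effect autocorrelation inherits from these scales.

Default run configuration: 4 chains × 10,000 iterations, 5,000 warmup,
thinning to every 10th draw. The parameter-recovery and acceptance
studies use 4 chains × 5,000/2,500 with no thinning — a deliberate
package choice that retains more draws per unit work; both
configurations clear the convergence gates (R-hat < 1.01, ESS > 1,000)
for every fixed effect and derived contrast. The random-effect
hyperparameters τ₀ and ρ are weakly identified with four rivers and
sometimes sit below the ESS gate; the fitter warns (never errors) and
the reported quantities do not include them.

Derived quantities are deterministic functions of the saved draws:
the predicted age-11 length for a location × period averages the river
deviations over that location's rivers (u₀ⱼ + 11·u₁ⱼ), mixes sexes
50/50 through μ_β₂ (both the age and the sex mix are arguments), and
adds the relevant fixed effects; the period decline is
historical − contemporary, and the south-minus-north contrast is the
difference of declines (in expectation −β₅). Recomputing them from a
saved fit reproduces the summaries bit-for-bit. Credible intervals are
central 95% quantile intervals of the pooled chains.

## Numerical and design notes

* Genotypes are unphased dosages {0, 1, 2} with −1 as the missing code;
  allele A of each locus is the first allele code encountered in file
  order, and loci with more than two observed alleles are rejected at
  parse time (the pipeline is strictly SNP-based).
* Growth tables are consumed as delimited text with a configurable
  column map; rivers map deterministically to locations
  (Takwa → north; Chalifour, Perch, Icon → south by default) and
  sampling years to periods (2002/2003 historical, 2015–2017
  contemporary). A spreadsheet deposit must be exported to CSV once by
  the user.
* Negative per-locus F_ST estimates are binned into the lowest
  distribution bin (the bins start at 0 but every estimable locus is
  counted); bin edges are [0.05, 0.10, 0.15, 0.20) with ≥ 0.2 open.
* Subsample normalization of F_ST distributions draws without
  replacement under an explicit seed; identical seeds give identical
  bins.
* Pipeline runs are bit-reproducible: the manifest echoes the config,
  input checksums and seeds, and contains no timestamps.

## Known limitations

* The exact-test variant (Fisher exact + Fisher combination) is not the
  Markov-chain genic test of the Genepop program; significance flags on
  borderline pairs may differ between the two.
* The pooled-F_IS > 0 filter is not innocuous on ordinary data: a
  pooled heterozygote deficit is a Wahlund effect, so conditioning on
  it enriches differentiated loci and biases the same pair's θ upward.
  The cascade demonstration therefore applies it where the paper-style
  workflow does — to a temporal pair whose true θ is ~0, where the
  artifact-removal effect dominates — and the limitation is worth
  remembering before applying such filters to genuinely structured
  pairs.
* HDplot requires per-genotype allele depths, which genepop files do
  not carry; on depth-less real data the HDplot stage cannot run and is
  validated on simulated depths.
* With only four rivers the random-effect scales τ₀, τ₁ and correlation
  ρ are informed mostly by the prior; their posteriors are wide and
  slow-mixing, which is reported honestly by the diagnostics rather
  than hidden.
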