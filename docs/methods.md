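# Methods

## Model and statistics

The unit of analysis is an LD block of *m* biallelic SNPs with hard-call
genotypes g ∈ {0, 1, 2} counting copies of a per-SNP *counted* allele, and a
binary phenotype from a case-control design with *n* cases and *n* controls.
Three codings per SNP encode the mode of inheritance: additive (the count),
dominant (count ≥ 1) and recessive (count = 2); the additive coding is
exactly the sum of the other two, so the stacked coding matrix has rank at
most 2m.

The per-SNP statistic is the logistic-regression **score** statistic for a
single coded predictor with intercept, z = U/√V with
U = Σᵢ xᵢ(yᵢ − ȳ) and V = ȳ(1 − ȳ)·Σᵢ(xᵢ − x̄)².  For the additive coding
this equals the Cochran–Armitage trend statistic (verified against a
closed-form oracle in the tests).  The score form was chosen over Wald or
likelihood-ratio statistics for two reasons: it stays finite under complete
separation, and under the null its correlation across predictors equals the
predictor correlation — the property the simulation null relies on.  A coded
column with zero variance (common for the recessive coding of a
low-frequency SNP) is *degenerate*: z = 0, p = 1, and the column is retained
so Bonferroni-type multiplicities remain exactly m (or 3m).

Block-level combiners are described in the README.  Implementation details
that are genuinely choices:

- **Null correlation.**  "The LD pattern in the block" is made concrete as
  the sample Pearson correlation of the coded genotype columns (m×m for the
  additive-only tests, 3m×3m for ADR) — exact for score statistics under
  the null.  Degenerate columns get unit diagonal and zero off-diagonals, so
  their null coordinates are independent standard normals that the observed
  z = 0 never exceeds; they can only make a test conservative.
- **Sampling.**  The null statistic vectors are drawn by eigendecomposition
  with negative eigenvalues clipped at zero.  No jitter is added; the
  stacked ADR matrix is genuinely rank-deficient and clipping handles it.
- **Monte-Carlo p-value.**  Add-one convention,
  p = (1 + #{null ≥ observed})/(B + 1), so p ∈ [1/(B+1), 1] and zero
  p-values are impossible.  Default B = 1,000 (B = 500 in the
  latent-normal power study, matching its design).
- **GATES p-value correlation.**  The effective number of tests should be
  computed from the correlation of the *p-values*, not of the statistics.
  With (Zᵢ, Zⱼ) bivariate normal at correlation r and p = 2Φ(−|Z|),
  corr(pᵢ, pⱼ) = (E[pᵢpⱼ] − ¼)/(1/12) is a smooth even function of r,
  tabulated once by two-dimensional Gauss–Legendre quadrature over the
  positive quadrant (the integrand is smooth there; the |z| kink lies on the
  axes) and interpolated.  Using the statistic correlation directly
  (`transform="direct"`) is available but measurably anti-conservative:
  in the null experiment it pushed GATES' empirical size to 0.076 at
  α = 0.05, while the p-value transform keeps it at nominal.
- **PC rank handling.**  Eigenvalues below 1e−8 are discarded before
  building PC statistics; k counts retained components only (the harness
  clamps k to the retained rank so single-SNP blocks remain testable).
- **Ties.**  p-value ordering breaks ties by SNP index, deterministically.

## Genotype simulator (latent-normal / polychoric)

Correlated genotypes are simulated by drawing latent m-variate normal
vectors — exchangeable correlation ρ by construction from a shared factor,
or any user-supplied PSD latent correlation matrix — and discretising each
coordinate at the probit thresholds τ₁ = Φ⁻¹((1−p)²), τ₂ = Φ⁻¹((1−p)² +
2p(1−p)) implied by Hardy–Weinberg equilibrium at counted-allele frequency
p.  The latent correlation is the polychoric correlation (PCC) of the
genotype pair; marginal genotype frequencies are invariant to it.  The
polychoric *estimator* is the standard two-step procedure: thresholds fixed
from the margins, then the latent correlation maximising the 3×3
contingency-table likelihood, with the bivariate-normal rectangle
probabilities evaluated through the identity
Φ₂(h,k,ρ) = Φ(h)Φ(k) + ∫₀^ρ φ₂(h,k,r)dr (32-point Gauss–Legendre), which is
cross-checked against `scipy.stats.multivariate_normal.cdf` in the tests.
Round-trip recovery (simulate at ρ, re-estimate) is accurate to ±0.03 at
n = 50,000 for ρ up to 0.9.

LD blocks on a panel are inferred by average-linkage hierarchical
clustering.  The method and the PCC² block threshold (0.64) are fixed by the
study design; the distance is a choice and is taken as d = 1 − PCC², with
the dendrogram cut at height 1 − threshold so the threshold keeps its
stated meaning.  The synthetic reference panel concatenates independent
simulated blocks and returns the ground-truth partition, so clustering
recovery is checkable (adjusted Rand ≥ 0.9 at the tested panel sizes).
Cohorts are generated from a panel by resampling rows with replacement,
which preserves multi-SNP LD exactly; whether the original study resampled
individuals or haplotypes is not recoverable, and row resampling is the
recorded choice.

## Phenotype simulation and calibration

Single-causal cohorts use genotype relative risks (R1 heterozygote, R2
homozygote): f₀ = K/(q² + 2pqR1 + p²R2), f₁ = R1·f₀, f₂ = R2·f₀, which
reproduces prevalence K exactly; settings with any fᵢ > 1 are rejected.
Multi-causal cohorts (k ≥ 2, identical mode across causal SNPs,
no interaction) use an **additive model on the probability scale**:
P(case|g) = clamp(b + δ·Σⱼ c(gⱼ), 0, 1), with c the mode coding.  The
probability scale makes δ directly comparable across modes (a recessive δ
must be much larger than an additive δ for equal detectability, matching
the study's published effect-size tables).  The baseline b is solved by
root finding so the mean case probability over a large generating sample
(50,000 draws) equals K; if the solution requires clamping any subject's
probability outside [0, 1], the setting is rejected as infeasible rather
than silently distorted.  Cohorts are rejection-sampled: fresh population
genotype vectors, Bernoulli status from the penetrance, accepted until both
classes hold exactly n subjects (guard at 10⁷ draws).

## Evaluation harness

`evaluate_size_power` simulates `replicates` cohorts per setting and runs
every requested method on the *same* univariate statistics per cohort, with
one shared set of null draws per correlation structure — so ADR/non-ADR and
SS-T threshold comparisons are paired and their differences are less noisy
than the individual rates.  Rejection rates carry Wilson 95% intervals.
A master seed spawns per-replicate substreams (`numpy.random.SeedSequence`),
making the full run bit-reproducible and each replicate reproducible alone.

### Canned study settings

`blocktest.experiments` freezes the study conditions used by the acceptance
checks.  The null setting (m = 20, ρ = 0.64, allele frequency 0.3,
K = 0.05, 1,000/1,000, 500 replicates, B = 1,000) is fixed by the published
size experiment.  The power grids emulate the latent-normal experiment's
design rule — effect sizes calibrated so the *average* power over all
method × ADR combinations is ≈50% — on a small grid chosen once: recessive
k = 1 at (m, ρ, p) ∈ {(10, 0.8, 0.1), (20, 0.64, 0.1), (10, 0.8, 0.05)}
with R1 = 1 and calibrated R2 ∈ {3.14, 3.40, 6.91}; additive and dominant
k = 1 counterparts (R2 = 2R1 − 1 for additive, R1 = R2 for dominant); and
recessive k = 2 with calibrated δ ∈ {0.054, 0.064}.  All block SNPs share
the causal allele frequency, mirroring the single-frequency
parameterisation of the original settings.  The published grid is far
larger (causal frequencies down to 0.01 with per-setting sample sizes);
a scaled-down grid reproduces the aggregate ADR gain/loss pattern and the
method ordering, but per-method averages (notably V-minP's and PC's gains)
need not match the full-grid averages.

### What passing tests do and do not show

The simulator produces exchangeably correlated HWE blocks with no
missingness, no genotyping error, equal allele frequencies within a block
and a homogeneous population.  Real panels have decaying LD, frequency
spectra, relatedness and stratification; passing the simulation checks
shows the statistics and their calibration are implemented correctly under
the stated model, not that the tests are robust to those realities.
Covariates, quantitative traits and related samples are out of scope.

### Null p-value calibration

For continuous block statistics (V-SS, V-minP) the Monte-Carlo p-value is
uniform under the null up to its 1/(B+1) discretisation, and a
Kolmogorov–Smirnov check on 2,000 null p-values passes.  SS-T at t > 0 has
a point mass at statistic 0 (no z² reaches the threshold), so its p-value
has an atom at 1 and is *sub-uniform*: the lower tail — the part that
matters for testing — is calibrated and conservative, but a two-sided KS
test against U(0,1) rejects by construction.  The tests assert the
calibrated-lower-tail property for SS-6 and full uniformity for V-SS and
V-minP.

## Known limitations

- SS-T p-values are bounded below by 1/(B+1); very small p-values need a
  larger B (no adaptive or importance sampling is implemented).
- The two-step polychoric estimator is biased very close to |ρ| = 1 and
  undefined for monomorphic columns (such pairs get maximal clustering
  distance).
- ADR multiplicity 3m is deliberately conservative; the three codings per
  SNP are strongly dependent.
- Multi-allelic sites are dropped at VCF ingestion; missing hard calls are
  mean-imputed and rounded, which slightly shrinks single-SNP variance at
  high missingness.
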