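# Methods

`heatgp` implements a complete genomic-prediction analysis for heat
tolerance in dairy cattle, exercised end to end on synthetic populations.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic data do and do not emulate.

## Phenotype model: reaction norms on THI

A cow's test-day yield is modelled as a linear reaction norm on the
temperature-humidity index (THI). Yield is flat below the heat-stress
threshold (THI 60), so THI is first thresholded, `max(THI, 60)`, and then
mapped to the order-1 Legendre domain: the interval [threshold, thi_max]
is rescaled affinely onto [−1, 1]. There is no single standard for the
orthogonalisation range; we expose it in the configuration and default
`thi_max` to the largest observed THI.

Trait derivation runs in two stages:

1. **Fixed-effect adjustment.** Yields are adjusted by least squares for
   herd-test-day and parity as categorical effects (sparse design,
   LSMR). National-evaluation systems additionally fit Legendre
   polynomials on age and on parity × days-in-milk; at desk scale those
   terms are deliberately omitted — the simplification is visible only
   through slightly noisier trait deviations.
2. **Random regression.** The adjusted yields follow
   `y_ij = a_i + b_i t_ij + e_ij`, with per-cow intercept/slope
   `(a_i, b_i) ~ N(0, Σ0)` and residual `e ~ N(0, σe²)`. No pedigree term
   is fitted. Because stage 1 removed the fixed effects, the model
   separates by cow into 2×2 blocks; variance components come from
   EM-REML on the per-cow sufficient statistics (relative tolerance 1e-6,
   max 500 iterations, variance floor 1e-12 of the data scale), or can be
   supplied. The BLUP solutions `(a_i, b_i)` are the intercept and slope
   **trait deviations (TD)** — the phenotypes of everything downstream.

A bull's phenotype (**DTD**) is the unweighted mean of his daughters'
TDs; his residual weight in prediction is

    w = (1 − h²) / (c·h² + (4 − h²)/p),  c = 0.2,

with `p` his daughter count and `h²` the trait's genomic heritability.
Cows with fewer than 4 records, or fewer than 2 distinct suprathreshold
THI values (slope unidentifiable), are dropped and counted in the log.

## Kinship and variance components

The genomic relationship matrix is VanRaden's first method,
`G = ZZ′ / 2Σp_j(1−p_j)` with observed allele frequencies. Genomic
heritability is estimated by average-information REML with EM fallback:
for the single-GRM model we eigendecompose `G` once, making every REML
iteration O(n); steps that would leave the parameter space or decrease
the restricted likelihood fall back to EM, and proposals are clipped at
a floor of 1e-8 of the phenotypic variance. Convergence is declared at a
relative parameter change below 1e-6. The SE of h² comes from the
inverse AI matrix by the delta method. The multi-kernel REML (two-GRM
GBLUP, weighted residuals) is the dense analogue; because EM only crawls
geometrically toward a zero-variance boundary, each iteration also
evaluates a boundary-projected candidate and keeps whichever proposal
has the highest restricted likelihood.

## GWAS and meta-analysis

`run_mlma` is the standard mixed-linear-model association: null-model
variance components are estimated once by GREML on the array-SNP GRM,
then every sequence SNP is tested by GLS with `V = Gσg² + Iσe²` held
fixed. In the eigenbasis this is a whitened OLS, vectorised over SNP
chunks; p-values use the normal approximation. The GRM contains all
array SNPs (no leave-one-chromosome-out), so proximal contamination is
accepted — the cost is a slight conservativeness at SNPs tagged by the
GRM, visible as λ marginally below 1 in calibration runs. A 0/1 breed
covariate is added for multi-breed discovery sets. SNPs with zero
variance in the tested sample are flagged and reported with `p = 1`.

The multi-trait statistic for the three slope traits is
`χ² = t′V⁻¹t` (3 df), where `t` stacks the signed single-trait
t-statistics and `V` is their correlation matrix estimated over **all**
SNPs — with a polygenic trait the genome-wide bulk is effectively null,
so no null-SNP subset is carved out. A singular `V` (collinear trait
results) is an error.

## Top-SNP selection

Selection order: significance-thresholded sliding-window election, then
LD pruning (the MAF > 0.005 filter is applied when genotypes are
loaded). Windows are 100 kb advanced by 50 kb, anchored at bp 1 of every
chromosome (the anchoring is a package convention; any fixed origin is
equally defensible and this one is reproducible). Within a window the
single most significant SNP is elected iff −log10(p) meets the threshold
(2 or 3); window ties keep the smaller bp. LD pruning mirrors the
`indep-pairwise 50 5 0.95` geometry — 50-SNP windows advancing by 5 —
iterated to a fixed point; within a violating pair we remove the SNP
with the smaller −log10(p) (tie: larger bp). Which member a particular
PLINK version removes is not documented; keeping the more significant
SNP preserves the intent of the selection and is pinned here as the
package's rule.

## Genomic prediction

**BayesR.** `y = Xβ + Wv + e`, W column-centred dosages, each SNP effect
from a four-component normal mixture with variances
`{0, 1e-4, 1e-3, 1e-2}·σv²`, residuals `N(0, σe²·diag(1/w_i))`. The
Gibbs sampler draws, per SNP, the class indicator with the effect
analytically integrated (marginal likelihood per component), then the
effect from its conditional normal; mixture proportions from
`Dirichlet(1+counts)`; σv² and σe² from scaled inverse chi-square
conditionals with flat priors (df −2; the σv² update uses the non-zero
effects and keeps its previous value when fewer than three are non-zero,
a deterministic guard at the q→0 boundary). σv² is defined on the
SNP-effect scale: class-k variance is `scalar_k · σv²`. The residual
vector is refreshed from scratch every 1000 sweeps against numerical
drift. Chains run sequentially with seeds `seed + chain` and are
bit-reproducible; the reference configuration is 5 chains of 40,000
iterations with 20,000 burn-in, and posterior summaries pool post-burn-in
samples across chains.

**BayesRC** is the same sampler with a separate mixture-proportion
vector (and Dirichlet update) per SNP annotation class — here class I =
array SNPs, class II = prioritised top SNPs. Empty classes are dropped
with a warning. With a single class it reduces exactly (bit for bit) to
BayesR.

**Identifiability at the null.** When the data carry no signal, σv²
shrinks and the small-effect components become likelihood-equivalent to
the zero component, so the mixture proportions stay prior-diffuse rather
than concentrating at the zero class. The identifiable null statement —
asserted in the tests — is that the zero class is modal and the
posterior-mean effects imply negligible genetic variance.

**GBLUP** fits one or two GRM kernels by the multi-kernel REML above on
the reference rows (weighted residual), then predicts
`ĝ = Σ_k σk² K_k[:, ref] V⁻¹(y − Xb̂)` for every individual in the
kernels. With all SNPs in one kernel this is algebraically identical to
weighted SNP-BLUP (ridge), which the tests verify.

**GBV** for validation animals are `W_val · v̄` with columns centred at
the **reference-set** allele frequencies (prediction never peeks at
validation data); fixed effects are excluded.

**Scale of bull-reference predictions.** A bull's DTD carries half his
additive merit (his transmitting ability), so SNP effects fitted on DTDs
— the bull's own genotype against his daughters' mean phenotype — are on
the half scale, and validation-cow GBVs are correspondingly
under-dispersed: the phenotype-on-GBV regression sits near 2 rather
than 1 at desk scale. No rescaling is applied; the validation metrics
report the dispersion as observed. Model-true cow-reference GBLUP (the
unbiasedness checks) is free of this and sits at 1.

## Validation

Accuracy is `r(GBV, TD) / √h²`, with h² taken from the cow GREML on
array SNPs (held in the run's variance-component table, never
re-estimated from the validation subset). Its SE is the sample SD of
the two subset accuracies divided by √2 (divisor N−1; with N = 2 the
population-SD alternative would halve it, so the convention is pinned
here). Dispersion bias is the
OLS slope of TD on GBV. The LR-method check refits GBLUP on a random
half of the reference set and regresses whole-data GBV on partial-data
GBV. Effect-direction concordance between two GWAS counts sign
agreement among SNPs significant in both at the chosen cutoff,
excluding zero effects.

## Synthetic populations

The generator produces the statistical structure the analysis assumes,
not a forward-in-time population:

- **Genotypes.** Gaussian-copula haplotypes: per chromosome a latent
  AR(1) process (neighbour correlation `exp(−d/100 kb)` by default) is
  thresholded at each SNP's frequency; ancestral frequencies
  (U(0.05, 0.95)) and the Balding-Nichols breed perturbation
  (parameterised by fst, default 0.1) are taken through the same copula
  so frequencies vary smoothly and tightly linked SNPs reach high r².
  This yields exponentially decaying LD and a mean best-tag r² of ~0.6
  between a sequence SNP and the array panel — the mechanism that lets
  array GRMs capture sequence-tier QTL. Pure-breed dosages sum two
  same-breed gametes; crossbreds take one gamete from each breed.
  Columns at or below the MAF floor are re-thresholded at fresh central
  frequencies and dropped if still failing.
- **Effects.** Every SNP draws a mixture class with configurable
  proportions (default 0.99/0.006/0.003/0.001) and an effect
  `N(0, c_k σv²)`; intercept and slope traits share QTL (pleiotropy)
  with independent effect sizes. `σv²` is solved from the target genetic
  variance via `E[var(TBV)] = Σ_j 2p_j(1−p_j) · Σ_k π_k c_k σv²` (exact
  in expectation even under LD, because effects are independent with
  mean zero).
- **Test days.** THI uniform over [40, 85] per record (the real
  herd-by-station climate merge is out of scope; only the slope
  structure matters downstream); herd-test-day effects N(0, 0.5²);
  parity offsets (0, 0.4, 0.6); residual SD 1 kg. Cow-level
  environmental intercept/slope deviations are bivariate normal with
  configurable correlation (default 0), sized so the cow-level slope
  heritability hits its target (default 0.25, in the range reported for
  heat-tolerance slopes).
- **Bulls.** Reference bulls are genotyped males; each gets a configured
  number of *non-genotyped* daughters whose genotypes are realised only
  at the QTL columns (one gamete from the sire at probability dosage/2
  per locus, one from the breed pool — recombination linkage between
  QTL transmissions is ignored, which slightly understates the variance
  of daughter averages). Daughters get their own test days, are run
  through the same reaction-norm fit, and their TDs average into DTDs.
- **Study designs.** Scenario 1 (single-breed discovery and reference),
  2 (two-breed discovery), 3 (two-breed reference); bulls siring a
  discovery cow are excluded from the reference, validation cows must
  not be reference-bull daughters, and each validation set splits into
  two near-equal subsets. All invariants are re-checked on every
  generated design.

What passing tests therefore show: the estimators recover the quantities
this generative model defines, at the configured sizes. What they do not
show: behaviour under real LD architecture, selection and pedigree
structure, imputation error, non-uniform climate exposure, or national
fixed-effect models — none of which the generator emulates.

## Default problem sizes

The package default configuration is a desk-scale study chosen so the
full pipeline (three traits, both Bayesian methods, both GBLUP variants)
completes in a few minutes: 5 chromosomes × 10 Mb, 30,000 sequence SNPs
containing 3,000 array SNPs, 2,000 discovery cows, 400 reference bulls ×
50 daughters, 400 validation cows, MCMC 2 chains × 3,000 iterations
(1,500 burn-in). The reference MCMC configuration (5 × 40,000 / 20,000)
is the `McmcConfig` dataclass default and is what a full-scale run would
use; the desk-scale chains are long enough for the posterior means the
pipeline consumes, as the oracle tests demonstrate on small instances.

## Known limitations

- Trait deviations come from a fixed-effect pre-adjustment followed by a
  cow-level mixed model, so part of each cow's signal is absorbed into
  herd-test-day means when groups are small.
- The meta-GWAS correlation matrix uses all SNPs; with strong pervasive
  signal it would over-correct.
- Multi-kernel REML reports no SE for per-kernel h² (the single-kernel
  AI-based SE is available where the pipeline needs it).
- The LD pruning tie rule and window anchoring are package conventions;
  other tools' output can differ legitimately at boundary cases.
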