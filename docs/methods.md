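# Methods

## The system being modeled

The t haplotype is a selfish variant of house-mouse chromosome 17. Two of
its properties drive everything this package computes:

1. **Drive (transmission ratio distortion).** A heterozygous (+/t) male
   transmits the t-bearing sperm to a fraction τ ≈ 0.9 of his offspring
   instead of the Mendelian 0.5. Transmission through females is Mendelian.
2. **Recessive lethality.** t/t conceptions die before birth, so t/t
   animals never appear among live-born or sampled mice.

Together these make a +/t × +/t mating *genetically incompatible*: a
fraction τ/2 of its conceptions are t/t and are lost, shrinking the litter.
The package quantifies (a) τ from litter genotype counts, (b) the
litter-size cost of incompatibility from birth counts and uterine scars,
(c) paternity bias with respect to t genotype in a monitored wild
population, and (d) the heterozygosity signature of the t-linked MHC
haplotype.

## Transmission model (`genetics`)

For sire genotype s, dam genotype d and parameters (τ, τ_dam, lethal), the
offspring genotype distribution at conception is the outer product of the
parental gamete distributions (a +/t parent transmits t with its τ; a +/+
parent never does). At birth, if lethality is on, the t/t mass is removed
and the distribution renormalized. For the +/t × +/t cross with Mendelian
dams this gives the viable +/t proportion

    E[+/t at birth] = 0.5 / (0.5 + (1 − τ)/2),

strictly increasing in τ, equal to 2/3 at τ = 0.5 and 0.9066 at τ = 0.897.
All probabilities are double precision; no rounding occurs inside the
model and the identities above hold to 1e-12 in the tests.

τ is deliberately a *per-cross* parameter rather than a single global
constant: the laboratory data the model emulates show stronger drive
through +/t sires mated to +/+ dams (0.897) than implied by the +/t × +/t
birth proportion (0.786, implying an effective τ of 0.728), i.e. the
female genetic background modifies male drive. The generator defaults
encode exactly that pair of values.

## Drive estimation (`transmission`)

The unit of analysis is the litter, represented as a binomial vector
(n_het, n_wt) of genotyped pups. The point estimate for a cross type is
the pooled proportion Σn_het/Σn — identical to the inverse-logit intercept
of an intercept-only binomial GLM, and invariant to how pups are
partitioned into litters. The 95% CI is Wald on the logit scale with a
quasi-likelihood dispersion φ estimated from the litter-level Pearson
statistic (φ = X²/(L−1), floored at 1 so underdispersed data are not
rewarded with spuriously narrow intervals). At the boundaries (pooled
proportion 0 or 1) the logit is undefined and an exact Clopper–Pearson
interval is substituted.

Cross types are compared with a litter-level binomial GLM (cross type as
factor): the overall test is the deviance χ² against the intercept-only
model, and pairwise contrasts are t statistics on the logit scale using
the quasibinomial dispersion with the residual degrees of freedom. The
exact binomial test (used for maternal transmission against 0.5) follows
the standard two-sided small-probability inclusion rule with a 1 + 1e-7
relative tie tolerance, validated against full enumeration.

`observed_vs_expected` composes the two: τ estimated from +/t × +/+
crosses fixes the lethality-adjusted expectation for +/t × +/t, and the
report flags whether that expectation falls inside the double-heterozygote
cross's confidence interval.

Simulation checks: nominal 95% CIs cover the true τ in ~95% of replicates
at τ ∈ {0.5, 0.75, 0.9} with 30 litters of ~6 pups.

## Incompatibility cost (`incompatibility`)

Post-partum uterine scars decompose implantations into live births (red
scars) and resorbed embryos (yellow scars). Three estimators:

* **Birth-litter / red-scar cost**: 1 − mean(focal)/mean(reference), where
  focal is the +/t × +/t cross and the reference swaps the focal sex's
  partner for +/+. CI: percentile bootstrap over litters (default
  B = 10,000, seeded); the bootstrap makes no normality assumption, which
  matters for small litter counts. Crosses that never conceived are
  excluded — the comparison is between litters produced.
* **Yellow-scar excess**: (mean yellow in +/t × +/t − mean yellow in all
  other crosses pooled) / overall mean implantations. Under the model this
  estimates the t/t conception fraction net of background loss, and on
  simulated data with τ = 1 and no background loss it converges to 0.5,
  the conception-stage t/t probability.
* **Fecundity**: 2 × (cross types) χ² without continuity correction on
  fecund/non-fecund counts; a degenerate table (all crosses fecund) returns
  χ² = 0, p = 1 rather than an error.

Group means of scar counts are compared with one-way ANOVA plus pooled-
variance t contrasts against the +/t × +/t group (the contrast form of a
one-way linear model; with two groups F = t² exactly, which is tested).

## Paternity bias (`paternity`)

`build_paternity_table` attaches to each pup its dam and sire genotypes and
the fraction of candidate sires that were +/t, where candidates are the
males whose detection interval intersects the half-open window
(birth − 30 d, birth]. The 30-day window is generous relative to the
~19-day gestation to absorb gaps in monitoring; the endpoint convention
(exclusive start, inclusive birth date) is a package choice since either
is defensible.

**2×2 tests** use the Yates-corrected Pearson χ²,
Σ(|O−E| − min(0.5, |O−E|))²/E with df = 1; the uncorrected statistic is
available by flag. The correction is the variant that reproduces published
statistics for this kind of sparse table.

**Virtual-pup correction.** Pups of +/t dams sired by +/t males are
undercounted because the t/t fraction m of such litters died before
sampling. The corrected count divides that single cell by (1 − m)
(equivalently, adds m/(1−m) virtual pups per observed pup); all other
cells are untouched and proportions are recomputed. The default
m = 0.403 is the red-scar estimate of prenatal loss from the laboratory
crosses. Division by (1 − m) — rather than multiplying the observed count
by (1 + m) — is the arithmetic that makes the observed and corrected
totals consistent with a loss *fraction* m, and is the form validated
against published corrected proportions in the tests. With m = 0 the
correction is the identity, and the corrected proportion is monotone
increasing in m.

**Models.** The litter-level model is binomial with response (pups +/t-
sired, pups +/+-sired) and fixed effects dam genotype, +/t male
availability, their interaction, and year; dam identity is a random
intercept fitted by maximum likelihood with 25-node Gauss–Hermite
quadrature (falling back to the fixed-effects ML fit when the variance
collapses, e.g. one litter per dam). Each term's significance is the χ²
(df 1) deviance difference between nested ML fits; for main effects
marginal to the interaction, the comparison is made between models that
both exclude the interaction, since dropping a main effect while keeping
its interaction is not a meaningful nested test. The pup-level model
treats every pup as an independent fertilization (plain logistic fit, same
terms). That independence assumption is knowingly violated when litters
share sires: on clustered simulated data the pup-level interaction test
rejects far above the nominal rate, so litter-level and pup-level results
should be read together (they agree in sign; the calibration test
therefore uses near-singleton litters, where the assumption holds in the
generator). Complete separation is detected (ML fit predicting every
response perfectly) and flagged, with weakly ridge-penalized coefficients
reported in that case.

**Multiple paternity.** Point estimate: fraction of litters with ≥ 2
assigned sires among litters of ≥ 2 pups (singletons cannot reveal a
second sire). CI: percentile bootstrap resampling litters with replacement
*within litter-size strata*, preserving the size composition that bounds
detectability — the litter-size-aware scheme used in the small-mammal
multiple-paternity literature.

## Marker statistics (`popgen`)

Allele frequencies are counts/2n. Expected heterozygosity uses the
small-sample unbiased gene diversity (2n/(2n−1))(1 − Σp²); the plain
1 − Σp² form is biased low by ~3% at n = 15 and does not reproduce
published tables at this sample size. Printed (rounded) frequency vectors
can be back-converted to integer allele counts with a consistency check,
since only count-exact frequencies reproduce three-decimal table values.

The Hardy–Weinberg test is the conditional exact test given allele counts:
the probability of a genotype array is (n!/Πg_ij!) 2^h (Πa_i!)/(2n)!, the
two-sided p sums arrays no more probable than the observed one, and
one-sided alternatives (excess/deficit) order arrays by total heterozygote
count. Full enumeration is used while a bound on the array space stays
below 10⁶; beyond that, a seeded Monte-Carlo permutation of the 2n allele
copies (default 10⁵ shuffles, p = (hits+1)/(B+1)). Monomorphic loci return
p = 1 with a flag. Enumeration and Monte-Carlo agree within Monte-Carlo
error on every small configuration tested, the enumerated probabilities
sum to 1, and the two-sided test's null rejection rate at α = 0.05 is
~0.05 at n = 50.

P-values are combined across loci with Fisher's method (χ² = −2Σln p,
df = 2k; zeros are rejected with advice to floor). Allelic differentiation
between the +/t and +/+ groups uses the Fisher-type probability test on
the 2 × k allele-count table: exact hypergeometric for 2 × 2, label-
permutation Monte-Carlo otherwise, combined across loci with Fisher's
method. Permuting allele copies treats the 2n copies within a group as
exchangeable, the standard approximation for this test.

## Synthetic data (`simulate`)

The generators emulate the study conditions, not any particular dataset:

* **Laboratory crosses** — ~30 crosses per sire×dam genotype combination;
  implantations Poisson with mean 7.58 (negative-binomial with
  configurable shape if overdispersion is wanted); each embryo's genotype
  drawn from the conception-stage transmission model; t/t embryos die
  (yellow scar), others die independently with background probability
  0.088 (= 0.67 expected yellow scars per litter over 7.58 implantations);
  survivors are red scars = litter size at birth. 79.3% of crosses are
  fecund. τ defaults: 0.897 for +/t sire × +/+ dam, 0.728 for +/t × +/t.
* **Wild population** — monthly steps; males hold staggered tenures
  (uniform entry, 4–12-month duration) so the +/t fraction among candidate
  sires varies over time; each female conceives with probability 0.25 per
  month; the sire is drawn by a preference function of dam genotype and
  current +/t male availability (default: frequency-proportional, i.e.
  random mating), with a second sire splitting the litter with probability
  0.3; pup genotypes follow the transmission model and t/t pups are deleted
  before output, while true parentage of survivors is retained.
* **Marker genotypes** — +/+ individuals drawn at Hardy–Weinberg
  proportions from per-class frequency vectors; at t-linked loci every
  +/t individual carries exactly one copy of the t-specific allele
  (enforcing its 0.5 frequency and observed heterozygosity 1.0 in that
  class), with the second allele drawn from the renormalized remainder.

Each generator consumes one `numpy` Generator seeded from its config;
identical seeds give identical outputs, and generated files carry a
provenance header (seed, config hash).

**What the generators do not emulate:** spatial/territorial structure,
infanticide, postnatal survival differences, parentage-assignment error
(the pipeline consumes truth or externally assigned parentage), linkage
between markers, or drift in female genotype frequencies. Passing tests
on these data therefore validate the estimators' arithmetic and sampling
properties, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* Dispersion floor 1 in quasibinomial CIs; Clopper–Pearson at proportion
  boundaries.
* Bootstrap and Monte-Carlo defaults: B = 10,000 resamples, 10⁵
  permutations, both seeded; percentile intervals throughout.
* GLMM: 25 Gauss–Hermite nodes, Nelder–Mead on (β, log σ) from the
  fixed-effects start; σ < 1e-4 or a likelihood below the fixed-effects
  fit collapses to the fixed-effects model, flagged.
* Exact-test tie rule: include outcomes with probability ≤ observed ×
  (1 + 1e-7).
* TT parents, empty groups, zero margins, m ≥ 1, and frequency vectors
  inconsistent with the stated sample size all raise informative errors;
  singly-sired tables where every litter is sired by one genotype return
  χ² = 0, p = 1 instead of failing on a zero margin.

## Problem sizes used in the test suite

Calibration and power checks run at the scale of the emulated study
(~30 litters per cross, ~15–30 candidate males, 14–15 individuals per
marker group) with 20–1000 replicates depending on the cost of one
replicate; the full suite completes in under a minute on one CPU.

## Known limitations

* The quasibinomial Wald CI is asymptotic; with very few litters the
  Clopper–Pearson fallback triggers only at exact boundaries, not near
  them.
* The pup-level model's independence assumption is violated by design in
  clustered litters (see above); it is reported alongside, never instead
  of, the litter-level model.
* The differentiation Monte-Carlo permutes allele copies, ignoring the
  pairing of copies within diploid individuals.
* The GLMM uses non-adaptive quadrature; with extreme random-effect
  variance and tiny groups the marginal likelihood can be imprecise, which
  is why the nested-deviance χ² (not σ̂ itself) is the reported statistic.
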