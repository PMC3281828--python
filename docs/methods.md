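# Methods

This note documents the statistical models implemented in `seqassoc`, the
defaults and why they were chosen, what the synthetic-data engine does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## The generalized score statistic

All single-variant machinery derives from one statistic over genotype
classes. Given scores X_k on classes k with case/control counts r_k, s_k
(R cases, S controls, N = R + S):

    U = (1/N) Σ_k X_k (S r_k − R s_k),
    Var0(U) = (R S / N³) [N Σ X_k² n_k − (Σ X_k n_k)²],
    T = U² / Var0.

Var0 is the permutation (hypergeometric) variance of U given the margins,
so T is asymptotically χ²₁ under the null. Choices of X recover the tests
studied: additive scores at one variant give the Cochran–Armitage trend
chi-square (T = N^O ρ², with ρ the genotype/case-indicator correlation over
the N^O individuals observed at that variant); an indicator of any minor
allele over a variant set gives a collapsing test; the total minor-allele
count gives a summing test.

Missing data are handled per variant: each variant's T uses only the
individuals with an observed genotype there, and variants monomorphic
among observed genotypes are excluded from the locus-wide summaries (the
exclusion depends only on the genotype columns, never the labels, so it is
permutation-safe). A permutation can, with missing data, leave all
observed individuals at a variant in one group; T is then set to 0, a
convention applied identically to observed and permuted label sets.

## Locus-wide tests

**BC-CA** rejects iff max T ≥ χ²₁(1 − α/v), with v the number of
polymorphic variants in the data set (recomputed per data set). A
Bonferroni-adjusted p-value min(1, v·P(χ²₁ ≥ max T)) is reported for
convenience; the decision uses the critical value.

**CA max / CA sum** estimate the permutation null of max T or Σ T by
shuffling case labels over individuals. Genotype rows — including their
missingness patterns — stay fixed, which is exactly the exchangeability
that remains valid when genotypes are missing completely at random. The
p-value is the add-one estimator p = (#{Q_t ≥ Q_obs} + 1)/(m + 1); ties
count toward the tail, so p ∈ [1/(m+1), 1]. When both summaries are
requested they share one shuffle stream (each p-value depends only on its
own statistic's null, so sharing is valid and halves the work). Per-variant
denominators and exclusion sets are label-independent and computed once;
each permutation costs two matrix-vector products.

**SKAT / C-alpha statistics.** Q_SKAT = Σ_j w_j U_j², with U_j and its
null variance computed from all available genotypes at each variant. Unit
weights give the C-alpha statistic; w_j = 1/Var0(U_j) reproduces Σ T
exactly, with or without missing data — the equivalence is asserted in the
test suite to 12 digits. A Beta(1,25)-density MAF weighting helper is
exposed but is not a default anywhere.

**CMC.** Rare variants (pooled-sample MAF ≤ 0.01 over observed genotypes,
threshold configurable) collapse to a presence indicator; common variants
enter as 0/1/2 counts. Individuals are excluded if (a) any common-variant
genotype is missing, or (b) no minor allele is observed at any rare
variant while at least one rare genotype is missing — the indicator would
then depend on unobserved values. The two rules commute, so exclusion
order is immaterial. Group means are compared with Hotelling's
T² = (R′S′/N′) d′ G d, where G is a g2 (reflexive) generalized inverse of
the pooled within-group covariance (denominator N′ − 2, the classical
two-sample form implied by the F(v, N′−v−1) reference distribution). G
comes from Goodnight's sweep algorithm: each column is swept in turn, and
a pivot below 10⁻⁸ times the largest original diagonal element marks a
numerically dependent column whose row and column are zeroed. The swept
rank v is the effective dimension; the statistic is invariant to
duplicated or reordered columns because any generalized inverse yields the
Hotelling statistic of a full-rank subset. Results with effective
denominator df N′ − v − 1 ≤ 4 are flagged invalid: near rank deficiency,
algebraically identical generalized inverses can disagree numerically, and
the F distribution's mean and variance need ddf > 2 and > 4.

**WSS.** Control-based frequency estimate q̂_j = (m_j^U + 1)/(2 n_j^U + 2)
(minor-allele count and count of controls observed at j), weight
w_j = √(n_j q̂_j (1 − q̂_j)) with n_j the number of individuals observed at
j (a flag switches n_j to controls only; the original description is
ambiguous). Individual scores sum G_ij / w_j over observed genotypes;
missing genotypes contribute 0 and are excluded from q̂. W is the case
midrank-sum. The p-value is two-sided directly from the permutation
distribution: p = (#{|W_t − W̄| ≥ |W_obs − W̄|} + 1)/(m + 1), with W̄ the
mean of W over the m permutations (no analytic mean is substituted).
Weights are recomputed inside each permutation by default, since the
controls change under shuffling; a flag freezes them at observed-data
values for comparison.

## Two-variant analytic power model

One rare risk and one rare neutral variant share MAF p; LD coefficient D
(r = D/(p(1−p))) gives haplotype frequencies (1−p)²+D, p(1−p)−D (twice),
p²+D, with D ∈ [−p², p(1−p)]. Nine genotype-class frequencies follow by
random union (HWE). Penetrance is multiplicative in the risk-variant
dosage, P(A|G) = f0 γ^{G₂}, and Bayes' rule yields case/control class
frequencies. For any score scheme, with p̄_k = (R p_k|A + S p_k|C)/N:

    E[U] = (R S / N) Σ X_k (p_k|A − p_k|C),
    Var0 = (R S / N) [Σ X² p̄ − (Σ X p̄)²],
    Var1 = (R S / N²) [S var_A(X) + R var_C(X)],

and two-sided power is Φ((−z√Var0 − E[U])/√Var1) + 1 − Φ((z√Var0 −
E[U])/√Var1), z = z_{1−α/2} — algebraically identical to the noncentral-χ²₁
tail with noncentrality E[U]²/Var1 and critical value scaled by Var0/Var1.
Both forms are computed and must agree to 10⁻¹⁰ on every call; the normal
form is returned. At γ = 1 the power equals α exactly.

The worst-case locus-wide power of BC-CA is bounded below by the level-α/2
trend-test power at the risk variant's marginal 3-class distribution; the
bound does not depend on D. The LD sweep takes 100 evenly spaced
increments of D — read as 101 grid points including both endpoints, where
boundary haplotype frequencies are exactly zero and valid; curve shapes
are insensitive to the off-by-one reading.

**Accuracy of the power approximation.** Validated against the
finite-sample test (multinomial class counts, T compared with the χ²₁
quantile): empirical size is 0.050 across the regimes checked, and in the
moderate-power regime (power ≲ 0.8, N 500–2000, MAF 0.005–0.05) analytic
and empirical power agree to well under 0.01 absolute. A known limitation:
at high power (> 0.85) with very rare variants (expected minor-allele
count 2Np below ~50), the first-order formula *underestimates* the
finite-sample rejection rate by up to ~0.02 — skewness of U under the
alternative, not a size defect. The simulation cross-checks in the test
suite therefore pin the approximation at five fixed points in the regime
where it is sharp; conclusions drawn from curves in the far upper tail
should allow for this bias.

## Synthetic-data engine

**Coalescent backends.** The default backend is msprime: standard neutral
coalescent, finite-sites recombination on the discrete 100 kb genome,
infinite-sites binary mutations at continuous positions (rescaled to
[0,1]). Defaults are n_hap = 10,000 haplotypes per population, L = 100 kb,
μ = 2.5×10⁻⁸ per nucleotide, recombination 10⁻⁸ between adjacent
nucleotides, N_e = 10,000 diploids, so θ = 4 N_e μ L = 100 and
E[S] = θ Σ_{i<n} 1/i ≈ 978.8. A self-contained no-recombination Kingman
coalescent (exponential coalescence times, Poisson mutations on branches)
serves as a hermetic cross-check; both backends satisfy the E[S] identity,
which recombination does not affect, but the internal backend has a larger
S variance, so range-type statements hold only for the msprime backend.

**What the simulations emulate, and what they do not.** Simulated
populations reproduce the rare-dominated MAF spectrum and the
predominantly small-negative pairwise LD of real resequencing data
(asserted qualitatively in the tests: median population MAF < 0.01, most
sampled r values < 0). They assume a constant-size, panmictic, neutral
population: no demographic growth or structure, no selection, no gene
conversion, no sequencing error, and biallelic variants only. Passing
tests therefore demonstrate correctness of the methods under this
idealized model, not performance on data shaped by demography or
ascertainment.

**Disease model.** P(A|G) = logistic(β0 + Σ β_j G_j), β0 = logit(f0) with
f0 = 0.05 by default. Risk variants are selected by rejection: draw a
uniformly random variant, accept if its population MAF falls in a
configured half-open class interval and it is not yet selected, until
n_risk (default 50 at full scale, ≈5% of variants) are chosen — this
samples classes in proportion to their occupancy. Selection is capped at
10⁶ draws to guard mis-specified classes. Minor-allele coding is fixed
from the population before sampling so data sets from one population are
comparable.

**Sampling and missingness.** Individuals are two haplotypes drawn with
replacement (random mating); affection is Bernoulli with the penetrance;
draws continue until exactly R cases and S controls accrue (cap 10⁷).
Missingness is a per-individual two-state Markov chain on the rescaled
[0,1] axis, starting in the observed state at 0: observed intervals ~
Exp(L(1−λ)), missing intervals ~ Exp(Lλ), giving an expected observed
fraction λ. The chain never sees genotypes or labels (MCAR) — the
condition under which label-shuffling inference stays valid after masking.

## Study orchestration

Populations are simulated once into a pool and may be reused across
replicates (recorded in provenance); disease models are assigned once per
population. A test rejects at level α iff p ≤ α; invalid results (e.g.,
CMC with ddf ≤ 4) are excluded from rejection-rate estimates and counted
separately. Rates carry exact Clopper–Pearson 95% intervals via beta
quantiles. Identical master seeds give bit-identical results; per-cell
rows stream to TSV when an output directory is given.

## Problem sizes used in the shipped checks

The test suite validates calibration and power orderings on a reduced
locus (2,000 haplotypes, 10 kb, θ = 10) with 500 null replicates (N = 500)
and 300 rare-risk replicates (N = 1,000), m = 199 permutations — the
permutation estimator is valid at any m, and these sizes keep the full
suite under a minute while leaving binomial error small relative to the
effects asserted. Full-scale quantities (segregating sites per population,
variants per 500-individual sample, CMC attrition at a 99.5% call rate)
are recomputed at the paper-scale configuration with 30 populations in
`scripts/acceptance.py` and the acceptance tests. Default m for real
analyses remains 10,000.

## Numerical conventions and degenerate inputs

* MAF ties at 0.5: allele 1 (derived) is declared minor — deterministic
  and consistent with simulator orientation.
* The missing-genotype sentinel is −9, never 0; WSS's missing→0 rule is
  applied inside its scoring only.
* Positions stay on [0,1] exactly as generated; base-pair conversion
  (floor(pos·L)) is for reporting only, since the missingness process is
  defined on the rescaled axis.
* Sweep pivot tolerance: 10⁻⁸ × the largest original diagonal element
  (scale-relative); the ddf > 4 rule is the guard against the remaining
  near-singular ambiguity.
* Monomorphic variants: excluded per data set at test time, preserved by
  I/O. Datasets where all variants are monomorphic yield invalid results
  with a reason, not exceptions, inside studies.
* VCF support is deliberately narrow: VCFv4.2, biallelic, diploid
  unphased GT; multi-allelic records are rejected. Case labels travel in
  a phenotype sidecar file. The minor allele per record is taken from the
  MA INFO key when present, else from the sample allele frequency (ties
  to ALT).

## Known limitations

* The analytic power model covers exactly two variants; the joint
  distribution of correlated single-variant statistics at a full locus is
  handled only through the BC-CA lower bound and by permutation.
* The genotype-based (unphased, HWE-assumed) LD estimator for real data
  is not implemented; simulated haplotypes are phased by construction, so
  r uses haplotype counts.
* No phasing, imputation, covariates, or population-structure correction;
  the SKAT machinery is provided at the statistic level only.
* Upper-tail bias of the asymptotic power approximation for very rare
  variants, quantified above.
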