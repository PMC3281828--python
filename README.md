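# seqassoc

Locus-wide case-control association tests for sequence data with rare
variants, together with the simulation and analytic-power machinery needed
to study them.

Sequencing a locus in cases and controls yields many biallelic variants,
most of them rare and in weak, predominantly negative linkage
disequilibrium (LD). Burden ("pooling") tests collapse or sum minor
alleles across the locus; when neutral or protective variants sit in
negative LD with risk variants, their contributions cancel in the pooled
score and the association signal is *masked*. Tests built on nonnegative
single-variant statistics do not suffer masking, because each variant
contributes only the magnitude of its own deviation from the null. This
package implements both families so they can be compared under controlled,
realistic conditions — it is aimed at statistical geneticists designing or
benchmarking rare-variant association tests.

## The statistic

For genotype classes k with scores X_k, case counts r_k, control counts
s_k, n_k = r_k + s_k, R cases, S controls, N = R + S:

    U    = (1/N) Σ_k X_k (S r_k − R s_k)
    Var0 = (R S / N³) [ N Σ_k X_k² n_k − (Σ_k X_k n_k)² ]
    T    = U² / Var0

With additive scores on one variant, T is the Cochran–Armitage trend
chi-square and equals N^O ρ², where ρ is the Pearson correlation between
minor-allele count and case status over the N^O individuals with observed
genotypes. The locus-wide tests are:

* **BC-CA** — reject iff max_j T_j ≥ χ²₁(1 − α/v), v = number of
  polymorphic variants (Bonferroni-corrected decision test);
* **CA max / CA sum** — permutation p-value of max_j T_j or Σ_j T_j from m
  case-label shuffles, p = (#{Q_t ≥ Q_obs} + 1)/(m + 1);
* **CMC** — rare variants (pooled MAF ≤ 0.01) collapsed to a presence
  indicator, joined with common-variant counts, Hotelling's T² with a g2
  generalized inverse (Goodnight sweep) and an F(v, N−v−1) p-value;
* **WSS** — rank-sum of per-individual scores Σ_j G_ij / w_j with
  w_j = √(n_j q̂_j (1 − q̂_j)), q̂_j = (m_j^U + 1)/(2 n_j^U + 2) estimated
  from controls; two-sided permutation p-value in |W − W̄|.

`Q_SKAT = Σ_j w_j U_j²` is also provided: with w_j = 1/Var0(U_j) it equals
the sum-T statistic exactly (C-alpha with unit weights).

Supporting modules simulate haplotype populations under the neutral
coalescent (msprime backend, θ = 4·N_e·μ·L), assign logistic disease
models over randomly selected risk variants, draw case-control samples by
rejection sampling, impose Markov-chain genotype missingness at a chosen
call rate, and compute the analytic power of collapsing/summing/trend
tests in a two-variant (risk + neutral) locus model across the full LD
range.

## Worked example

`python examples/two_variant_power_curve.py` sweeps LD between a rare risk
variant (MAF 0.005, relative risk 3) and a rare neutral variant at N = 500:

```
      D       r  power_collapse  power_sum  power_bcca_lb
-0.0000 -0.0050          0.2727     0.2739         0.2854
 0.0012  0.2462          0.2939     0.2985         0.2854
 0.0025  0.4975          0.3192     0.3272         0.2854
 0.0037  0.7487          0.3498     0.3574         0.2854
 0.0050  1.0000          0.3875     0.3880         0.2854
```

The BC-CA column is the worst-case power of the Bonferroni-corrected
single-variant test (a level α/2 trend test at the risk variant alone); it
does not depend on D. For r ≤ 0 — where most observed rare-variant LD
lies — it beats both pooling tests: the neutral variant only adds noise
and masking to the pooled scores. Pooling wins only under strong positive
LD, where the neutral variant effectively tags the risk variant.

`python examples/missingness_and_cmc_attrition.py` shows the other
headline effect: at a 99.5% per-bp call rate only 19 of 500 individuals
retain complete common-variant data, leaving the CMC's F test without
usable denominator degrees of freedom, and at 95% it cannot be run at all,
while the permutation tests keep using every observed genotype.

The other examples run all five tests on a simulated sample and summarize
simulated MAF/LD spectra. A thin CLI wraps the same functions:
`seqassoc assoc|power|study --help`.

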