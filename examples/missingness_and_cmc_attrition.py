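"""How randomly missing genotypes erode the CMC test's usable sample.

Draws a null-model sample of 500 individuals at the full study scale,
masks genotypes with the two-state Markov-chain missingness process at
per-bp call rates of 100%, 99.5%, and 95%, and reports how many
individuals survive the CMC completeness rules.
"""

import numpy as np

import seqassoc as sa
from seqassoc.pooling import build_cmc_vectors
from seqassoc.simulate import CoalescentConfig, DiseaseModel

rng = np.random.default_rng(11)
pop = sa.simulate_population(CoalescentConfig(), rng)
ds = sa.sample_case_control(pop, DiseaseModel.null(pop.n_variants),
                            250, 250, rng)

print(f"sample: {int(ds.polymorphic_in_sample().sum())} polymorphic variants, "
      f"{ds.n_individuals} individuals\n")
print(f"{'call rate':>9s} {'usable':>7s} {'excl. common':>13s} "
      f"{'excl. ambiguous':>16s} {'CMC result':>12s}")
for rate in (1.0, 0.995, 0.95):
    masked = ds if rate == 1.0 else sa.missingness_mask(ds, rate, rng)
    _, usable, info = build_cmc_vectors(masked)
    res = sa.cmc_test(masked)
    verdict = f"p={res.p_value:.3f}" if res.valid else res.reason
    print(f"{rate:9.3f} {int(usable.sum()):7d} {info['n_excluded_common']:13d} "
          f"{info['n_excluded_ambiguous']:16d} {verdict:>12s}")

print("\nAn individual missing any common-variant genotype, or with an")
print("ambiguous rare-variant indicator, cannot enter Hotelling's T^2.")
print("Even 0.5% missingness removes ~92% of the sample; at 5% missingness")
print("the CMC typically cannot be performed at all. Permutation tests on")
print("single-variant statistics keep using all observed genotypes.")
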