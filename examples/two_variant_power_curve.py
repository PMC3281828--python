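"""Analytic power of pooling vs single-variant tests as LD varies.

Builds the two-variant locus model (one rare risk variant, one rare
neutral variant, shared MAF) and sweeps the LD coefficient D from its
minimum -p^2 (minor alleles never together) to its maximum p(1-p)
(perfect correlation), printing power for the collapsing and summing
tests and the worst-case Bonferroni-corrected single-variant test.
"""

import seqassoc as sa

p, gamma, f0, n = 0.005, 3.0, 0.05, 500
df = sa.power_curve(p, gamma, f0, n, alpha=0.05)

print(f"MAF={p}, relative risk={gamma}, f0={f0}, N={n} balanced, alpha=0.05")
print(df.iloc[[0, 25, 50, 75, 100]].to_string(index=False,
                                              float_format="%.4f"))

neg = df[df["r"] <= 0]
frac = (neg["power_bcca_lb"] > neg[["power_collapse", "power_sum"]].max(axis=1)).mean()
print(f"\nFor r <= 0 the BC-CA lower bound beats both pooling tests at "
      f"{100*frac:.0f}% of grid points: with negative LD, a neutral variant")
print("masks the risk signal in pooled scores, while single-variant tests")
print("are unaffected. Pooling only wins when the two variants are in")
print("strong positive LD (r near 1).")
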