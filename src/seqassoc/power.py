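"""Analytic power for a two-variant locus: one rare risk, one rare neutral.

The locus carries two biallelic variants with a shared MAF p and LD
coefficient D (r = D / (p(1-p))). Haplotype frequencies are

    h[0,0] = (1-p)^2 + D,   h[0,1] = h[1,0] = p(1-p) - D,   h[1,1] = p^2 + D,

with 1 the minor allele; genotype-class frequencies over the nine
two-variant classes follow by random union of haplotypes (HWE). A
multiplicative penetrance P(A | G_k) = f0 * gamma^{G_2k} acts through the
risk variant (variant 2) only; case/control-conditional class frequencies
come from Bayes' rule.

For any score scheme X over the classes, first and second moments of the
score statistic U under the null and the alternative give the asymptotic
two-sided power of the trend-type test T = U^2 / Var0 at level alpha —
evaluated both in a normal form and as a noncentral chi-square(1) tail,
which agree algebraically. The worst-case (lower-bound) power of the
Bonferroni-corrected single-variant max-T test (BC-CA) over this locus is
the power of the level alpha/2 additive trend test at the risk variant
alone; it does not depend on D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoVariantModel",
    "build_two_variant_model",
    "marginal_risk_variant_model",
    "score_scheme_moments",
    "asymptotic_power",
    "power_curve",
    "monte_carlo_power",
]

#: The nine two-variant genotype classes [G_1k, G_2k], g in {0,1,2} each.
GENOTYPE_CLASSES: np.ndarray = np.array(
    [[g1, g2] for g1 in range(3) for g2 in range(3)], dtype=int
)


@dataclass
class TwoVariantModel:
    """Two-variant locus model with conditional genotype frequencies.

    ``p_classes``, ``p_case`` and ``p_control`` are the population,
    case-conditional and control-conditional frequencies of the nine
    genotype classes in :data:`GENOTYPE_CLASSES` order; ``prevalence`` is
    the marginal disease probability P(A).
    """

    p: float
    d: float
    gamma: float
    f0: float
    haplotype_freqs: np.ndarray = field(repr=False)
    p_classes: np.ndarray = field(repr=False)
    p_case: np.ndarray = field(repr=False)
    p_control: np.ndarray = field(repr=False)
    prevalence: float = 0.0

    @property
    def r(self) -> float:
        """LD correlation r = D / (p(1-p)) (equal MAFs)."""
        return self.d / (self.p * (1.0 - self.p))

    @property
    def genotype_classes(self) -> np.ndarray:
        return GENOTYPE_CLASSES


def d_bounds(p: float) -> tuple[float, float]:
    """Admissible LD range [-p^2, p(1-p)] for two variants of equal MAF p."""
    return -p * p, p * (1.0 - p)


def build_two_variant_model(
    p: float, d: float, gamma: float, f0: float
) -> TwoVariantModel:
    """Construct the model and its case/control class frequencies.

    Raises
    ------
    ValueError
        If D is outside [-p^2, p(1-p)] or the maximum penetrance
        f0 * gamma^2 exceeds 1.
    """
    if not 0 < p <= 0.5:
        raise ValueError("p must be in (0, 0.5]")
    lo, hi = d_bounds(p)
    if d < lo - 1e-12 or d > hi + 1e-12:
        raise ValueError(f"D = {d} outside [{lo}, {hi}]")
    if f0 * gamma**2 > 1 + 1e-12:
        raise ValueError("penetrance f0 * gamma^2 exceeds 1")

    h = np.empty((2, 2))
    h[0, 0] = (1 - p) ** 2 + d
    h[0, 1] = h[1, 0] = p * (1 - p) - d
    h[1, 1] = p * p + d
    h = np.clip(h, 0.0, 1.0)  # boundary D: exact zeros, no negatives

    # genotype class frequencies by random union of two haplotypes
    p_classes = np.zeros(9)
    haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for a1, a2 in haps:
        for b1, b2 in haps:
            k = (a1 + b1) * 3 + (a2 + b2)
            p_classes[k] += h[a1, a2] * h[b1, b2]

    pen = f0 * gamma ** GENOTYPE_CLASSES[:, 1].astype(float)
    prevalence = float(np.sum(p_classes * pen))
    p_case = p_classes * pen / prevalence
    p_control = p_classes * (1.0 - pen) / (1.0 - prevalence)
    return TwoVariantModel(
        p=p, d=d, gamma=gamma, f0=f0, haplotype_freqs=h,
        p_classes=p_classes, p_case=p_case, p_control=p_control,
        prevalence=prevalence,
    )


def marginal_risk_variant_model(
    p: float, gamma: float, f0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Marginal 3-class genotype distribution at the risk variant alone.

    Returns (population, case-conditional, control-conditional)
    frequencies for genotypes 0/1/2 under HWE and penetrance f0 gamma^g.
    """
    q = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    pen = f0 * gamma ** np.arange(3.0)
    prev = float(np.sum(q * pen))
    return q, q * pen / prev, q * (1 - pen) / (1 - prev)


def score_scheme_moments(
    p_case: np.ndarray,
    p_control: np.ndarray,
    scores: np.ndarray,
    n: int,
    r: int | None = None,
) -> tuple[float, float, float]:
    """(E[U], Var0(U), Var1(U)) for a score scheme and sampling design.

    With pbar_k = (R p_k|A + S p_k|C) / N:

        E[U]    = (R S / N)   * sum_k X_k (p_k|A - p_k|C)
        Var0(U) = (R S / N)   * [sum X^2 pbar - (sum X pbar)^2]
        Var1(U) = (R S / N^2) * [S var_A(X) + R var_C(X)]
    """
    x = np.asarray(scores, dtype=float)
    pa = np.asarray(p_case, dtype=float)
    pc = np.asarray(p_control, dtype=float)
    r = n // 2 if r is None else r
    s = n - r
    pbar = (r * pa + s * pc) / n
    e_u = r * s / n * float(np.sum(x * (pa - pc)))
    var0 = r * s / n * float(np.sum(x**2 * pbar) - np.sum(x * pbar) ** 2)
    var_a = float(np.sum(x**2 * pa) - np.sum(x * pa) ** 2)
    var_c = float(np.sum(x**2 * pc) - np.sum(x * pc) ** 2)
    var1 = r * s / n**2 * (s * var_a + r * var_c)
    return e_u, var0, var1


def asymptotic_power(
    e_u: float, var0: float, var1: float, alpha: float = 0.05
) -> float:
    """Asymptotic power of the two-sided test T = U^2 / Var0 at level alpha.

    Computed in the normal form

        Phi((-z sqrt(Var0) - E[U]) / sqrt(Var1))
        + 1 - Phi((z sqrt(Var0) - E[U]) / sqrt(Var1)),  z = z_{1-alpha/2},

    and cross-checked against the noncentral chi-square(1) tail with
    noncentrality E[U]^2 / Var1 and critical value scaled by Var0 / Var1;
    the two forms must agree to 1e-10.
    """
    if var0 <= 0 or var1 <= 0:
        raise ValueError("degenerate score scheme: zero variance")
    z = stats.norm.ppf(1 - alpha / 2)
    s0, s1 = np.sqrt(var0), np.sqrt(var1)
    power_normal = stats.norm.cdf((-z * s0 - e_u) / s1) + stats.norm.sf(
        (z * s0 - e_u) / s1
    )
    crit = stats.chi2.ppf(1 - alpha, df=1)
    power_ncx2 = stats.ncx2.sf(crit * var0 / var1, df=1, nc=e_u**2 / var1)
    if abs(power_normal - power_ncx2) > 1e-10:
        raise AssertionError(
            "normal and noncentral chi-square power forms disagree: "
            f"{power_normal} vs {power_ncx2}"
        )
    return float(power_normal)


def _scheme_power(
    model: TwoVariantModel, scores: np.ndarray, n: int, r: int, alpha: float
) -> float:
    e_u, var0, var1 = score_scheme_moments(
        model.p_case, model.p_control, scores, n, r
    )
    return asymptotic_power(e_u, var0, var1, alpha)


def bc_ca_lower_bound_power(
    p: float, gamma: float, f0: float, n: int, r: int | None = None,
    alpha: float = 0.05, n_variants: int = 2,
) -> float:
    """Worst-case BC-CA power: level alpha/v additive trend test at the
    risk variant alone (v = 2 variants at the locus). Independent of D."""
    q, qa, qc = marginal_risk_variant_model(p, gamma, f0)
    x = np.arange(3.0)
    r = n // 2 if r is None else r
    e_u, var0, var1 = score_scheme_moments(qa, qc, x, n, r)
    return asymptotic_power(e_u, var0, var1, alpha / n_variants)


def power_curve(
    p: float,
    gamma: float,
    f0: float,
    n: int,
    case_fraction: float = 0.5,
    alpha: float = 0.05,
    n_grid: int = 101,
) -> pd.DataFrame:
    """Power of collapse/sum schemes and the BC-CA lower bound over LD.

    The grid takes 100 evenly spaced increments of D (``n_grid`` = 101
    points including both endpoints) from D_min = -p^2 to
    D_max = p(1-p). Columns: D, r, power_collapse, power_sum,
    power_bcca_lb.
    """
    r_cases = int(round(n * case_fraction))
    lo, hi = d_bounds(p)
    d_grid = np.linspace(lo, hi, n_grid)
    collapse_x = (GENOTYPE_CLASSES.sum(axis=1) > 0).astype(float)
    sum_x = GENOTYPE_CLASSES.sum(axis=1).astype(float)
    bcca_lb = bc_ca_lower_bound_power(p, gamma, f0, n, r_cases, alpha)
    rows = []
    for d in d_grid:
        model = build_two_variant_model(p, d, gamma, f0)
        rows.append(
            {
                "D": d,
                "r": model.r,
                "power_collapse": _scheme_power(model, collapse_x, n, r_cases, alpha),
                "power_sum": _scheme_power(model, sum_x, n, r_cases, alpha),
                "power_bcca_lb": bcca_lb,
            }
        )
    return pd.DataFrame(rows)


def monte_carlo_power(
    p_case: np.ndarray,
    p_control: np.ndarray,
    scores: np.ndarray,
    n: int,
    r: int | None = None,
    alpha: float = 0.05,
    n_reps: int = 20_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical rejection rate of the finite-sample test T >= chi2_1
    quantile, drawing multinomial case/control class counts per replicate.

    Serves as the simulation cross-check for :func:`asymptotic_power`;
    replicates where the scores are constant on occupied classes count as
    non-rejections.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(scores, dtype=float)
    r = n // 2 if r is None else r
    s = n - r
    rk = rng.multinomial(r, p_case, size=n_reps).astype(float)
    sk = rng.multinomial(s, p_control, size=n_reps).astype(float)
    nk = rk + sk
    u = (x * (s * rk - r * sk)).sum(axis=1) / n
    var0 = r * s / n**3 * (n * (x**2 * nk).sum(axis=1) - (x * nk).sum(axis=1) ** 2)
    crit = stats.chi2.ppf(1 - alpha, df=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var0 > 0, u**2 / var0, 0.0)
    return float(np.mean(t >= crit))
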