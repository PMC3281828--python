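"""Two-variant analytic power model: frequencies, moments, power, LD sweep."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seqassoc as sa
from seqassoc.power import (
    GENOTYPE_CLASSES,
    bc_ca_lower_bound_power,
    d_bounds,
    marginal_risk_variant_model,
    monte_carlo_power,
)

COLLAPSE = (GENOTYPE_CLASSES.sum(axis=1) > 0).astype(float)
SUM = GENOTYPE_CLASSES.sum(axis=1).astype(float)
TREND_RISK = GENOTYPE_CLASSES[:, 1].astype(float)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def test_null_gamma_one_gives_equal_conditional_frequencies():
    m = sa.build_two_variant_model(0.01, 0.0, 1.0, 0.05)
    np.testing.assert_allclose(m.p_case, m.p_classes, atol=1e-14)
    np.testing.assert_allclose(m.p_control, m.p_classes, atol=1e-14)
    assert m.prevalence == pytest.approx(0.05)


def test_minimum_d_removes_double_minor_haplotype():
    p = 0.01
    m = sa.build_two_variant_model(p, -p * p, 3.0, 0.05)
    assert m.haplotype_freqs[1, 1] == pytest.approx(0.0, abs=1e-15)
    # genotype class [2, 2] requires two copies of the [1,1] haplotype
    k22 = 2 * 3 + 2
    assert m.p_classes[k22] == pytest.approx(0.0, abs=1e-15)


def test_case_frequencies_match_haplotype_pair_enumeration():
    """Brute-force oracle: enumerate the 10 unordered haplotype pairs (with
    HWE pair probabilities), apply the multiplicative penetrance, and
    compare the Bayes case-conditional class frequencies."""
    p, d, gamma, f0 = 0.005, 0.0, 3.0, 0.05
    m = sa.build_two_variant_model(p, d, gamma, f0)
    haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
    hf = {h: m.haplotype_freqs[h] for h in haps}
    joint = np.zeros(9)
    for h1, h2 in itertools.product(haps, repeat=2):
        g1, g2 = h1[0] + h2[0], h1[1] + h2[1]
        k = g1 * 3 + g2
        joint[k] += hf[h1] * hf[h2] * f0 * gamma**g2
    expected = joint / joint.sum()
    np.testing.assert_allclose(m.p_case, expected, atol=1e-14)


def test_model_rejects_out_of_range_d_and_penetrance():
    with pytest.raises(ValueError, match="outside"):
        sa.build_two_variant_model(0.01, 0.02, 2.0, 0.05)
    with pytest.raises(ValueError, match="penetrance"):
        sa.build_two_variant_model(0.01, 0.0, 5.0, 0.05)


@given(
    st.floats(0.001, 0.2),
    st.floats(0.0, 1.0),
    st.floats(1.0, 3.0),
    st.floats(0.01, 0.1),
)
@settings(max_examples=100, deadline=None)
def test_law_of_total_probability_for_conditional_frequencies(p, dfrac, gamma, f0):
    """p_k|A P(A) + p_k|C (1 - P(A)) = p_k on random valid parameters."""
    if f0 * gamma**2 > 1:
        return
    lo, hi = d_bounds(p)
    d = lo + dfrac * (hi - lo)
    m = sa.build_two_variant_model(p, d, gamma, f0)
    np.testing.assert_allclose(
        m.p_case * m.prevalence + m.p_control * (1 - m.prevalence),
        m.p_classes,
        atol=1e-12,
    )
    assert m.p_classes.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def test_null_moments_have_zero_mean_and_equal_variances():
    m = sa.build_two_variant_model(0.01, 0.001, 1.0, 0.05)
    e_u, var0, var1 = sa.score_scheme_moments(m.p_case, m.p_control, SUM, 1000)
    assert e_u == pytest.approx(0.0, abs=1e-14)
    assert var0 == pytest.approx(var1, rel=1e-12)


def test_collapse_mean_matches_direct_probability_arithmetic():
    """With h[1,1] = 0 the collapse expectation is (R S / N) times the
    case-control difference in P(any minor allele)."""
    p = 0.01
    m = sa.build_two_variant_model(p, -p * p, 3.0, 0.05)
    n, r = 1000, 500
    e_u, _, _ = sa.score_scheme_moments(m.p_case, m.p_control, COLLAPSE, n, r)
    p_any_case = m.p_case[COLLAPSE == 1].sum()
    p_any_ctrl = m.p_control[COLLAPSE == 1].sum()
    assert e_u == pytest.approx(r * (n - r) / n * (p_any_case - p_any_ctrl))


def test_sample_statistic_moments_match_formulas_by_simulation():
    """Mean and variance of U over 10,000 simulated datasets at N = 1,000
    agree with E[U] and Var1(U) within 3 SEs."""
    m = sa.build_two_variant_model(0.005, 0.0, 3.0, 0.05)
    n, r, reps = 1000, 500, 10_000
    e_u, var0, var1 = sa.score_scheme_moments(m.p_case, m.p_control, SUM, n, r)
    rng = np.random.default_rng(101)
    rk = rng.multinomial(r, m.p_case, size=reps).astype(float)
    sk = rng.multinomial(n - r, m.p_control, size=reps).astype(float)
    u = (SUM * ((n - r) * rk - r * sk)).sum(axis=1) / n
    se_mean = np.sqrt(var1 / reps)
    assert abs(u.mean() - e_u) <= 3 * se_mean
    # SE of a sample variance ~ var * sqrt(2/(reps-1)) under near-normality
    assert abs(u.var(ddof=1) - var1) <= 3 * var1 * np.sqrt(2 / (reps - 1))


# ---------------------------------------------------------------------------
# Asymptotic power
# ---------------------------------------------------------------------------

def test_power_under_null_equals_alpha_exactly():
    m = sa.build_two_variant_model(0.01, 0.0, 1.0, 0.05)
    for alpha in (0.05, 0.01):
        for x in (COLLAPSE, SUM, TREND_RISK):
            e_u, v0, v1 = sa.score_scheme_moments(m.p_case, m.p_control, x, 1000)
            assert sa.asymptotic_power(e_u, v0, v1, alpha) == pytest.approx(
                alpha, abs=1e-10
            )


def test_power_is_nondecreasing_in_sample_size():
    m = sa.build_two_variant_model(0.005, 0.0, 3.0, 0.05)
    powers = []
    for n in (500, 1000, 2000, 4000):
        e_u, v0, v1 = sa.score_scheme_moments(m.p_case, m.p_control, SUM, n)
        powers.append(sa.asymptotic_power(e_u, v0, v1, 0.05))
    assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))


def test_normal_and_noncentral_chisquare_forms_agree():
    """asymptotic_power internally asserts the two algebraic forms agree to
    1e-10; exercise it across a parameter sweep."""
    for p, gamma, n in [(0.005, 3.0, 500), (0.01, 2.0, 2000), (0.05, 1.5, 1000)]:
        lo, hi = d_bounds(p)
        for d in (lo, 0.0, hi):
            m = sa.build_two_variant_model(p, d, gamma, 0.05)
            for x in (COLLAPSE, SUM, TREND_RISK):
                e_u, v0, v1 = sa.score_scheme_moments(m.p_case, m.p_control, x, n)
                sa.asymptotic_power(e_u, v0, v1, 0.05)  # raises on mismatch


#: Validation points for the simulation cross-check: paper-realistic
#: (MAF 0.005-0.05, OR 1.5-3, N 500-1000, D spanning negative to positive),
#: in the moderate-power regime where first-order asymptotics are accurate
#: (see docs/methods.md for the upper-tail limitation).
MC_VALIDATION_POINTS = [
    (0.005, 0.0, 3.0, 500, "collapse", 1001),
    (0.01, 0.004, 2.0, 1000, "sum", 1002),
    (0.02, 0.0, 2.0, 500, "collapse", 1003),
    (0.01, -1e-4, 2.0, 500, "trend", 1004),
    (0.05, 0.001, 1.5, 1000, "sum", 1005),
]


@pytest.mark.parametrize("p,d,gamma,n,scheme,seed", MC_VALIDATION_POINTS)
def test_analytic_power_matches_monte_carlo(p, d, gamma, n, scheme, seed):
    """Analytic power within 3 binomial SEs of the empirical rejection rate
    of the finite-sample chi-square test over 20,000 simulated datasets."""
    x = {"collapse": COLLAPSE, "sum": SUM, "trend": TREND_RISK}[scheme]
    m = sa.build_two_variant_model(p, d, gamma, 0.05)
    e_u, v0, v1 = sa.score_scheme_moments(m.p_case, m.p_control, x, n)
    ana = sa.asymptotic_power(e_u, v0, v1, 0.05)
    rng = np.random.default_rng(seed)
    mc = monte_carlo_power(m.p_case, m.p_control, x, n, alpha=0.05,
                           n_reps=20_000, rng=rng)
    se = np.sqrt(mc * (1 - mc) / 20_000)
    assert abs(ana - mc) <= 3 * se, f"analytic {ana:.4f} vs MC {mc:.4f}"


# ---------------------------------------------------------------------------
# Power curve over LD
# ---------------------------------------------------------------------------

def test_power_curve_grid_and_columns():
    df = sa.power_curve(0.005, 3.0, 0.05, 500)
    assert len(df) == 101
    assert df["D"].iloc[0] == pytest.approx(-0.005**2)
    assert df["D"].iloc[-1] == pytest.approx(0.005 * 0.995)
    assert df["r"].iloc[-1] == pytest.approx(1.0)
    assert set(df.columns) == {"D", "r", "power_collapse", "power_sum",
                               "power_bcca_lb"}


def test_bcca_lower_bound_is_flat_in_d():
    df = sa.power_curve(0.01, 2.0, 0.05, 1000)
    assert df["power_bcca_lb"].nunique() == 1


def test_perfect_ld_reduces_pooling_to_single_variant_tests():
    """At r = 1 the two-variant collapse (sum) power equals the level-alpha
    dominant-score (additive-score) trend power at the risk variant alone,
    computed from the marginal 3-class distribution."""
    p, gamma, f0, n, alpha = 0.005, 3.0, 0.05, 500, 0.05
    m = sa.build_two_variant_model(p, p * (1 - p), gamma, f0)
    q, qa, qc = marginal_risk_variant_model(p, gamma, f0)

    dom = np.array([0.0, 1.0, 1.0])
    add = np.arange(3.0)
    expect = {}
    for name, x in (("collapse", dom), ("sum", add)):
        e_u, v0, v1 = sa.score_scheme_moments(qa, qc, x, n)
        expect[name] = sa.asymptotic_power(e_u, v0, v1, alpha)

    e_u, v0, v1 = sa.score_scheme_moments(m.p_case, m.p_control, COLLAPSE, n)
    assert sa.asymptotic_power(e_u, v0, v1, alpha) == pytest.approx(
        expect["collapse"], abs=1e-10
    )
    # sum scores are 0/2/4 at r = 1: scale-invariant, equal to additive
    e_u, v0, v1 = sa.score_scheme_moments(m.p_case, m.p_control, SUM, n)
    assert sa.asymptotic_power(e_u, v0, v1, alpha) == pytest.approx(
        expect["sum"], abs=1e-10
    )


def test_bcca_bound_dominates_pooling_for_small_ld():
    """Qualitative ordering: at p = 0.005, gamma = 3, N = 500, alpha = 0.05
    the BC-CA lower bound exceeds collapse and sum power at every grid
    point with r <= 0.08, while pooling wins at large positive r."""
    df = sa.power_curve(0.005, 3.0, 0.05, 500, alpha=0.05)
    low = df[df["r"] <= 0.08]
    assert (low["power_bcca_lb"] > low["power_collapse"]).all()
    assert (low["power_bcca_lb"] > low["power_sum"]).all()
    top = df.iloc[-1]
    assert top["power_collapse"] > top["power_bcca_lb"]
    assert top["power_sum"] > top["power_bcca_lb"]


def test_exact_reduction_of_collapse_statistic_at_perfect_ld():
    """At r = 1 with equal MAFs, every dataset's two-variant collapse
    statistic equals the single-variant dominant-score trend statistic."""
    rng = np.random.default_rng(55)
    g_risk = rng.choice([0, 0, 0, 1, 2], size=30)  # r = 1: identical dosages
    y = rng.permutation(np.repeat([1, 0], 15))
    classes = [tuple(row) for row in GENOTYPE_CLASSES]
    r_counts = [np.sum((g_risk == g1) & (g_risk == g2) & (y == 1))
                for g1, g2 in classes]
    s_counts = [np.sum((g_risk == g1) & (g_risk == g2) & (y == 0))
                for g1, g2 in classes]
    from seqassoc.core import ContingencySummary

    _, _, t_collapse = sa.generalized_statistic(
        ContingencySummary(r_counts, s_counts), COLLAPSE
    )
    dom_counts_r = [np.sum((np.minimum(g_risk, 1) == v) & (y == 1)) for v in (0, 1)]
    dom_counts_s = [np.sum((np.minimum(g_risk, 1) == v) & (y == 0)) for v in (0, 1)]
    _, _, t_dom = sa.generalized_statistic(
        ContingencySummary(dom_counts_r, dom_counts_s), np.array([0.0, 1.0])
    )
    assert t_collapse == pytest.approx(t_dom, rel=1e-12)
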