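"""Trend-statistic machinery and locus-wide tests built on it.

The building block is a generalized score statistic over genotype classes:
with scores ``X_k``, case/control class counts ``r_k``/``s_k``,
``n_k = r_k + s_k``, ``N = R + S``,

    U    = (1/N) * sum_k X_k (S r_k - R s_k)
    Var0 = (R S / N^3) * [N sum_k X_k^2 n_k - (sum_k X_k n_k)^2]
    T    = U^2 / Var0

For additive scores on one variant, T is the classical Cochran-Armitage
trend chi-square and equals ``N * rho^2`` with rho the Pearson correlation
between minor-allele count and case indicator.

Locus-wide inference uses the per-variant T values: BC-CA compares max T
with a Bonferroni-corrected chi-square(1) quantile; CA max / CA sum compare
the max or sum against its permutation null from case-label shuffles; and
the SKAT statistic sum_j w_j U_j^2 reduces to sum T with inverse-null-
variance weights (C-alpha with unit weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import MISSING, ContingencySummary, GenotypeDataset
from .results import PermutationNull, TestResult

__all__ = [
    "generalized_statistic",
    "trend_scan",
    "TrendScan",
    "bc_ca_test",
    "permutation_test",
    "permutation_tests",
    "skat_statistic",
    "weights_inverse_null_variance",
    "weights_beta_maf",
    "trend_scores",
    "collapse_scores",
    "sum_scores",
]


# ---------------------------------------------------------------------------
# Score schemes over multi-variant genotype classes
# ---------------------------------------------------------------------------

def trend_scores(genotype_classes: np.ndarray, variant: int) -> np.ndarray:
    """Additive single-variant scores: X_k = G_{jk} in {0, 1, 2}."""
    return np.asarray(genotype_classes, dtype=float)[:, variant]


def collapse_scores(genotype_classes: np.ndarray, variants=None) -> np.ndarray:
    """Collapsing scores: X_k = 1 if any minor allele among ``variants``."""
    g = np.asarray(genotype_classes, dtype=float)
    if variants is not None:
        g = g[:, list(variants)]
    return (g.sum(axis=1) > 0).astype(float)


def sum_scores(genotype_classes: np.ndarray) -> np.ndarray:
    """Summing scores: X_k = sum_j G_{jk}."""
    return np.asarray(genotype_classes, dtype=float).sum(axis=1)


def generalized_statistic(
    summary: ContingencySummary, scores: np.ndarray
) -> tuple[float, float, float]:
    """Compute (U, Var0, T) for arbitrary genotype-class scores.

    Raises
    ------
    ValueError
        If the scores are constant on the occupied classes (Var0 = 0,
        statistic undefined).
    """
    x = np.asarray(scores, dtype=float)
    r, s = summary.r_counts, summary.s_counts
    if x.shape != r.shape:
        raise ValueError("scores must align with genotype classes")
    n = r + s
    big_r, big_s = r.sum(), s.sum()
    big_n = big_r + big_s
    u = float(np.sum(x * (big_s * r - big_r * s)) / big_n)
    var0 = float(
        big_r * big_s / big_n**3 * (big_n * np.sum(x**2 * n) - np.sum(x * n) ** 2)
    )
    if var0 <= 0:
        raise ValueError("scores constant on occupied classes: T undefined")
    return u, var0, u**2 / var0


# ---------------------------------------------------------------------------
# Vectorized per-variant scan (shared by observed data and permutations)
# ---------------------------------------------------------------------------

@dataclass
class _ScanPrep:
    """Label-independent per-variant quantities for fast rescans."""

    g0: np.ndarray        # genotypes with missing -> 0, float (N, v_kept)
    obs: np.ndarray       # observed mask, float (N, v_kept)
    n_obs: np.ndarray     # individuals observed per variant
    sum_g: np.ndarray     # sum of genotypes over observed individuals
    ss_term: np.ndarray   # N^O * sum g^2 - (sum g)^2  (>0 iff polymorphic)
    kept: np.ndarray      # indices of kept variants in the original dataset


def _prepare_scan(ds: GenotypeDataset) -> _ScanPrep:
    obs = ds.genotypes != MISSING
    g0 = np.where(obs, ds.genotypes, 0).astype(float)
    n_obs = obs.sum(axis=0).astype(float)
    sum_g = g0.sum(axis=0)
    sum_g2 = (g0**2).sum(axis=0)
    ss = n_obs * sum_g2 - sum_g**2
    # Monomorphic among observed genotypes (ss == 0) are excluded from the
    # scan; this set depends only on the genotype columns, never the labels.
    kept = np.flatnonzero((n_obs > 0) & (ss > 0))
    return _ScanPrep(
        g0=g0[:, kept],
        obs=obs[:, kept].astype(float),
        n_obs=n_obs[kept],
        sum_g=sum_g[kept],
        ss_term=ss[kept],
        kept=kept,
    )


def _scan_T(prep: _ScanPrep, labels: np.ndarray) -> np.ndarray:
    """T values for each row of a (n_label_sets, N) 0/1 label matrix.

    A permutation can leave all observed individuals at a variant in one
    group (possible only with missing data); T is set to 0 there, a
    convention applied identically to observed and permuted label sets.
    """
    y = np.atleast_2d(labels).astype(float)
    r_j = y @ prep.obs                      # cases observed at each variant
    a_j = y @ prep.g0                       # case genotype sums
    s_j = prep.n_obs[None, :] - r_j
    b_j = prep.sum_g[None, :] - a_j
    u = (s_j * a_j - r_j * b_j) / prep.n_obs[None, :]
    var0 = r_j * s_j / prep.n_obs[None, :] ** 3 * prep.ss_term[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var0 > 0, u**2 / var0, 0.0)
    return t


def _scan_U_var0(prep: _ScanPrep, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.atleast_2d(labels).astype(float)
    r_j = y @ prep.obs
    a_j = y @ prep.g0
    s_j = prep.n_obs[None, :] - r_j
    b_j = prep.sum_g[None, :] - a_j
    u = (s_j * a_j - r_j * b_j) / prep.n_obs[None, :]
    var0 = r_j * s_j / prep.n_obs[None, :] ** 3 * prep.ss_term[None, :]
    return u, var0


@dataclass
class TrendScan:
    """Per-variant Cochran-Armitage trend chi-squares T = N^O rho^2.

    Each variant's T uses only the individuals observed at that variant;
    variants monomorphic among observed genotypes are excluded
    (``variant_index`` maps back to dataset columns).
    """

    T: np.ndarray
    variant_index: np.ndarray
    n_obs: np.ndarray
    n_variants_total: int

    @property
    def n_variants(self) -> int:
        return len(self.T)

    def max_T(self) -> float:
        return float(self.T.max())

    def sum_T(self) -> float:
        return float(self.T.sum())


def trend_scan(ds: GenotypeDataset) -> TrendScan:
    """Single-variant trend scan over all polymorphic observed variants."""
    prep = _prepare_scan(ds)
    t = _scan_T(prep, ds.case_label)[0]
    return TrendScan(
        T=t,
        variant_index=prep.kept,
        n_obs=prep.n_obs.astype(int),
        n_variants_total=ds.n_variants,
    )


# ---------------------------------------------------------------------------
# Locus-wide tests
# ---------------------------------------------------------------------------

def bc_ca_test(
    data: GenotypeDataset | TrendScan, alpha: float = 0.05
) -> TestResult:
    """Bonferroni-corrected max-T decision test (BC-CA).

    Rejects iff max T >= the chi-square(1) quantile at 1 - alpha/v, where v
    is the number of polymorphic variants in the data set. The Bonferroni-
    adjusted p-value min(1, v P(chi2_1 >= max T)) is reported for
    convenience; the decision is taken on the critical value.
    """
    scan = data if isinstance(data, TrendScan) else trend_scan(data)
    v = scan.n_variants
    if v == 0:
        return TestResult("bcca", np.nan, None, 0, valid=False,
                          reason="no polymorphic variants")
    max_t = scan.max_T()
    crit = stats.chi2.ppf(1 - alpha / v, df=1)
    p_adj = min(1.0, v * stats.chi2.sf(max_t, df=1))
    return TestResult(
        "bcca", max_t, p_adj, v,
        extras={"critical_value": float(crit), "reject": bool(max_t >= crit),
                "alpha": alpha},
    )


def permutation_tests(
    ds: GenotypeDataset,
    summaries: tuple[str, ...] = ("max", "sum"),
    m: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, TestResult]:
    """CA max / CA sum permutation tests sharing one shuffle stream.

    For each of ``m`` random case-label shuffles the full trend scan is
    recomputed (per-variant missingness handled within each permuted data
    set) and the requested summaries recorded. The p-value is the add-one
    permutation estimate p = (#{Q_t >= Q_obs} + 1) / (m + 1); ties count
    toward the tail.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if ds.n_cases == 0 or ds.n_controls == 0:
        raise ValueError("both cases and controls required")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    prep = _prepare_scan(ds)
    if prep.kept.size == 0:
        return {
            s: TestResult(f"ca{s}", np.nan, None, 0, m=m, valid=False,
                          reason="no polymorphic variants")
            for s in summaries
        }
    labels = np.empty((m + 1, ds.n_individuals), dtype=np.int8)
    labels[0] = ds.case_label
    for t in range(1, m + 1):
        labels[t] = rng.permutation(ds.case_label)
    t_mat = _scan_T(prep, labels)
    out: dict[str, TestResult] = {}
    for s in summaries:
        if s == "max":
            q = t_mat.max(axis=1)
        elif s == "sum":
            q = t_mat.sum(axis=1)
        else:
            raise ValueError(f"unknown summary: {s!r}")
        q_obs, q_null = q[0], q[1:]
        p = (np.sum(q_null >= q_obs) + 1) / (m + 1)
        out[s] = TestResult(
            f"ca{s}", float(q_obs), float(p), int(prep.kept.size), m=m,
            permutation_null=PermutationNull(q_null),
        )
    return out


def permutation_test(
    ds: GenotypeDataset,
    summary: str = "max",
    m: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> TestResult:
    """Single-summary wrapper around :func:`permutation_tests`."""
    return permutation_tests(ds, (summary,), m=m, seed=seed)[summary]


# ---------------------------------------------------------------------------
# SKAT / C-alpha statistic
# ---------------------------------------------------------------------------

def weights_inverse_null_variance(ds: GenotypeDataset) -> np.ndarray:
    """Weights 1/Var0(U_j) per kept variant; makes Q_SKAT equal sum T."""
    prep = _prepare_scan(ds)
    _, var0 = _scan_U_var0(prep, ds.case_label)
    return 1.0 / var0[0]


def weights_beta_maf(ds: GenotypeDataset, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Squared Beta(a, b) density at the pooled sample MAF (optional helper;
    the default elsewhere in this package is never this weighting)."""
    prep = _prepare_scan(ds)
    maf = ds.sample_maf()[prep.kept]
    return stats.beta.pdf(maf, a, b) ** 2


def skat_statistic(
    ds: GenotypeDataset, weights: np.ndarray | None = None
) -> float:
    """Q_SKAT = sum_j w_j U_j^2 over polymorphic variants.

    U_j and its null variance are computed from all available genotypes at
    each variant. ``weights=None`` uses unit weights (the C-alpha
    statistic); inverse-null-variance weights reproduce the sum-T statistic
    exactly, with or without missing genotypes.
    """
    prep = _prepare_scan(ds)
    u, _ = _scan_U_var0(prep, ds.case_label)
    u = u[0]
    if weights is None:
        w = np.ones_like(u)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != u.shape:
            raise ValueError("weights must align with kept variants")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    if u.size and not np.any(w > 0):
        raise ValueError("all weights zero: degenerate statistic")
    return float(np.sum(w * u**2))
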