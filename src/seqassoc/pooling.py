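"""Pooling (burden) tests: CMC via Hotelling's T^2 and a modified WSS.

CMC collapses rare variants (pooled-sample MAF <= 0.01 by default) into a
presence indicator, joins it with the minor-allele counts at common
variants, and compares group means with Hotelling's T^2. LD among common
variants can make the pooled covariance singular, so the statistic uses a
g2 generalized inverse obtained by Goodnight's sweep algorithm; the swept
rank v feeds the F(v, N-v-1) reference distribution, and results with
effective denominator df <= 4 are flagged invalid (near rank deficiency,
algebraically identical generalized inverses can disagree numerically, and
the F moments need ddf > 4).

WSS weights each variant by the estimated standard deviation of its
minor-allele count under the control-based allele-frequency estimate,
scores individuals by the weighted sum of their observed minor alleles
(missing -> 0), and tests the case midrank-sum W against its permutation
null with a two-sided tail in |W - W_bar|.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import MISSING, GenotypeDataset
from .results import PermutationNull, TestResult

__all__ = ["g2_sweep_inverse", "cmc_test", "wss_test", "build_cmc_vectors"]


# ---------------------------------------------------------------------------
# Goodnight G2SWEEP
# ---------------------------------------------------------------------------

def g2_sweep_inverse(
    a: np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, int, list[int]]:
    """g2 (reflexive) generalized inverse of a symmetric PSD matrix.

    Applies the sweep operator once to each column in succession. A pivot
    smaller than ``tol`` times the largest original diagonal element marks
    its column as numerically dependent on the previously swept columns;
    its row and column are zeroed. For a full-rank matrix the result is the
    ordinary inverse; in general it satisfies A G A = A and G A G = G.

    Returns
    -------
    (G, rank, dependent)
        The generalized inverse, the number of swept (independent) columns,
        and the indices of the dependent columns.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a, a.T, rtol=1e-10, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    n = a.shape[0]
    w = a.copy()
    threshold = tol * max(np.max(np.diag(a)), np.finfo(float).tiny)
    dependent: list[int] = []
    for k in range(n):
        d = w[k, k]
        if d < threshold:
            w[k, :] = 0.0
            w[:, k] = 0.0
            dependent.append(k)
            continue
        col_k = w[:, k].copy()
        w[k, :] = w[k, :] / d
        for i in range(n):
            if i != k:
                w[i, :] -= col_k[i] * w[k, :]
        w[:, k] = -col_k / d
        w[k, k] = 1.0 / d
    rank = n - len(dependent)
    # dependent rows/cols are zeroed again: intermediate sweeps may have
    # written into them before the dependency was detected
    for k in dependent:
        w[k, :] = 0.0
        w[:, k] = 0.0
    return w, rank, dependent


# ---------------------------------------------------------------------------
# CMC (collapse + Hotelling's T^2)
# ---------------------------------------------------------------------------

def build_cmc_vectors(
    ds: GenotypeDataset, rare_maf_threshold: float = 0.01
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-individual CMC vectors and the usable-individual mask.

    The vector is the rare-variant presence indicator (omitted when the
    rare set is empty) followed by minor-allele counts at each common
    variant. Individuals are excluded when (a) any common-variant genotype
    is missing, or (b) no minor allele is observed at any rare variant but
    at least one rare genotype is missing, making the indicator ambiguous.
    """
    poly = ds.polymorphic_in_sample()
    maf = ds.sample_maf()
    rare = poly & (maf <= rare_maf_threshold)
    common = poly & (maf > rare_maf_threshold)

    g_common = ds.genotypes[:, common]
    g_rare = ds.genotypes[:, rare]
    missing_common = (g_common == MISSING).any(axis=1)

    obs_rare = g_rare != MISSING
    any_minor = np.where(obs_rare, g_rare, 0).sum(axis=1) > 0
    any_missing_rare = (~obs_rare).any(axis=1)
    ambiguous = ~any_minor & any_missing_rare

    usable = ~missing_common & ~(ambiguous & ~missing_common)
    info = {
        "n_excluded_common": int(missing_common.sum()),
        "n_excluded_ambiguous": int((ambiguous & ~missing_common).sum()),
        "n_rare": int(rare.sum()),
        "n_common": int(common.sum()),
    }
    cols: list[np.ndarray] = []
    if rare.sum() > 0:
        cols.append(any_minor[usable].astype(float)[:, None])
    if common.sum() > 0:
        cols.append(g_common[usable].astype(float))
    if cols:
        x = np.hstack(cols)
    else:
        x = np.zeros((int(usable.sum()), 0))
    return x, usable, info


def cmc_test(
    ds: GenotypeDataset, rare_maf_threshold: float = 0.01
) -> TestResult:
    """CMC test: rare-variant indicator + common counts, Hotelling's T^2.

    T^2 = (R S / N) d' G d with d the case-control mean difference, G the
    g2 inverse of the pooled within-group covariance (denominator N - 2),
    and v the swept rank; p from F(v, N - v - 1) after the classical
    scaling. Flagged invalid when no usable individuals remain, either
    group is empty, or the effective ddf = N - v - 1 is <= 4.
    """
    x, usable, info = build_cmc_vectors(ds, rare_maf_threshold)
    y = ds.case_label[usable]
    n_used = int(usable.sum())
    extras = {"n_used": n_used, **info}
    r, s = int(y.sum()), int(n_used - y.sum())
    if n_used == 0 or x.shape[1] == 0:
        return TestResult("cmc", np.nan, None, 0, valid=False,
                          reason="no complete data", extras=extras)
    if r == 0 or s == 0 or n_used < 3:
        return TestResult("cmc", np.nan, None, 0, valid=False,
                          reason="a group has no usable individuals",
                          extras=extras)
    xa, xc = x[y == 1], x[y == 0]
    d = xa.mean(axis=0) - xc.mean(axis=0)
    # pooled within-group covariance, classical two-sample Hotelling
    sa = np.cov(xa, rowvar=False, ddof=1) if r > 1 else np.zeros((x.shape[1],) * 2)
    sc = np.cov(xc, rowvar=False, ddof=1) if s > 1 else np.zeros((x.shape[1],) * 2)
    sp = ((r - 1) * np.atleast_2d(sa) + (s - 1) * np.atleast_2d(sc)) / (n_used - 2)
    g_inv, v, dependent = g2_sweep_inverse(sp)
    extras.update({"v_effective": v, "ddf": n_used - v - 1,
                   "n_dependent": len(dependent)})
    if v == 0:
        return TestResult("cmc", np.nan, None, 0, valid=False,
                          reason="degenerate covariance (rank 0)",
                          extras=extras)
    t2 = float(r * s / n_used * d @ g_inv @ d)
    ddf = n_used - v - 1
    if ddf <= 0:
        return TestResult("cmc", t2, None, v, valid=False,
                          reason="nonpositive denominator df", extras=extras)
    f_stat = ddf / (v * (n_used - 2)) * t2
    p = float(stats.f.sf(f_stat, v, ddf))
    valid = ddf > 4
    return TestResult(
        "cmc", t2, p, v, valid=valid,
        reason="" if valid else "effective ddf <= 4",
        extras={**extras, "F": f_stat},
    )


# ---------------------------------------------------------------------------
# WSS (weighted rank-sum)
# ---------------------------------------------------------------------------

def _wss_W(
    g0: np.ndarray,
    obs: np.ndarray,
    labels: np.ndarray,
    recompute_weights: bool,
    weight_n: str,
) -> np.ndarray:
    """Case midrank-sum W for each row of a (n_sets, N) label matrix.

    Control-based frequency estimate q_j = (m_j^U + 1) / (2 n_j^U + 2) with
    m_j^U the minor-allele count and n_j^U the number of controls observed
    at variant j; weight w_j = sqrt(n_j q_j (1 - q_j)) where n_j counts all
    individuals observed at j (``weight_n="controls"`` uses n_j^U instead).
    Genetic score = sum over observed genotypes of G_ij / w_j.
    """
    y = np.atleast_2d(labels).astype(float)
    n_obs = obs.sum(axis=0)
    if recompute_weights:
        ctrl = 1.0 - y
        n_ju = ctrl @ obs                       # controls observed at j
        m_ju = ctrl @ g0                        # control minor-allele counts
    else:
        ctrl0 = 1.0 - y[0]
        n_ju = np.tile(ctrl0 @ obs, (y.shape[0], 1))
        m_ju = np.tile(ctrl0 @ g0, (y.shape[0], 1))
    q = (m_ju + 1.0) / (2.0 * n_ju + 2.0)
    n_j = n_obs[None, :] if weight_n == "all" else n_ju
    w = np.sqrt(n_j * q * (1.0 - q))
    inv_w = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    scores = g0 @ inv_w.T                       # (N, n_sets)
    ranks = stats.rankdata(scores, axis=0, method="average")
    return np.einsum("ti,it->t", y, ranks)


def wss_test(
    ds: GenotypeDataset,
    m: int = 10_000,
    seed: int | np.random.Generator | None = None,
    recompute_weights: bool = True,
    weight_n: str = "all",
) -> TestResult:
    """Modified WSS: midranks, two-sided permutation p-value.

    Missing genotypes are excluded from the control-frequency estimate and
    contribute 0 to an individual's score. Weights are recomputed inside
    each permutation by default (controls change under shuffling);
    ``recompute_weights=False`` freezes them at the observed-data values.
    The two-sided p-value is (#{|W_t - W_bar| >= |W_obs - W_bar|} + 1) /
    (m + 1), with W_bar the mean of W over the m permutations.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if ds.n_cases == 0 or ds.n_controls == 0:
        raise ValueError("both cases and controls required")
    if weight_n not in ("all", "controls"):
        raise ValueError("weight_n must be 'all' or 'controls'")
    poly = ds.polymorphic_in_sample()
    if not poly.any():
        return TestResult("wss", np.nan, None, 0, m=m, valid=False,
                          reason="no polymorphic variants")
    obs = (ds.genotypes != MISSING)[:, poly]
    g0 = np.where(obs, ds.genotypes[:, poly], 0).astype(float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.empty((m + 1, ds.n_individuals), dtype=np.int8)
    labels[0] = ds.case_label
    for t in range(1, m + 1):
        labels[t] = rng.permutation(ds.case_label)
    w_all = _wss_W(g0, obs.astype(float), labels, recompute_weights, weight_n)
    w_obs, w_null = w_all[0], w_all[1:]
    w_bar = float(w_null.mean())
    p = (np.sum(np.abs(w_null - w_bar) >= np.abs(w_obs - w_bar)) + 1) / (m + 1)
    return TestResult(
        "wss", float(w_obs), float(p), int(poly.sum()), m=m,
        extras={"W_bar": w_bar},
        permutation_null=PermutationNull(w_null),
    )
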