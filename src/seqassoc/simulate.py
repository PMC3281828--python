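"""Coalescent haplotype populations, disease models, case-control sampling,
and the Markov-chain genotype-missingness process.

Two interchangeable coalescent backends generate haplotype populations:

* ``msprime`` (default for studies): standard neutral coalescent with a
  finite-sites recombination model and infinite-sites binary mutations —
  diploid time scale, so theta = 4 N_e mu L;
* ``hudson``: a self-contained no-recombination Kingman coalescent
  (exponential coalescence times, Poisson mutations on branches) used as a
  hermetic cross-check.

Both satisfy E[segregating sites] = theta * sum_{i=1}^{n-1} 1/i, since
recombination does not change the expected number of segregating sites.

Disease risk follows a logistic penetrance model: the log odds of disease
for multi-variant genotype G is beta0 + sum_j beta_j G_j, with beta0 the
log odds of the wild-type penetrance and beta_j = ln(OR) for risk variants
(0 for neutral). Case-control samples are drawn by rejection: random union
of two haplotypes (random mating), affection assigned with the penetrance
probability, until the requested numbers of cases and controls accrue.

Genotype missingness is a per-individual two-state Markov chain along the
rescaled [0, 1] sequence axis: alternating observed intervals of length
Exp(L(1-lambda)) and missing intervals of length Exp(L lambda), starting
at 0 in the observed state, so the expected observed fraction equals the
call rate lambda. The process is independent of genotype and affection
status (MCAR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
from scipy.special import expit, logit

from .core import MISSING, GenotypeDataset, HaplotypePopulation

__all__ = [
    "CoalescentConfig",
    "RiskClass",
    "DiseaseModel",
    "simulate_population",
    "assign_disease_model",
    "penetrance",
    "sample_case_control",
    "missingness_mask",
]


# ---------------------------------------------------------------------------
# Coalescent configuration and backends
# ---------------------------------------------------------------------------

@dataclass
class CoalescentConfig:
    """Neutral-coalescent parameters for one haplotype population.

    Defaults describe a 100 kb locus in a human-like population:
    per-nucleotide mutation rate 2.5e-8, recombination 1e-8 between
    adjacent nucleotides, effective diploid size N_e = 10,000 (20,000
    haplotypes), with 10,000 haplotypes sampled per population.
    """

    n_hap: int = 10_000
    locus_length_bp: int = 100_000
    mu: float = 2.5e-8
    recombination_rate: float = 1e-8
    ne: int = 10_000

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate theta = 4 N_e mu L."""
        return 4.0 * self.ne * self.mu * self.locus_length_bp

    def expected_segregating_sites(self, n_hap: int | None = None) -> float:
        """E[S] = theta * sum_{i=1}^{n-1} 1/i (backend-independent)."""
        n = self.n_hap if n_hap is None else n_hap
        return self.theta * float(np.sum(1.0 / np.arange(1, n)))


def _msprime_population(
    config: CoalescentConfig, rng: np.random.Generator
) -> HaplotypePopulation:
    seed_anc, seed_mut = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(config.n_hap, ploidy=1)],
        ploidy=2,
        population_size=config.ne,
        sequence_length=config.locus_length_bp,
        recombination_rate=config.recombination_rate,
        random_seed=int(seed_anc),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=config.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,  # infinite-sites mutation
        random_seed=int(seed_mut),
    )
    geno = mts.genotype_matrix().T.astype(np.int8)  # (n_hap, sites)
    positions = np.array([s.position for s in mts.sites()]) / config.locus_length_bp
    freq = geno.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    return HaplotypePopulation(geno[:, keep], positions[keep], config.locus_length_bp)


def _hudson_population(
    config: CoalescentConfig, rng: np.random.Generator
) -> HaplotypePopulation:
    """No-recombination Kingman coalescent with infinite-sites mutations.

    Times are in units of 2N generations, so a branch of length t carries
    Poisson(theta/2 * t) mutations and E[S] = theta * H_{n-1}.
    """
    n = config.n_hap
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    active = list(range(n))
    t = 0.0
    for node in range(n, n_nodes):
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        c1, c2 = active[i], active[j]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(node)
        parent[c1] = parent[c2] = node
        children[node] = [c1, c2]
        time[node] = t

    branch_len = np.zeros(n_nodes)
    non_root = parent >= 0
    branch_len[non_root] = time[parent[non_root]] - time[non_root]
    total = branch_len.sum()
    n_mut = rng.poisson(config.theta / 2.0 * total)
    if n_mut == 0:
        return HaplotypePopulation(
            np.zeros((n, 0), dtype=np.int8), np.zeros(0), config.locus_length_bp
        )
    branches = rng.choice(n_nodes, size=n_mut, p=branch_len / total)
    positions = rng.uniform(0.0, 1.0, size=n_mut)
    order = np.argsort(positions)
    geno = np.zeros((n, n_mut), dtype=np.int8)
    for col, b in enumerate(branches[order]):
        stack = [int(b)]
        while stack:
            node = stack.pop()
            if node < n:
                geno[node, col] = 1
            else:
                stack.extend(children[node])
    return HaplotypePopulation(geno, positions[order], config.locus_length_bp)


def simulate_population(
    config: CoalescentConfig,
    seed: int | np.random.Generator | None = None,
    backend: str = "msprime",
) -> HaplotypePopulation:
    """Simulate one haplotype population under the neutral coalescent."""
    if config.mu <= 0 or config.ne <= 0 or config.recombination_rate < 0:
        raise ValueError("rates and population size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if backend == "msprime":
        return _msprime_population(config, rng)
    if backend == "hudson":
        return _hudson_population(config, rng)
    raise ValueError(f"unknown backend: {backend!r}")


# ---------------------------------------------------------------------------
# Disease models
# ---------------------------------------------------------------------------

@dataclass
class RiskClass:
    """Half-open population-MAF range [maf_lo, maf_hi) with an odds ratio."""

    maf_lo: float
    maf_hi: float
    odds_ratio: float

    def contains(self, maf: np.ndarray) -> np.ndarray:
        return (maf >= self.maf_lo) & (maf < self.maf_hi)


@dataclass
class DiseaseModel:
    """Logistic penetrance model over a haplotype population's variants.

    P(A | G) = expit(beta0 + sum_j beta_j G_j) with G_j the minor-allele
    count at variant j; beta0 = logit(f0) is the log odds of the wild-type
    penetrance, and beta_j = ln(theta_c) for risk variants in class c
    (0 for neutral variants).
    """

    beta0: float
    beta: np.ndarray
    risk_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def f0(self) -> float:
        return float(expit(self.beta0))

    @property
    def n_risk(self) -> int:
        return len(self.risk_index)

    @classmethod
    def null(cls, n_variants: int, f0: float = 0.05) -> "DiseaseModel":
        """Null model: no risk variants, constant penetrance f0."""
        return cls(beta0=float(logit(f0)), beta=np.zeros(n_variants))


def assign_disease_model(
    pop: HaplotypePopulation,
    risk_classes: list[RiskClass],
    n_risk: int = 50,
    f0: float = 0.05,
    seed: int | np.random.Generator | None = None,
    max_draws: int = 10**6,
) -> DiseaseModel:
    """Randomly select risk variants from a haplotype population.

    Repeats: draw a uniformly random variant; if its population MAF lies
    in some class's half-open interval and it is not already a risk
    variant, assign beta_j = ln(odds ratio). This samples risk-variant
    classes in proportion to the occurrence of each MAF range in the
    population. Errors out if fewer than ``n_risk`` variants are eligible
    or after ``max_draws`` rejection draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = np.zeros(pop.n_variants)
    if n_risk == 0:
        return DiseaseModel(beta0=float(logit(f0)), beta=beta)
    maf = pop.maf
    eligible = np.zeros(pop.n_variants, dtype=bool)
    for rc in risk_classes:
        eligible |= rc.contains(maf)
    if eligible.sum() < n_risk:
        raise ValueError(
            f"only {int(eligible.sum())} variants eligible for {n_risk} risk slots"
        )
    chosen: set[int] = set()
    draws = 0
    while len(chosen) < n_risk:
        if draws >= max_draws:
            raise RuntimeError("risk-variant selection exceeded max_draws")
        j = int(rng.integers(0, pop.n_variants))
        draws += 1
        if j in chosen:
            continue
        for rc in risk_classes:
            if rc.maf_lo <= maf[j] < rc.maf_hi:
                beta[j] = np.log(rc.odds_ratio)
                chosen.add(j)
                break
    return DiseaseModel(
        beta0=float(logit(f0)), beta=beta,
        risk_index=np.array(sorted(chosen), dtype=int),
    )


def penetrance(genotypes: np.ndarray, model: DiseaseModel) -> np.ndarray:
    """P(A | G) = expit(beta0 + G @ beta) for minor-allele count rows."""
    g = np.atleast_2d(np.asarray(genotypes, dtype=float))
    nz = np.flatnonzero(model.beta)
    eta = model.beta0 + g[:, nz] @ model.beta[nz]
    return expit(eta)


# ---------------------------------------------------------------------------
# Case-control sampling
# ---------------------------------------------------------------------------

def sample_case_control(
    pop: HaplotypePopulation,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator | None = None,
    max_draws: int = 10**7,
) -> GenotypeDataset:
    """Rejection-sample a case-control dataset from a haplotype population.

    Individuals are formed by drawing two haplotypes with replacement
    (random mating), affection is Bernoulli with the model penetrance, and
    sampling continues until exactly ``n_cases`` cases and ``n_controls``
    controls accumulate. Genotypes are minor-allele counts under the
    population-based minor-allele coding, fixed before sampling so that
    data sets from one population are comparable.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    minor = pop.minor_allele
    flip = minor == 0  # population minor allele is the ancestral allele
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    drawn = 0
    batch = max(256, 2 * (n_cases + n_controls))
    while len(cases) < n_cases or len(controls) < n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                "case-control sampling exceeded max_draws "
                "(pathological penetrance model?)"
            )
        idx = rng.integers(0, pop.n_hap, size=(batch, 2))
        g_derived = pop.haplotypes[idx[:, 0]] + pop.haplotypes[idx[:, 1]]
        g_minor = np.where(flip[None, :], 2 - g_derived, g_derived).astype(np.int8)
        p_aff = penetrance(g_minor, model)
        affected = rng.random(batch) < p_aff
        drawn += batch
        for row, aff in zip(g_minor, affected):
            if aff and len(cases) < n_cases:
                cases.append(row)
            elif not aff and len(controls) < n_controls:
                controls.append(row)
    geno = np.vstack(cases + controls).astype(np.int16)
    labels = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return GenotypeDataset(
        genotypes=geno,
        case_label=labels,
        positions=pop.positions.copy(),
        pop_maf=pop.maf,
        minor_allele_source="population",
        locus_length_bp=pop.locus_length_bp,
    )


# ---------------------------------------------------------------------------
# Missingness process
# ---------------------------------------------------------------------------

def missingness_mask(
    ds: GenotypeDataset,
    call_rate: float,
    seed: int | np.random.Generator | None = None,
) -> GenotypeDataset:
    """Apply the two-state Markov-chain missingness process per individual.

    On the rescaled [0, 1] axis each individual's chain starts at position
    0 in the observed state and alternates observed intervals ~
    Exp(L(1 - lambda)) with missing intervals ~ Exp(L lambda); genotypes at
    variant positions inside a missing interval become MISSING. The
    expected observed fraction is the call rate lambda; the process never
    looks at genotypes or labels (MCAR).
    """
    lam = call_rate
    if not 0 < lam <= 1:
        raise ValueError("call rate must be in (0, 1]")
    if ds.positions is None:
        raise ValueError("dataset has no variant positions")
    geno = ds.genotypes.copy()
    if lam < 1.0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        L = ds.locus_length_bp
        scale_o = 1.0 / (L * (1.0 - lam))   # mean observed-interval length
        scale_m = 1.0 / (L * lam)           # mean missing-interval length
        n_pairs = int(1.0 / (scale_o + scale_m) * 1.5) + 20
        pos = ds.positions
        for i in range(ds.n_individuals):
            lengths = np.empty(2 * n_pairs)
            lengths[0::2] = rng.exponential(scale_o, size=n_pairs)
            lengths[1::2] = rng.exponential(scale_m, size=n_pairs)
            cum = np.cumsum(lengths)
            while cum[-1] < 1.0:  # rare: extend the chain
                extra = np.empty(2 * n_pairs)
                extra[0::2] = rng.exponential(scale_o, size=n_pairs)
                extra[1::2] = rng.exponential(scale_m, size=n_pairs)
                cum = np.concatenate([cum, cum[-1] + np.cumsum(extra)])
            state = np.searchsorted(cum, pos, side="right") % 2
            geno[i, state == 1] = MISSING
    return GenotypeDataset(
        genotypes=geno,
        case_label=ds.case_label.copy(),
        positions=None if ds.positions is None else ds.positions.copy(),
        pop_maf=None if ds.pop_maf is None else ds.pop_maf.copy(),
        minor_allele_source=ds.minor_allele_source,
        locus_length_bp=ds.locus_length_bp,
        sample_ids=list(ds.sample_ids),
    )
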