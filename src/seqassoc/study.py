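"""Type-I error and power studies over disease models and nuisance settings.

A study cell is one combination of (test, sample size, call rate, alpha).
For each replicate a haplotype population is taken from a pre-simulated
pool (populations may be reused across replicates, as recorded in the
provenance), a disease model is assigned once per population, a balanced
case-control sample is drawn, missingness masks are applied per call rate,
and every requested test runs on every masked dataset. A test rejects at
level alpha iff its p-value is <= alpha; CMC results with effective
denominator df <= 4 are excluded from the estimates and counted
separately. Rejection rates carry exact (Clopper-Pearson) binomial 95%
confidence intervals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import GenotypeDataset
from .pooling import cmc_test, wss_test
from .results import TestResult
from .simulate import (
    CoalescentConfig,
    DiseaseModel,
    RiskClass,
    assign_disease_model,
    missingness_mask,
    sample_case_control,
    simulate_population,
)
from .single_variant import bc_ca_test, permutation_tests

__all__ = ["StudyConfig", "StudyResult", "run_study", "summarize_rejections",
           "load_study_config"]

PERMUTATION_TESTS = ("camax", "casum")


@dataclass
class StudyConfig:
    """Configuration for a type-I error / power study."""

    coalescent: CoalescentConfig = field(default_factory=CoalescentConfig)
    risk_classes: list[RiskClass] = field(default_factory=list)
    n_risk: int = 0
    f0: float = 0.05
    sample_sizes: tuple[int, ...] = (500, 1000, 2000)
    case_fraction: float = 0.5
    call_rates: tuple[float, ...] = (1.0, 0.995, 0.95)
    alphas: tuple[float, ...] = (0.05, 0.01)
    replicates: int = 1000
    tests: tuple[str, ...] = ("bcca", "camax", "casum", "cmc", "wss")
    m: int = 10_000
    rare_maf_threshold: float = 0.01
    n_populations: int | None = None  # pool size; None = one per replicate
    backend: str = "msprime"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for rate in self.call_rates:
            if not 0 < rate <= 1:
                raise ValueError("call rates must be in (0, 1]")


@dataclass
class StudyResult:
    """Long-format per-replicate results plus per-cell summary."""

    results: pd.DataFrame
    summary: pd.DataFrame
    provenance: dict


def summarize_rejections(n: int, x: int) -> tuple[float, float, float]:
    """Rejection rate with its exact (Clopper-Pearson) binomial 95% CI.

    Bounds come from beta quantiles; x = 0 gives a lower bound of 0 and
    x = n an upper bound of 1.
    """
    if n < 1:
        raise ValueError("no valid analyses to summarize")
    if not 0 <= x <= n:
        raise ValueError("rejections must lie in [0, n]")
    rate = x / n
    lo = 0.0 if x == 0 else float(stats.beta.ppf(0.025, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(0.975, x + 1, n - x))
    return rate, lo, hi


def _run_tests_on_dataset(
    ds: GenotypeDataset, config: StudyConfig, rng: np.random.Generator
) -> dict[str, TestResult]:
    out: dict[str, TestResult] = {}
    perm = [t for t in config.tests if t in PERMUTATION_TESTS]
    if perm:
        shared = permutation_tests(
            ds, tuple(t.removeprefix("ca") for t in perm), m=config.m, seed=rng
        )
        for t in perm:
            out[t] = shared[t.removeprefix("ca")]
    if "bcca" in config.tests:
        out["bcca"] = bc_ca_test(ds, alpha=min(config.alphas))
    if "cmc" in config.tests:
        out["cmc"] = cmc_test(ds, config.rare_maf_threshold)
    if "wss" in config.tests:
        out["wss"] = wss_test(ds, m=config.m, seed=rng)
    return out


def _rejects(res: TestResult, alpha: float) -> bool:
    if res.p_value is not None:
        return res.p_value <= alpha
    # BC-CA decision at the requested level: compare max T with the
    # Bonferroni-corrected chi-square quantile for this data set
    v = res.n_variants
    return res.statistic >= stats.chi2.ppf(1 - alpha / v, df=1)


def run_study(
    config: StudyConfig, out_dir: str | Path | None = None
) -> StudyResult:
    """Run the full study loop; identical seeds give identical results.

    Per replicate: population (from the pool), disease model (assigned
    once per population), case-control sample, one masked dataset per call
    rate, all requested tests. Errors from individual tests are recorded
    as invalid results, never aborting the study.
    """
    rng = np.random.default_rng(config.seed)
    n_pool = config.n_populations or config.replicates
    pool = [
        simulate_population(config.coalescent, rng, backend=config.backend)
        for _ in range(n_pool)
    ]
    models: list[DiseaseModel] = [
        assign_disease_model(
            pop, config.risk_classes, config.n_risk, config.f0, rng
        )
        if config.n_risk > 0
        else DiseaseModel.null(pop.n_variants, config.f0)
        for pop in pool
    ]

    writer = None
    fh = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = open(out_dir / "results.tsv", "w", newline="")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["replicate", "population", "test", "N", "call_rate",
             "statistic", "p", "n_variants", "valid", "reason"]
        )

    rows = []
    for rep in range(config.replicates):
        pop_id = rep % n_pool
        pop, model = pool[pop_id], models[pop_id]
        for n_total in config.sample_sizes:
            r = int(round(n_total * config.case_fraction))
            ds_full = sample_case_control(pop, model, r, n_total - r, rng)
            for rate in config.call_rates:
                ds = ds_full if rate == 1.0 else missingness_mask(ds_full, rate, rng)
                try:
                    results = _run_tests_on_dataset(ds, config, rng)
                except Exception as exc:  # pragma: no cover - defensive
                    results = {
                        t: TestResult(t, np.nan, None, 0, valid=False,
                                      reason=f"error: {exc}")
                        for t in config.tests
                    }
                for test, res in results.items():
                    row = {
                        "replicate": rep, "population": pop_id, "test": test,
                        "N": n_total, "call_rate": rate,
                        "statistic": res.statistic, "p": res.p_value,
                        "n_variants": res.n_variants, "valid": res.valid,
                        "reason": res.reason,
                    }
                    for alpha in config.alphas:
                        row[f"reject_{alpha}"] = (
                            _rejects(res, alpha) if res.valid else None
                        )
                    rows.append(row)
                    if writer is not None:
                        writer.writerow(
                            [row[c] for c in
                             ("replicate", "population", "test", "N",
                              "call_rate", "statistic", "p", "n_variants",
                              "valid", "reason")]
                        )
    if fh is not None:
        fh.close()

    results_df = pd.DataFrame(rows)
    summary_rows = []
    for (test, n_total, rate), grp in results_df.groupby(
        ["test", "N", "call_rate"]
    ):
        for alpha in config.alphas:
            valid = grp[grp["valid"]]
            n_valid = len(valid)
            n_invalid = len(grp) - n_valid
            if n_valid:
                x = int(valid[f"reject_{alpha}"].sum())
                rate_hat, lo, hi = summarize_rejections(n_valid, x)
            else:
                x, rate_hat, lo, hi = 0, np.nan, np.nan, np.nan
            summary_rows.append(
                {"test": test, "N": n_total, "call_rate": rate,
                 "alpha": alpha, "n_valid": n_valid, "n_invalid": n_invalid,
                 "rejections": x, "rejection_rate": rate_hat,
                 "ci_low": lo, "ci_high": hi}
            )
    summary_df = pd.DataFrame(summary_rows)
    if out_dir is not None:
        summary_df.to_csv(Path(out_dir) / "summary.tsv", sep="\t", index=False)
    provenance = {
        "seed": config.seed,
        "n_populations": n_pool,
        "populations_reused": n_pool < config.replicates,
        "backend": config.backend,
    }
    return StudyResult(results_df, summary_df, provenance)


def load_study_config(path: str | Path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML/JSON mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = dict(raw)
    if "coalescent" in kwargs:
        kwargs["coalescent"] = CoalescentConfig(**kwargs["coalescent"])
    if "risk_classes" in kwargs:
        kwargs["risk_classes"] = [RiskClass(**rc) for rc in kwargs["risk_classes"]]
    for key in ("sample_sizes", "call_rates", "alphas", "tests"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return StudyConfig(**kwargs)
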