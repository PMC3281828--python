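"""Haplotype and genotype data model, MAF/LD summaries, and file I/O.

Conventions
-----------
* Haplotypes are binary matrices (haplotype x variant); allele 1 is the
  derived allele as emitted by coalescent simulators.
* Genotypes are minor-allele counts in {0, 1, 2}; :data:`MISSING` (-9) is an
  out-of-band sentinel, never 0, because 0 is a valid genotype.
* Variant positions live on the unit interval (fraction of the locus length
  L in base pairs); conversion to bp is for reporting only.
* The minor allele is the allele with frequency < 0.5; at exactly 0.5,
  allele 1 (derived) is declared minor so that the coding is deterministic
  and matches the simulator's orientation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Out-of-band sentinel for a missing genotype call.
MISSING: int = -9


# ---------------------------------------------------------------------------
# Haplotype populations
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePopulation:
    """A population of binary haplotypes at a locus.

    Parameters
    ----------
    haplotypes
        ``(n_hap, n_variants)`` array with entries in {0, 1}; allele 1 is
        the derived allele.
    positions
        Per-variant coordinates on [0, 1], strictly increasing (fractions
        of the locus length).
    locus_length_bp
        Physical locus length L in base pairs.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    locus_length_bp: int = 100_000

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.positions.shape != (self.haplotypes.shape[1],):
            raise ValueError("positions must have one entry per variant")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def pop_allele_freq(self) -> np.ndarray:
        """Frequency of allele 1 at each variant (column mean)."""
        return self.haplotypes.mean(axis=0)

    @property
    def minor_allele(self) -> np.ndarray:
        """Which allele (0/1) is minor; ties at 0.5 resolve to allele 1."""
        return np.where(self.pop_allele_freq <= 0.5, 1, 0).astype(np.int8)

    @property
    def maf(self) -> np.ndarray:
        f = self.pop_allele_freq
        return np.minimum(f, 1.0 - f)

    def positions_bp(self) -> np.ndarray:
        """Integer base-pair positions, floor(position * L); reporting only."""
        return np.floor(self.positions * self.locus_length_bp).astype(np.int64)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        h = self.haplotypes
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if self.n_variants:
            if np.any(self.positions < 0) or np.any(self.positions > 1):
                raise ValueError("positions must lie in [0, 1]")
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            f = self.pop_allele_freq
            if np.any(f <= 0) or np.any(f >= 1):
                raise ValueError("all variants must be polymorphic in the population")


def maf_and_minor_allele(pop: HaplotypePopulation) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (MAF, minor allele) from population allele frequencies.

    Raises
    ------
    ValueError
        If any variant is monomorphic (minor allele undefined).
    """
    f = pop.pop_allele_freq
    if f.size == 0:
        raise ValueError("population has no variants")
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("monomorphic variant: minor allele undefined")
    return pop.maf, pop.minor_allele


def pairwise_r(pop: HaplotypePopulation, i: int, j: int) -> float:
    """LD correlation coefficient r between variants ``i`` and ``j``.

    r = D / sqrt(p_i (1-p_i) p_j (1-p_j)) with
    D = freq(minor_i, minor_j) - p_i p_j, computed from haplotype counts.
    Identical to the Pearson correlation of the two minor-allele indicator
    columns, and by symmetry to the major-allele correlation.
    """
    maf, minor = maf_and_minor_allele(pop)
    a = (pop.haplotypes[:, i] == minor[i]).astype(float)
    b = (pop.haplotypes[:, j] == minor[j]).astype(float)
    pi, pj = maf[i], maf[j]
    d = np.mean(a * b) - pi * pj
    return float(d / np.sqrt(pi * (1 - pi) * pj * (1 - pj)))


def pairwise_r_sample(
    pop: HaplotypePopulation, n_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """r values for ``n_pairs`` random distinct variant pairs (LD spectrum)."""
    v = pop.n_variants
    if v < 2:
        return np.empty(0)
    ii = rng.integers(0, v, size=n_pairs)
    jj = rng.integers(0, v - 1, size=n_pairs)
    jj[jj >= ii] += 1  # distinct pairs
    minor = pop.minor_allele
    ind = np.where(minor[None, :] == 1, pop.haplotypes, 1 - pop.haplotypes).astype(float)
    maf = pop.maf
    out = np.empty(n_pairs)
    for t, (i, j) in enumerate(zip(ii, jj)):
        d = np.mean(ind[:, i] * ind[:, j]) - maf[i] * maf[j]
        out[t] = d / np.sqrt(maf[i] * (1 - maf[i]) * maf[j] * (1 - maf[j]))
    return out


# ---------------------------------------------------------------------------
# Genotype datasets
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Case-control genotypes as minor-allele counts with missingness.

    ``genotypes`` is ``(N, v)`` with entries in {0, 1, 2, MISSING};
    ``case_label`` is 1 for cases and 0 for controls. ``positions`` and
    ``pop_maf`` carry per-variant metadata when the dataset came from a
    simulated haplotype population (minor-allele coding is then fixed by
    the population frequencies, recorded in ``minor_allele_source``).
    """

    genotypes: np.ndarray
    case_label: np.ndarray
    positions: np.ndarray | None = None
    pop_maf: np.ndarray | None = None
    minor_allele_source: str = "sample"
    locus_length_bp: int = 100_000
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        self.case_label = np.asarray(self.case_label, dtype=np.int8)
        if self.genotypes.shape[0] != self.case_label.shape[0]:
            raise ValueError("one case label per individual required")
        ok = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype entries must be 0/1/2 or MISSING")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(self.n_individuals)]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.case_label.sum())

    @property
    def n_controls(self) -> int:
        return self.n_individuals - self.n_cases

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) genotype calls."""
        return self.genotypes != MISSING

    def sample_maf(self) -> np.ndarray:
        """Per-variant MAF among observed genotypes (folded at 0.5).

        The stored counts follow a fixed coding (population minor allele for
        simulated data); the sample frequency of that allele can exceed 0.5,
        hence the fold.
        """
        obs = self.observed
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(obs, self.genotypes, 0).sum(axis=0) / (2.0 * n_obs)
        f = np.where(n_obs > 0, f, np.nan)
        return np.minimum(f, 1.0 - f)

    def polymorphic_in_sample(self) -> np.ndarray:
        """Variants with >= 2 distinct observed genotype values."""
        obs = self.observed
        g = np.where(obs, self.genotypes, MISSING)
        out = np.zeros(self.n_variants, dtype=bool)
        for j in range(self.n_variants):
            vals = g[obs[:, j], j]
            out[j] = vals.size > 0 and np.any(vals != vals[0])
        return out


@dataclass
class ContingencySummary:
    """Per-genotype-class case/control counts for the generalized statistic.

    ``r_counts[k]`` cases and ``s_counts[k]`` controls carry genotype class
    k; ``n_counts = r_counts + s_counts``.
    """

    r_counts: np.ndarray
    s_counts: np.ndarray

    def __post_init__(self) -> None:
        self.r_counts = np.asarray(self.r_counts, dtype=float)
        self.s_counts = np.asarray(self.s_counts, dtype=float)
        if self.r_counts.shape != self.s_counts.shape:
            raise ValueError("case and control count vectors must align")
        if np.any(self.r_counts < 0) or np.any(self.s_counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_counts(self) -> np.ndarray:
        return self.r_counts + self.s_counts

    @property
    def n_cases(self) -> float:
        return float(self.r_counts.sum())

    @property
    def n_controls(self) -> float:
        return float(self.s_counts.sum())

    @classmethod
    def from_single_variant(
        cls, genotypes: np.ndarray, case_label: np.ndarray
    ) -> "ContingencySummary":
        """3-class summary (genotype 0/1/2) over observed genotypes only."""
        g = np.asarray(genotypes)
        y = np.asarray(case_label)
        obs = g != MISSING
        g, y = g[obs], y[obs]
        r = np.array([np.sum((g == k) & (y == 1)) for k in range(3)], dtype=float)
        s = np.array([np.sum((g == k) & (y == 0)) for k in range(3)], dtype=float)
        return cls(r, s)


# ---------------------------------------------------------------------------
# Hudson ms-format text I/O
# ---------------------------------------------------------------------------

def read_ms(source: str | Path | io.TextIOBase) -> list[HaplotypePopulation]:
    """Parse Hudson ms-style output into haplotype populations.

    Replicates are delimited by ``//``; each has a ``segsites:`` line, a
    ``positions:`` line of coordinates in [0, 1], then one 0/1 string per
    haplotype. ``segsites: 0`` yields a population with zero variants.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = str(source)

    lines = text.splitlines()
    pops: list[HaplotypePopulation] = []
    locus_length = 100_000
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        # segsites line
        while i < len(lines) and not lines[i].startswith("segsites:"):
            i += 1
        if i >= len(lines):
            raise ValueError("replicate missing 'segsites:' line")
        segsites = int(lines[i].split(":", 1)[1])
        i += 1
        if segsites == 0:
            pops.append(
                HaplotypePopulation(
                    np.zeros((0, 0), dtype=np.int8), np.zeros(0), locus_length
                )
            )
            continue
        while i < len(lines) and not lines[i].startswith("positions:"):
            i += 1
        if i >= len(lines):
            raise ValueError("replicate missing 'positions:' line")
        positions = np.array([float(x) for x in lines[i].split(":", 1)[1].split()])
        if positions.size != segsites:
            raise ValueError("positions count does not match segsites")
        i += 1
        rows: list[list[int]] = []
        while i < len(lines) and lines[i].strip() and lines[i].strip() != "//":
            row = lines[i].strip()
            if len(row) != segsites:
                raise ValueError(
                    f"haplotype line length {len(row)} != segsites {segsites}"
                )
            if set(row) - {"0", "1"}:
                raise ValueError("haplotype lines must be 0/1 strings")
            rows.append([int(c) for c in row])
            i += 1
        pops.append(
            HaplotypePopulation(np.array(rows, dtype=np.int8), positions, locus_length)
        )
    return pops


def write_ms(
    pops: list[HaplotypePopulation], path: str | Path, command: str = "seqassoc"
) -> None:
    """Write populations in the Hudson ms output dialect."""
    with open(path, "w") as fh:
        fh.write(f"{command}\n0 0 0\n")
        for pop in pops:
            fh.write("\n//\n")
            fh.write(f"segsites: {pop.n_variants}\n")
            if pop.n_variants:
                pos = " ".join(f"{x:.6f}" for x in pop.positions)
                fh.write(f"positions: {pos}\n")
                for row in pop.haplotypes:
                    fh.write("".join(str(int(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Genotype matrix / VCF I/O
# ---------------------------------------------------------------------------

_TSV_MISSING = "NA"


def write_dataset(ds: GenotypeDataset, prefix: str | Path, fmt: str = "tsv") -> None:
    """Write a dataset as ``<prefix>.geno.tsv``/``<prefix>.vcf`` plus a
    ``<prefix>.pheno.tsv`` phenotype sidecar (sample id, case label)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.pheno.tsv", "w") as fh:
        fh.write("sample\tcase\n")
        for sid, y in zip(ds.sample_ids, ds.case_label):
            fh.write(f"{sid}\t{int(y)}\n")
    if fmt == "tsv":
        _write_tsv(ds, f"{prefix}.geno.tsv")
    elif fmt == "vcf":
        _write_vcf(ds, f"{prefix}.vcf")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_dataset(prefix: str | Path, fmt: str = "tsv") -> GenotypeDataset:
    """Read a dataset written by :func:`write_dataset`."""
    prefix = Path(prefix)
    pheno = {}
    order: list[str] = []
    with open(f"{prefix}.pheno.tsv") as fh:
        next(fh)
        for line in fh:
            sid, y = line.split()
            pheno[sid] = int(y)
            order.append(sid)
    if fmt == "tsv":
        return _read_tsv(f"{prefix}.geno.tsv", pheno)
    if fmt == "vcf":
        return _read_vcf(f"{prefix}.vcf", pheno)
    raise ValueError(f"unknown format: {fmt!r}")


def _write_tsv(ds: GenotypeDataset, path: str | Path) -> None:
    pos_bp = (
        np.floor(ds.positions * ds.locus_length_bp).astype(int)
        if ds.positions is not None
        else np.arange(ds.n_variants)
    )
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(f"var{p}" for p in pos_bp) + "\n")
        for sid, row in zip(ds.sample_ids, ds.genotypes):
            vals = [_TSV_MISSING if g == MISSING else str(int(g)) for g in row]
            fh.write(sid + "\t" + "\t".join(vals) + "\n")


def _read_tsv(path: str | Path, pheno: dict[str, int]) -> GenotypeDataset:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_var = len(header) - 1
        ids: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) - 1 != n_var:
                raise ValueError("inconsistent row length in genotype matrix")
            ids.append(parts[0])
            rows.append(
                [MISSING if v == _TSV_MISSING else int(v) for v in parts[1:]]
            )
    labels = np.array([pheno[s] for s in ids], dtype=np.int8)
    return GenotypeDataset(np.array(rows), labels, sample_ids=ids)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=seqassoc
##contig=<ID=1>
##INFO=<ID=MA,Number=1,Type=String,Description="Minor allele (REF or ALT)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _write_vcf(ds: GenotypeDataset, path: str | Path) -> None:
    """Minimal VCFv4.2 writer: biallelic, diploid unphased GT.

    The ALT allele is the coded (minor) allele, so a stored count g maps to
    GT with g ALT alleles; missing calls become ``./.``.
    """
    pos_bp = (
        np.floor(ds.positions * ds.locus_length_bp).astype(int) + 1
        if ds.positions is not None
        else np.arange(1, ds.n_variants + 1)
    )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.sample_ids)
            + "\n"
        )
        for j in range(ds.n_variants):
            gts = "\t".join(gt_map[int(g)] for g in ds.genotypes[:, j])
            fh.write(
                f"1\t{pos_bp[j]}\tv{j}\tA\tT\t.\tPASS\tMA=ALT\tGT\t{gts}\n"
            )


def _read_vcf(path: str | Path, pheno: dict[str, int]) -> GenotypeDataset:
    """Read a biallelic diploid VCF into minor-allele counts.

    The minor allele per record is taken from the ``MA`` INFO key when
    present; otherwise it is the allele with sample frequency < 0.5 (ties
    to ALT). Multi-allelic records are rejected: the model is biallelic.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    pos: list[int] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError("multi-allelic records are not supported")
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = rec.gt_types
        alt_count = np.select(
            [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING
        ).astype(np.int16)
        ma = dict(rec.INFO).get("MA")
        if ma is None:
            obs = alt_count != MISSING
            f_alt = alt_count[obs].sum() / (2.0 * max(obs.sum(), 1))
            ma = "ALT" if f_alt <= 0.5 else "REF"
        if ma == "REF":
            alt_count = np.where(alt_count == MISSING, MISSING, 2 - alt_count)
        cols.append(alt_count)
        pos.append(rec.POS)
    geno = np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=np.int16)
    labels = np.array([pheno[s] for s in samples], dtype=np.int8)
    return GenotypeDataset(geno, labels, sample_ids=samples)
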