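"""Genotype quality control: exact Hardy-Weinberg and linkage-
disequilibrium tests with Holm correction, plus descriptive counts.

The HWE test is the exact conditional test (probability of the observed
genotype array given the allele counts): full enumeration of the
heterozygote-count distribution for biallelic loci, Monte-Carlo shuffling
of allele copies otherwise.  The LD test is a genotypic permutation test
on the two-locus contingency table using the log-likelihood-ratio (G)
statistic.  Monte-Carlo p-values use the (b + 1)/(m + 1) convention, which
includes the observed table and guarantees p > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .containers import MISSING, GenotypeTable, HaplotypeAlignment, InputError


@dataclass
class TestResult:
    """Outcome of one QC hypothesis test."""

    test: str                 # "hwe" or "ld"
    locus: str                # locus name or "locusA:locusB"
    group: str
    p: float
    method: str               # "enumeration" or "monte-carlo"
    mc_reps: int = 0
    seed: int | None = None
    p_adj: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise InputError(f"p-value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _complete_rows(calls: np.ndarray) -> np.ndarray:
    """Rows of an (n, 2) call array where both alleles are observed."""
    return calls[(calls != MISSING).all(axis=1)]


def _log_array_prob(het: int, gcounts: np.ndarray, allele_counts: np.ndarray,
                    n: int) -> float:
    """Log conditional probability of a genotype array given allele counts.

    log P = log n! - sum log n_jk! + h log 2 + sum log n_j! - log (2n)!
    (Levene's distribution; h = number of heterozygotes).
    """
    return (gammaln(n + 1) - gammaln(gcounts + 1).sum() + het * np.log(2.0)
            + gammaln(allele_counts + 1).sum() - gammaln(2 * n + 1))


def _genotype_counts(calls: np.ndarray, alleles: np.ndarray):
    """Counts per unordered genotype, heterozygote count, allele counts."""
    order = {a: i for i, a in enumerate(alleles)}
    n_a = len(alleles)
    g = np.zeros((n_a, n_a))
    het = 0
    for a, b in calls:
        i, j = sorted((order[a], order[b]))
        g[i, j] += 1
        het += i != j
    allele_counts = np.bincount(
        [order[a] for row in calls for a in row], minlength=n_a).astype(float)
    return g[np.triu_indices(n_a)], het, allele_counts


def hwe_exact_test(calls: np.ndarray, group: str = "", locus: str = "",
                   mc_reps: int = 2000, seed: int = 0,
                   max_enumeration: int = 100_000) -> TestResult:
    """Exact conditional test of Hardy-Weinberg proportions at one locus.

    ``calls`` is an (n, 2) array of allele labels (missing sentinel
    allowed; incomplete individuals are dropped).  The p-value is the
    probability mass of genotype arrays no more probable than the observed
    one, conditional on the allele counts.  Biallelic configurations are
    fully enumerated (the heterozygote count determines the array); others
    fall back to Monte-Carlo shuffling of the 2n allele copies.
    """
    calls = _complete_rows(np.asarray(calls))
    n = calls.shape[0]
    if n < 2:
        raise InputError("need >= 2 fully typed individuals")
    alleles = np.unique(calls)
    if alleles.size == 1:
        return TestResult("hwe", locus, group, 1.0, "enumeration")
    gcounts, het, allele_counts = _genotype_counts(calls, alleles)
    logp_obs = _log_array_prob(het, gcounts, allele_counts, n)

    if alleles.size == 2 and int(min(allele_counts)) + 1 <= max_enumeration:
        nA = int(min(allele_counts))
        total = 0.0
        mass = 0.0
        for h in range(nA % 2, nA + 1, 2):
            # the heterozygote count determines the whole genotype array
            n_aa = (int(allele_counts[0]) - h) // 2
            n_bb = (int(allele_counts[1]) - h) // 2
            if n_aa < 0 or n_bb < 0:
                continue
            g = np.array([n_aa, h, n_bb], dtype=float)
            lp = _log_array_prob(h, g, allele_counts, n)
            p_tab = np.exp(lp)
            total += p_tab
            if lp <= logp_obs + 1e-10:
                mass += p_tab
        return TestResult("hwe", locus, group, min(mass / total, 1.0),
                          "enumeration")

    rng = np.random.default_rng(seed)
    copies = calls.ravel().copy()
    hits = 0
    for _ in range(mc_reps):
        rng.shuffle(copies)
        shuffled = copies.reshape(n, 2)
        g, h, _ = _genotype_counts(shuffled, alleles)
        if _log_array_prob(h, g, allele_counts, n) <= logp_obs + 1e-10:
            hits += 1
    p = (hits + 1) / (mc_reps + 1)
    return TestResult("hwe", locus, group, p, "monte-carlo", mc_reps, seed)


# ---------------------------------------------------------------------------
# Linkage-disequilibrium permutation test
# ---------------------------------------------------------------------------

def _g_statistic(c1: np.ndarray, c2: np.ndarray, k1: int, k2: int) -> float:
    """Log-likelihood-ratio statistic of the c1 x c2 contingency table."""
    table = np.bincount(c1 * k2 + c2, minlength=k1 * k2).reshape(k1, k2).astype(float)
    n = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / n
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def ld_exact_test(calls_a: np.ndarray, calls_b: np.ndarray,
                  group: str = "", loci: str = "",
                  mc_reps: int = 1000, seed: int = 0) -> TestResult:
    """Genotypic permutation test of linkage disequilibrium between two loci.

    Individuals fully typed at both loci form a genotype-by-genotype
    contingency table; the G statistic is compared to its permutation null
    obtained by shuffling one locus's genotypes across individuals.
    """
    calls_a, calls_b = np.asarray(calls_a), np.asarray(calls_b)
    ok = (calls_a != MISSING).all(axis=1) & (calls_b != MISSING).all(axis=1)
    a, b = calls_a[ok], calls_b[ok]
    if a.shape[0] < 5:
        raise InputError("need >= 5 individuals typed at both loci")
    geno_a = [tuple(sorted(r)) for r in a]
    geno_b = [tuple(sorted(r)) for r in b]
    cats_a = {g: i for i, g in enumerate(dict.fromkeys(geno_a))}
    cats_b = {g: i for i, g in enumerate(dict.fromkeys(geno_b))}
    c1 = np.array([cats_a[g] for g in geno_a])
    c2 = np.array([cats_b[g] for g in geno_b])
    k1, k2 = len(cats_a), len(cats_b)
    g_obs = _g_statistic(c1, c2, k1, k2)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = c2.copy()
    for _ in range(mc_reps):
        rng.shuffle(perm)
        if _g_statistic(c1, perm, k1, k2) >= g_obs - 1e-10:
            hits += 1
    p = (hits + 1) / (mc_reps + 1)
    return TestResult("ld", loci, group, p, "monte-carlo", mc_reps, seed)


# ---------------------------------------------------------------------------
# Multiple-testing correction and descriptive counts
# ---------------------------------------------------------------------------

def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1].tolist()


def adjust_family(results: Sequence[TestResult]) -> list[TestResult]:
    """Attach Holm-adjusted p-values to a family of test results."""
    adj = holm_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return list(results)


def count_polymorphic_loci(genotypes: GenotypeTable,
                           group: str | None = None) -> int:
    """Number of loci with >= 2 observed alleles (within ``group`` if given)."""
    table = genotypes.subset(group) if group is not None else genotypes
    count = 0
    for j in range(table.n_loci):
        col = table.calls[:, j, :]
        if np.unique(col[col != MISSING]).size >= 2:
            count += 1
    return count


def count_haplotypes(alignment: HaplotypeAlignment,
                     group: str | None = None,
                     collapse_ambiguous: bool = False) -> dict[str, int]:
    """Distinct full-length haplotypes per group.

    With ``collapse_ambiguous``, columns containing any N/- are removed
    before comparing, so sequences differing only at no-information sites
    collapse to one haplotype.
    """
    by_group = alignment.by_group()
    if group is not None:
        if group not in by_group:
            raise InputError(f"group {group!r} not present")
        by_group = {group: by_group[group]}
    if collapse_ambiguous:
        keep = [i for i in range(alignment.length)
                if all(s[i] in "ACGT" for s in alignment.sequences)]
        by_group = {g: ["".join(s[i] for i in keep) for s in seqs]
                    for g, seqs in by_group.items()}
    return {g: len(set(seqs)) for g, seqs in by_group.items()}
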