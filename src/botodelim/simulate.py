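"""Synthetic genotype and sequence generators.

The generators emulate the statistical structure of the study system — a
genus of river dolphins with three drift-diverged populations — so that
every downstream stage (clustering, ordination, QC, diagnostic-site
analysis, tree building, dating) can be exercised offline.

* Microsatellites: K populations whose per-locus allele frequencies are
  drawn around shared ancestral frequencies from the Balding–Nichols
  distribution with differentiation parameter F (the "correlated allele
  frequencies" model the clustering stage assumes).  No mutation process is
  modelled; populations differ by drift only.
* mtDNA: three lineages related as ((A,B):T1, C):T2 evolving by a
  Jukes–Cantor substitution kernel at a fixed clock rate, with
  within-lineage diversity injected as independent terminal-branch
  mutations (a star-like within-group genealogy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import MISSING, GenotypeTable, HaplotypeAlignment, InputError

_BASES = np.array(list("ACGT"))


class ParameterError(ValueError):
    """Raised when a generator spec violates its parameter constraints."""


# ---------------------------------------------------------------------------
# Microsatellite genotypes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPopSpec:
    """Parameters for the K-population microsatellite generator.

    Parameters
    ----------
    sample_sizes
        Individuals per population; the study design is (45, 44, 32).
    ancestral_freqs
        One allele-frequency vector per locus (each summing to 1); these are
        the shared ancestral frequencies of the F-model.
    drift
        Balding–Nichols differentiation parameter F in [0, 1); group
        frequencies are Dirichlet(p * (1-F)/F) around the ancestral p.
    admixture_alpha
        Dirichlet concentration for individual ancestry; 0 means every
        individual is purely from its own population.
    missing_rate
        Proportion of genotype cells set to the missing sentinel.
    """

    sample_sizes: tuple[int, ...] = (45, 44, 32)
    ancestral_freqs: Sequence[np.ndarray] = ()
    drift: float = 0.15
    admixture_alpha: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    group_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.sample_sizes):
            raise ParameterError("sample sizes must be >= 1")
        if not (0.0 <= self.drift < 1.0):
            raise ParameterError("drift F must lie in [0, 1)")
        if self.admixture_alpha < 0:
            raise ParameterError("admixture alpha must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing rate must lie in [0, 1)")
        self.ancestral_freqs = [np.asarray(p, dtype=float) for p in self.ancestral_freqs]
        for j, p in enumerate(self.ancestral_freqs):
            if p.ndim != 1 or len(p) < 1 or np.any(p < 0):
                raise ParameterError(f"locus {j}: invalid frequency vector")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ParameterError(f"locus {j}: frequencies sum to {p.sum()}, not 1")
        if not self.group_names:
            self.group_names = tuple(f"pop{k+1}" for k in range(len(self.sample_sizes)))
        if len(self.group_names) != len(self.sample_sizes):
            raise ParameterError("group_names length != number of populations")

    @property
    def n_groups(self) -> int:
        return len(self.sample_sizes)

    @property
    def n_loci(self) -> int:
        return len(self.ancestral_freqs)


def study_design_pop_spec(seed: int = 0, drift: float = 0.15,
                        admixture_alpha: float = 0.0,
                        n_loci: int = 10,
                        missing_rate: float = 0.0) -> SyntheticPopSpec:
    """Study-design spec: 3 populations of 45/44/32 individuals, 10 loci.

    Ancestral allele frequencies are drawn once (from ``seed``) as
    flat-Dirichlet vectors over 4–8 alleles per locus, a typical
    microsatellite allele richness.
    """
    rng = np.random.default_rng(seed)
    freqs = []
    for _ in range(n_loci):
        k = int(rng.integers(4, 9))
        freqs.append(rng.dirichlet(np.ones(k)))
    return SyntheticPopSpec(
        sample_sizes=(45, 44, 32),
        ancestral_freqs=freqs,
        drift=drift,
        admixture_alpha=admixture_alpha,
        missing_rate=missing_rate,
        seed=seed,
        group_names=("boliviensis", "geoffrensis", "araguaiaensis"),
    )


def balding_nichols_freqs(p: np.ndarray, F: float, n_groups: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw per-group allele frequencies around ancestral ``p``.

    Each group's vector is Dirichlet(p * (1-F)/F); the across-group variance
    of each allele frequency is F * p * (1-p).  F = 0 returns ``p`` for all
    groups (no drift).
    """
    if F == 0.0:
        return np.tile(p, (n_groups, 1))
    conc = p * (1.0 - F) / F
    # Dirichlet via independent gammas so zero-frequency alleles stay zero
    g = rng.gamma(np.tile(conc, (n_groups, 1)))
    tot = g.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return g / tot


def simulate_microsatellite_genotypes(spec: SyntheticPopSpec) -> GenotypeTable:
    """Generate a diploid genotype table under the F-model.

    Allele labels are microsatellite-like fragment sizes (100 + 2*index).
    Bit-reproducible for a fixed spec.
    """
    if spec.n_loci == 0:
        raise ParameterError("spec has no loci")
    rng = np.random.default_rng(spec.seed)
    K, L = spec.n_groups, spec.n_loci
    n_total = sum(spec.sample_sizes)

    group_freqs = [balding_nichols_freqs(p, spec.drift, K, rng)
                   for p in spec.ancestral_freqs]  # per locus: (K, n_alleles)

    origin = np.repeat(np.arange(K), spec.sample_sizes)
    if spec.admixture_alpha > 0:
        q = rng.dirichlet(np.full(K, spec.admixture_alpha), size=n_total)
    else:
        q = np.eye(K)[origin]

    calls = np.empty((n_total, L, 2), dtype=np.int64)
    for j in range(L):
        freqs = group_freqs[j]
        n_alleles = freqs.shape[1]
        labels = 100 + 2 * np.arange(n_alleles)
        for c in (0, 1):
            # each allele copy picks a source population, then an allele
            src = (q.cumsum(axis=1) > rng.random((n_total, 1))).argmax(axis=1)
            u = rng.random(n_total)
            idx = (freqs[src].cumsum(axis=1) > u[:, None]).argmax(axis=1)
            calls[:, j, c] = labels[idx]
    if spec.missing_rate > 0:
        mask = rng.random((n_total, L)) < spec.missing_rate
        calls[mask] = MISSING

    ids = [f"{spec.group_names[k]}_{i+1:03d}"
           for k in range(K) for i in range(spec.sample_sizes[k])]
    groups = [spec.group_names[k] for k in range(K) for _ in range(spec.sample_sizes[k])]
    return GenotypeTable(ids, [f"L{j+1:02d}" for j in range(L)], calls, groups)


# ---------------------------------------------------------------------------
# Sequence alignments
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSeqSpec:
    """Parameters for the three-lineage mtDNA alignment generator.

    ``split_times`` are the two node ages (T1, T2) in My of the rooted tree
    ((A,B):T1, C):T2; ``rate`` is the clock rate in substitutions/site/yr,
    so a pair split T years ago has expected divergence ~ 2*rate*T.
    ``within_theta`` is the expected within-lineage pairwise diversity.
    """

    split_times: tuple[float, float] = (2.08, 2.87)
    rate: float = 1.01e-8
    seq_length: int = 1140
    samples_per_lineage: tuple[int, int, int] = (8, 8, 8)
    within_theta: float = 0.002
    seed: int = 0
    lineage_names: tuple[str, str, str] = ("A", "B", "C")

    def __post_init__(self) -> None:
        t1, t2 = self.split_times
        if not (0 < t1 < t2):
            raise ParameterError("need 0 < T1 < T2 (ages in My)")
        if self.rate < 0:
            raise ParameterError("rate must be >= 0")
        if self.seq_length < 1:
            raise ParameterError("sequence length must be >= 1")
        if any(n < 1 for n in self.samples_per_lineage):
            raise ParameterError("need >= 1 sample per lineage")
        if self.within_theta < 0:
            raise ParameterError("within_theta must be >= 0")


def _jc_evolve(seq: np.ndarray, branch: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve one branch of length ``branch`` (expected subs/site) under JC69.

    Exact site-wise transition: a site differs from its ancestor with
    probability (3/4)(1 - exp(-4d/3)), landing uniformly on the other bases.
    """
    if branch <= 0:
        return seq.copy()
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * branch / 3.0))
    hit = rng.random(seq.size) < p_diff
    out = seq.copy()
    # shift by 1..3 mod 4 gives a uniform draw over the three other bases
    out[hit] = (seq[hit] + rng.integers(1, 4, hit.sum())) % 4
    return out


def simulate_sequence_alignment(spec: SyntheticSeqSpec) -> HaplotypeAlignment:
    """Generate aligned haplotypes for three lineages under a strict clock.

    The root sequence is uniform over ACGT; trunk branches follow the tree
    ((A,B):T1, C):T2 scaled to expected substitutions/site by ``rate``;
    each sampled individual then receives independent terminal mutations at
    theta/2 per site so within-lineage pairwise diversity ~ within_theta.
    """
    rng = np.random.default_rng(spec.seed)
    t1, t2 = (t * 1e6 for t in spec.split_times)  # My -> years
    r = spec.rate
    root = rng.integers(0, 4, spec.seq_length)
    anc_ab = _jc_evolve(root, r * (t2 - t1), rng)
    trunk = {
        spec.lineage_names[0]: _jc_evolve(anc_ab, r * t1, rng),
        spec.lineage_names[1]: _jc_evolve(anc_ab, r * t1, rng),
        spec.lineage_names[2]: _jc_evolve(root, r * t2, rng),
    }
    ids, groups, seqs = [], [], []
    for name, n in zip(spec.lineage_names, spec.samples_per_lineage):
        for i in range(n):
            tip = _jc_evolve(trunk[name], spec.within_theta / 2.0, rng)
            ids.append(f"{name}|{i+1:02d}")
            groups.append(name)
            seqs.append("".join(_BASES[tip]))
    return HaplotypeAlignment(ids, groups, seqs)
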