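"""Tree-based lineage evidence and desk-scale divergence dating.

Distances (p, JC69, K80) from aligned haplotypes, neighbor-joining trees,
Fitch parsimony scores, nonparametric bootstrap support for group
monophyly, offset-lognormal fossil-calibration priors, strict-clock
least-squares dating on a fixed rooted topology, and divergence/rate/time
arithmetic.

The dating step fits a global clock rate r and ultrametric node ages t to
pairwise distances by least squares, minimising sum over pairs of
(d_ij - 2 r t_MRCA(i,j))^2 with the root age fixed by a calibration.  For
clock-like (additive ultrametric) input the fit is exact.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy import stats

from .containers import HaplotypeAlignment, InputError

#: sentinel distance for saturated pairs (p >= 3/4 under JC69)
SATURATED = math.inf

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class OptimizationError(RuntimeError):
    """Raised when clock dating cannot satisfy its constraints."""


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in substitutions/site."""

    taxa: list[str]
    values: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise InputError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.values), 0.0):
            raise InputError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise InputError("matrix must be symmetric")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise InputError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join([""] + self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write("\t".join([t] + [f"{x:.10g}" for x in self.values[i]]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, model: str = "p") -> "DistanceMatrix":
        with open(path) as fh:
            taxa = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [line.rstrip("\n").split("\t")[1:] for line in fh if line.strip()]
        return cls(taxa, np.array(rows, dtype=float), model)


def _pair_distance(s1: str, s2: str, model: str) -> float:
    ts = tv = same = 0
    for a, b in zip(s1, s2):
        if a not in "ACGT" or b not in "ACGT":
            continue
        if a == b:
            same += 1
        elif (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    sites = same + ts + tv
    if sites < 1:
        raise InputError("no pairwise complete sites")
    p = (ts + tv) / sites
    if model == "p":
        return p
    if model == "JC69":
        if p >= 0.75:
            return SATURATED
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    if model == "K80":
        P, Q = ts / sites, tv / sites
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            return SATURATED
        return -0.5 * math.log(w1 * math.sqrt(w2))
    raise InputError(f"unknown model {model!r}")


def pairwise_distance(alignment: HaplotypeAlignment,
                      model: str = "JC69") -> DistanceMatrix:
    """All-pairs evolutionary distances; gap/ambiguous sites dropped pairwise.

    Saturated pairs (p >= 3/4 under JC69, or a non-positive K80 log
    argument) receive an infinite sentinel.
    """
    n = alignment.n
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(
                alignment.sequences[i], alignment.sequences[j], model)
    return DistanceMatrix(list(alignment.ids), d, model)


# ---------------------------------------------------------------------------
# Neighbor joining and parsimony
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted) from a distance matrix.

    On an additive matrix the generating topology and branch lengths are
    recovered exactly.
    """
    if len(D.taxa) < 3:
        raise InputError("need >= 3 taxa")
    if not np.all(np.isfinite(D.values)):
        raise InputError("non-finite distances (saturated pairs?)")
    buf = io.StringIO()
    buf.write("," + ",".join(D.taxa) + "\n")
    for i, t in enumerate(D.taxa):
        buf.write(t + "," + ",".join(f"{x:.12g}" for x in D.values[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    tree.is_rooted = False
    return tree


def fitch_score(tree: dendropy.Tree, alignment: HaplotypeAlignment) -> int:
    """Fitch parsimony length of the alignment on the given tree.

    Gaps and ambiguity codes behave as fully missing (the universal state
    set) and never contribute changes.
    """
    seq_by_id = dict(zip(alignment.ids, alignment.sequences))
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(alignment.ids):
        raise InputError("tree tips do not match alignment ids")
    full = frozenset("ACGT")
    total = 0
    for s in range(alignment.length):
        changes = 0
        state: dict[int, frozenset] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                ch = seq_by_id[node.taxon.label][s]
                state[id(node)] = frozenset(ch) if ch in "ACGT" else full
            else:
                sets = [state[id(c)] for c in node.child_nodes()]
                inter = frozenset.intersection(*sets)
                if inter:
                    state[id(node)] = inter
                else:
                    # pairwise Fitch fold for possibly multifurcating nodes
                    acc = sets[0]
                    for nxt in sets[1:]:
                        both = acc & nxt
                        if both:
                            acc = both
                        else:
                            acc = acc | nxt
                            changes += 1
                    state[id(node)] = acc
        total += changes
    return total


@dataclass
class MonophylyResult:
    """Bootstrap support for the monophyly of each labelled group."""

    support: dict[str, float]
    reps: int
    seed: int
    trivial_groups: tuple[str, ...] = ()   # singletons (support 1 by definition)
    no_signal: bool = False                # all distances zero in the data


def _group_bitmask(tns: dendropy.TaxonNamespace, members: set[str]) -> int:
    mask = 0
    for taxon in tns:
        if taxon.label in members:
            mask |= tns.taxon_bitmask(taxon)
    return mask


def is_monophyletic(tree: dendropy.Tree, members: set[str]) -> bool:
    """Whether a taxon set forms one side of some bipartition (unrooted)."""
    tns = tree.taxon_namespace
    target = _group_bitmask(tns, members)
    full = tns.all_taxa_bitmask()
    for edge in tree.encode_bipartitions():
        leafset = edge.leafset_bitmask
        if leafset == target or (full ^ leafset) == target:
            return True
    return False


def bootstrap_monophyly(alignment: HaplotypeAlignment, reps: int = 100,
                        seed: int = 0, model: str = "JC69") -> MonophylyResult:
    """Site-resampled NJ bootstrap support for each group's monophyly.

    Support is the fraction of bootstrap replicates in which the group's
    sequences form one side of a bipartition.  Size-1 groups are trivially
    monophyletic and flagged as such.  Data with no variation at all are
    flagged ``no_signal`` (every replicate then yields an arbitrary
    zero-length topology).
    """
    groups = alignment.group_names()
    if len(groups) < 2:
        raise InputError("need >= 2 groups")
    if reps < 1:
        raise InputError("need >= 1 bootstrap replicate")
    members = {g: {i for i, gg in zip(alignment.ids, alignment.groups) if gg == g}
               for g in groups}
    trivial = tuple(g for g in groups if len(members[g]) == 1)
    base = pairwise_distance(alignment, "p")
    no_signal = bool(np.all(base.values == 0.0))
    rng = np.random.default_rng(seed)
    hits = {g: 0 for g in groups}
    L = alignment.length
    for _ in range(reps):
        cols = rng.integers(0, L, L)
        res = HaplotypeAlignment(
            list(alignment.ids), list(alignment.groups),
            ["".join(s[c] for c in cols) for s in alignment.sequences])
        D = pairwise_distance(res, model)
        if not np.all(np.isfinite(D.values)):
            D = pairwise_distance(res, "p")   # fall back for saturated pairs
        tree = neighbor_joining(D)
        for g in groups:
            if g in trivial or is_monophyletic(tree, members[g]):
                hits[g] += 1
    return MonophylyResult({g: hits[g] / reps for g in groups}, reps, seed,
                           trivial, no_signal)


# ---------------------------------------------------------------------------
# Fossil calibrations
# ---------------------------------------------------------------------------

#: one-sided 95% standard-normal quantile
Z_95 = 1.6448536269514722


@dataclass(frozen=True)
class CalibrationPrior:
    """Offset-lognormal node-age prior.

    Support is [offset, inf): ``offset`` is the youngest fossil age (My);
    the lognormal tail (log-location mu, log-sd sigma) is chosen so that an
    older bounding fossil age sits at the chosen one-sided credible level.
    """

    name: str
    offset: float          # youngest fossil age, My
    mu: float              # log-location
    sigma: float           # log-sd
    old: float             # bounding older age, My
    z: float = Z_95

    def _dist(self):
        return stats.lognorm(s=self.sigma, scale=math.exp(self.mu),
                             loc=self.offset)

    def quantile(self, q: float) -> float:
        return float(self._dist().ppf(q))

    def cdf(self, age: float) -> float:
        return float(self._dist().cdf(age))

    def pdf(self, age: float) -> float:
        return float(self._dist().pdf(age))

    def to_dict(self) -> dict:
        return {"name": self.name, "offset": self.offset, "mu": self.mu,
                "sigma": self.sigma, "old": self.old, "z": self.z}


def build_calibration(name: str, young: float, old: float,
                      sd: float | None = None, z: float = Z_95) -> CalibrationPrior:
    """Construct an offset-lognormal calibration from two fossil ages.

    The prior's support starts at ``young``.  Given a log-sd ``sd``, the
    log-location is solved as mu = ln(old - young) - z*sd so the quantile
    at the one-sided level (z = 1.645 for 95%) equals ``old``.  Without
    ``sd``, sigma is solved with mu = 0.
    """
    if not (0 < young < old):
        raise InputError("need 0 < young < old")
    span = old - young
    if sd is not None:
        if sd <= 0:
            raise InputError("sd must be positive")
        mu, sigma = math.log(span) - z * sd, sd
    else:
        mu, sigma = 0.0, math.log(span) / z
        if sigma <= 0:
            raise InputError("old - young must exceed 1 My to solve sigma with mu=0")
    return CalibrationPrior(name, young, mu, sigma, old, z)


def default_calibrations() -> list[CalibrationPrior]:
    """The four cetacean fossil calibrations used for the dating analysis.

    (young fossil age, older 95%-CI bound, log-sd), all in My:
    Mysticeti-Odontoceti 33.5->40 (1.068); crown Odontoceti 23.7->30
    (1.135); Iniidae-Pontoporiidae 11.2->16.6 (1.223);
    Phocoenidae-Monodontidae 10->11.2 (1.061).
    """
    specs = [("mysticeti_odontoceti", 33.5, 40.0, 1.068),
             ("crown_odontoceti", 23.7, 30.0, 1.135),
             ("iniidae_pontoporiidae", 11.2, 16.6, 1.223),
             ("phocoenidae_monodontidae", 10.0, 11.2, 1.061)]
    return [build_calibration(n, y, o, sd) for n, y, o, sd in specs]


# ---------------------------------------------------------------------------
# Strict-clock least-squares dating
# ---------------------------------------------------------------------------

@dataclass
class DatingResult:
    """Fitted ultrametric node ages (My) and global clock rate."""

    node_heights: dict[tuple[str, ...], float]   # clade tip labels -> age
    rate: float            # substitutions/site per unit of the root-age scale
    rss: float
    clipped: tuple[tuple[str, ...], ...] = ()    # nodes adjusted for monotonicity

    def height_of(self, tips: Sequence[str]) -> float:
        return self.node_heights[tuple(sorted(tips))]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "rate": self.rate, "rss": self.rss,
            "node_heights": {";".join(k): v for k, v in self.node_heights.items()},
            "clipped": [";".join(k) for k in self.clipped]}, indent=2))


def three_lineage_tree(names: Sequence[str]) -> dendropy.Tree:
    """Rooted topology ((A,B),C) over three labelled tip sets or tips."""
    a, b, c = names
    return dendropy.Tree.get(data=f"(({a},{b}),{c});", schema="newick")


def strict_clock_dating(D: DistanceMatrix, topology: dendropy.Tree,
                        root_age: float) -> DatingResult:
    """Least-squares strict-clock dating on a fixed rooted topology.

    Each internal node m gets u_m = mean(d_ij)/2 over pairs whose MRCA is
    m (the least-squares solution of sum (d_ij - 2 u_m)^2); the root age
    calibration converts u to ages via r = u_root / root_age.  Child ages
    exceeding their parent's are clipped down (flagged); a root with zero
    fitted height is an error.
    """
    if root_age <= 0:
        raise InputError("root age must be positive")
    if not np.all(np.isfinite(D.values)):
        raise InputError("non-finite distances")
    tree = topology
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if set(tips) - set(D.taxa):
        raise InputError("topology tips missing from distance matrix")
    # leaf sets per node
    leafset: dict[int, list[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[id(node)] = [node.taxon.label]
        else:
            leafset[id(node)] = sum((leafset[id(c)] for c in node.child_nodes()), [])
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    u: dict[int, float] = {}
    for node in internal:
        children = node.child_nodes()
        ds = []
        for x in range(len(children)):
            for y in range(x + 1, len(children)):
                for ti in leafset[id(children[x])]:
                    for tj in leafset[id(children[y])]:
                        ds.append(D.get(ti, tj))
        u[id(node)] = float(np.mean(ds)) / 2.0 if ds else 0.0
    root = tree.seed_node
    if u[id(root)] <= 0:
        raise OptimizationError(
            "fitted root height is zero; distances carry no between-clade signal")
    rate = u[id(root)] / root_age
    clipped: list[tuple[str, ...]] = []
    heights: dict[tuple[str, ...], float] = {}
    # enforce parent >= child top-down
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        h = u[id(node)] / rate
        parent = node.parent_node
        if parent is not None:
            hp = heights[tuple(sorted(leafset[id(parent)]))]
            if h > hp:
                h = hp
                clipped.append(tuple(sorted(leafset[id(node)])))
        heights[tuple(sorted(leafset[id(node)]))] = h
    rss = 0.0
    for node in internal:
        key = tuple(sorted(leafset[id(node)]))
        children = node.child_nodes()
        for x in range(len(children)):
            for y in range(x + 1, len(children)):
                for ti in leafset[id(children[x])]:
                    for tj in leafset[id(children[y])]:
                        rss += (D.get(ti, tj) - 2.0 * rate * heights[key]) ** 2
    return DatingResult(heights, rate, rss, tuple(clipped))


def rate_time_convert(d: float | None = None, T: float | None = None,
                      r: float | None = None) -> float:
    """Convert between pairwise divergence d, split time T and clock rate r.

    Exactly two of (d, T, r) must be given; the third is returned using
    d = 2 r T (T in years, r in substitutions/site/yr).
    """
    given = [x is not None for x in (d, T, r)]
    if sum(given) != 2:
        raise InputError("give exactly two of d, T, r")
    if r is None:
        if T <= 0:
            raise InputError("T must be positive")
        return d / (2.0 * T)
    if T is None:
        if r <= 0:
            raise InputError("r must be positive")
        return d / (2.0 * r)
    return 2.0 * r * T
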