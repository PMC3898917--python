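"""Bayesian admixture-model clustering of multilocus genotypes.

A desk-scale Gibbs sampler for the admixture model with correlated allele
frequencies (the F-model): each individual i has ancestry proportions
q_i over K clusters, each allele copy is assigned a cluster of origin z,
and cluster allele frequencies P are drawn around shared ancestral
frequencies with drift parameter F (a Balding–Nichols / Dirichlet prior
with concentration p_ancestral * (1-F)/F).

Model support for a given K is summarised from the post-burn-in
log-likelihood trace as  LnP(K) = mean(lnL) - var(lnL)/2  (the harmonic-
style estimator tabulated by the standard clustering software), and a
posterior over K follows by Bayes' Rule with a user prior (uniform by
default).  Replicate runs are reconciled by an exact search over cluster-
label permutations (label switching), and individuals are classified as
admixed or not by their modal ancestry coefficient.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .containers import MISSING, GenotypeTable, InputError
from .fixtures import LnPTable


class ParameterError(ValueError):
    """Raised for invalid sampler or classification parameters."""


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class ClusterRun:
    """One MCMC run of the admixture sampler at a fixed K."""

    K: int
    Q: np.ndarray                      # (n, K) posterior-mean ancestry
    P: list[np.ndarray]                # per locus: (K, n_alleles) mean freqs
    allele_labels: list[np.ndarray]    # per locus: observed allele labels
    lnL_trace: np.ndarray              # post-burn-in log-likelihood samples
    lnP: float                         # mean - var/2 model support
    alpha_trace: np.ndarray
    seed: int
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows = self.Q.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ParameterError("Q rows must sum to 1")

    def save_q(self, path: str | Path, ids: Sequence[str] | None = None) -> None:
        import pandas as pd
        df = pd.DataFrame(self.Q, columns=[f"cluster{k+1}" for k in range(self.K)])
        df.insert(0, "id", list(ids) if ids is not None else range(len(df)))
        df.to_csv(path, sep="\t", index=False)


@dataclass
class KPosterior:
    """Posterior distribution over the number of biological groups."""

    K: tuple[int, ...]
    mean_lnP: tuple[float, ...]
    posterior: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.posterior) - 1.0) > 1e-12:
            raise ParameterError("posterior must sum to 1")

    @property
    def modal_K(self) -> int:
        return self.K[int(np.argmax(self.posterior))]

    def probability(self, k: int) -> float:
        return self.posterior[self.K.index(k)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "K": list(self.K),
            "mean_lnP": list(self.mean_lnP),
            "posterior": list(self.posterior),
            "modal_K": self.modal_K}, indent=2))


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _index_alleles(genotypes: GenotypeTable):
    """Map allele labels to 0-based indices per locus; -1 marks missing."""
    idx = np.full(genotypes.calls.shape, -1, dtype=np.int64)
    labels: list[np.ndarray] = []
    for j in range(genotypes.n_loci):
        col = genotypes.calls[:, j, :]
        obs = np.unique(col[col != MISSING])
        if obs.size == 0:
            raise InputError(f"locus {genotypes.loci[j]!r} has no observed alleles")
        labels.append(obs)
        lookup = {a: i for i, a in enumerate(obs)}
        for a, i in lookup.items():
            idx[:, j, :][col == a] = i
    return idx, labels


def gibbs_admixture(genotypes: GenotypeTable, K: int,
                    iters: int = 12_000, burn_in: int = 2_000,
                    seed: int = 0, *,
                    alpha_init: float = 1.0, F_init: float = 0.05,
                    infer_alpha: bool = True,
                    alpha_max: float = 10.0,
                    alpha_step: float = 0.25) -> ClusterRun:
    """Run the admixture-model Gibbs sampler at a fixed number of clusters.

    Each sweep cycles: (i) cluster-of-origin assignments z for every allele
    copy given (Q, P); (ii) cluster allele frequencies P from their F-model
    Dirichlet full conditional; (iii) ancestry rows Q ~ Dirichlet(alpha +
    copy counts); (iv) optionally the ancestry concentration alpha by
    random-walk Metropolis under a Uniform(0, alpha_max) prior.  The
    log-likelihood of the data under (Q, P) is recorded every sweep;
    post-burn-in samples form ``lnL_trace``.

    Ancestral frequencies of the F-model are the pooled sample frequencies,
    held fixed throughout; F is fixed at ``F_init``.
    """
    if K < 1:
        raise InputError("K must be >= 1")
    if not iters > burn_in >= 0:
        raise InputError("need iters > burn_in >= 0")
    rng = np.random.default_rng(seed)
    idx, labels = _index_alleles(genotypes)
    n, L = genotypes.n, genotypes.n_loci
    observed = idx >= 0                       # (n, L, 2)

    # pooled (ancestral) frequencies and F-model prior concentrations
    lam: list[np.ndarray] = []
    for j in range(L):
        a = idx[:, j, :][observed[:, j, :]]
        counts = np.bincount(a, minlength=len(labels[j])).astype(float)
        p_anc = counts / counts.sum()
        lam.append(np.maximum(p_anc, 1e-6) * (1.0 - F_init) / F_init)

    # initial state
    Q = rng.dirichlet(np.ones(K), size=n)
    P = [rng.dirichlet(np.ones(len(lab)), size=K) for lab in labels]
    alpha = float(alpha_init)

    keep = iters - burn_in
    lnL_trace = np.empty(keep)
    alpha_trace = np.empty(keep)
    Q_sum = np.zeros((n, K))
    P_sum = [np.zeros_like(p) for p in P]
    kept = 0

    arange_n = np.arange(n)
    for sweep in range(iters):
        copy_counts = np.zeros((n, K))
        lnL = 0.0
        for j in range(L):
            obs_j = observed[:, j, :]
            a_j = idx[:, j, :]
            # membership weights for each copy: (K, n, 2)
            Pa = P[j][:, np.where(obs_j, a_j, 0)]      # (K, n, 2)
            W = Q.T[:, :, None] * Pa
            tot = W.sum(axis=0)
            tot_safe = np.where(tot > 0, tot, 1.0)
            lnL += float(np.log(tot_safe[obs_j]).sum())
            if K > 1:
                u = rng.random((n, 2))
                z = ((W / tot_safe).cumsum(axis=0) > u).argmax(axis=0)  # (n, 2)
            else:
                z = np.zeros((n, 2), dtype=np.int64)
            # allele counts per cluster for the P update
            acounts = np.zeros((K, len(labels[j])))
            for c in (0, 1):
                m = obs_j[:, c]
                np.add.at(acounts, (z[m, c], a_j[m, c]), 1.0)
                np.add.at(copy_counts, (arange_n[m], z[m, c]), 1.0)
            g = rng.gamma(lam[j][None, :] + acounts)
            P[j] = g / g.sum(axis=1, keepdims=True)
        # Q update
        g = rng.gamma(alpha + copy_counts)
        gs = g.sum(axis=1, keepdims=True)
        gs[gs == 0] = 1.0
        Q = g / gs
        Q = np.clip(Q, 1e-300, None)
        Q /= Q.sum(axis=1, keepdims=True)
        # alpha update (random-walk Metropolis, Uniform(0, alpha_max) prior)
        if infer_alpha and K > 1:
            prop = alpha + rng.normal(0.0, alpha_step)
            if 0.0 < prop <= alpha_max:
                S = np.log(Q).sum()
                d = n * (gammaln(K * prop) - K * gammaln(prop)
                         - gammaln(K * alpha) + K * gammaln(alpha))
                d += (prop - alpha) * S
                if np.log(rng.random()) < d:
                    alpha = prop
        if sweep >= burn_in:
            lnL_trace[kept] = lnL
            alpha_trace[kept] = alpha
            Q_sum += Q
            for j in range(L):
                P_sum[j] += P[j]
            kept += 1

    Q_mean = Q_sum / keep
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    P_mean = [ps / keep for ps in P_sum]
    lnP = estimate_lnP(lnL_trace)
    return ClusterRun(
        K=K, Q=Q_mean, P=P_mean, allele_labels=labels,
        lnL_trace=lnL_trace, lnP=lnP, alpha_trace=alpha_trace, seed=seed,
        options={"iters": iters, "burn_in": burn_in, "alpha_init": alpha_init,
                 "F_init": F_init, "infer_alpha": infer_alpha})


# ---------------------------------------------------------------------------
# Model support and Bayes' Rule over K
# ---------------------------------------------------------------------------

def estimate_lnP(lnL_trace: Sequence[float]) -> float:
    """Model support from a log-likelihood trace: mean - sample variance / 2."""
    trace = np.asarray(lnL_trace, dtype=float)
    if trace.size < 2:
        raise InputError("trace must have length >= 2")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def bayes_rule_K(table: LnPTable | Mapping[int, float],
                 prior: Mapping[int, float] | None = None) -> KPosterior:
    """Posterior over K from mean LnP(K) values via Bayes' Rule.

    posterior(K) ∝ prior(K) * exp(lnP(K)), computed after subtracting the
    maximum lnP for numerical stability.  The prior defaults to uniform.
    """
    if isinstance(table, LnPTable):
        ks, lnp = list(table.K), list(table.mean_lnP)
    else:
        ks = sorted(table)
        lnp = [table[k] for k in ks]
    if not ks:
        raise InputError("no K values supplied")
    lnp_arr = np.asarray(lnp, dtype=float)
    if not np.all(np.isfinite(lnp_arr)):
        raise InputError("non-finite lnP values")
    if prior is None:
        w = np.ones(len(ks))
    else:
        w = np.asarray([prior[k] for k in ks], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise InputError("invalid prior weights")
    log_post = np.log(w) + (lnp_arr - lnp_arr.max())
    post = np.exp(log_post)
    post /= post.sum()
    # exact renormalisation so the tuple sums to 1 at float precision
    post[np.argmax(post)] += 1.0 - post.sum()
    return KPosterior(tuple(ks), tuple(lnp_arr), tuple(post))


# ---------------------------------------------------------------------------
# Label alignment across replicate runs
# ---------------------------------------------------------------------------

def align_runs(runs: Sequence[ClusterRun] | Sequence[np.ndarray],
               max_exact_K: int = 8):
    """Align cluster labels of replicate runs to the first run.

    For each run the permutation of cluster columns maximising the
    Frobenius inner product <Q_ref, Q_perm> is found by exhaustive search
    over all K! permutations (exact for K <= ``max_exact_K``).

    Returns ``(aligned, consensus, permutations)`` where ``aligned`` is the
    list of permuted Q matrices and ``consensus`` their element-wise mean.
    """
    qs = [r.Q if isinstance(r, ClusterRun) else np.asarray(r, dtype=float)
          for r in runs]
    if not qs:
        raise InputError("no runs to align")
    K = qs[0].shape[1]
    if any(q.shape != qs[0].shape for q in qs):
        raise InputError("all runs must share K and individual order")
    if K > max_exact_K:
        raise InputError(f"exact permutation search limited to K <= {max_exact_K}")
    ref = qs[0]
    aligned = [ref]
    perms: list[tuple[int, ...]] = [tuple(range(K))]
    for q in qs[1:]:
        best, best_score = None, -np.inf
        for perm in itertools.permutations(range(K)):
            score = float(np.sum(ref * q[:, perm]))
            if score > best_score:
                best, best_score = perm, score
        aligned.append(q[:, best])
        perms.append(best)
    consensus = np.mean(aligned, axis=0)
    return aligned, consensus, perms


def classify_admixed(Q: np.ndarray, threshold: float = 0.90,
                     ids: Sequence[str] | None = None):
    """Classify individuals as admixed or not by their modal ancestry q.

    An individual is non-admixed when its largest ancestry proportion
    exceeds ``threshold`` (the conventional 90% rule).  Ties go to the
    lowest cluster index.
    """
    import pandas as pd
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must lie in (0, 1)")
    Q = np.asarray(Q, dtype=float)
    modal = Q.argmax(axis=1)
    qmax = Q[np.arange(len(Q)), modal]
    return pd.DataFrame({
        "id": list(ids) if ids is not None else list(range(len(Q))),
        "modal_cluster": modal + 1,
        "q": qmax,
        "status": np.where(qmax > threshold, "non-admixed", "admixed"),
    })


# ---------------------------------------------------------------------------
# Convergence diagnostic
# ---------------------------------------------------------------------------

def geweke_z(trace: Sequence[float], first: float = 0.1, last: float = 0.5) -> float:
    """Geweke-style z-score comparing early and late trace segments.

    |z| well above 2 suggests the chain had not converged over the kept
    portion of the run.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 10:
        raise InputError("trace too short for a Geweke diagnostic")
    a = x[: int(first * x.size)]
    b = x[int((1.0 - last) * x.size):]
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)
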