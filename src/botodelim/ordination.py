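"""Ordination of multilocus genotypes: PCA, correspondence analysis and
group density-contour ellipses.

Genotypes are recoded as allele-dosage indicators (0/1/2 copies of each
observed allele per locus).  PCA operates on the centred dosage matrix;
correspondence analysis (COA) operates on the raw indicator counts under
the chi-square metric, so total inertia equals the Pearson chi-square of
the table divided by its grand total.

Group scatter is summarised by Mahalanobis ellipses.  An ellipse of radius
c around a bivariate-normal cloud covers 1 - exp(-c^2/2) of its density;
the default c = 1.5 gives the 67.53% contour used in the published
ordination figures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import MISSING, GenotypeTable, InputError


@dataclass
class DosageMatrix:
    """Individuals x (locus, allele) indicator counts in {0, 1, 2}."""

    values: np.ndarray                       # (n, m) float; may be imputed
    columns: list[tuple[str, int]]           # (locus, allele label)
    ids: list[str]
    imputed: np.ndarray | None = None        # boolean mask of imputed cells

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def allele_frequencies(self) -> np.ndarray:
        """Sample allele frequency per column, from observed dosages only."""
        vals = self.values.copy()
        counts = np.ones_like(vals)
        if self.imputed is not None:
            counts[self.imputed] = 0.0
            vals[self.imputed] = 0.0
        # frequencies are per locus: sum of dosages / 2*(called individuals)
        freqs = np.empty(vals.shape[1])
        loci = np.array([c[0] for c in self.columns])
        for locus in np.unique(loci):
            cols = np.where(loci == locus)[0]
            called = counts[:, cols[0]].sum()
            freqs[cols] = vals[:, cols].sum(axis=0) / max(2.0 * called, 1.0)
        return freqs


@dataclass
class OrdinationResult:
    """Scores, eigenvalues and per-axis variance/inertia proportions."""

    scores: np.ndarray          # (n, n_axes)
    eigenvalues: np.ndarray     # non-negative, non-increasing
    proportion: np.ndarray
    ids: list[str] = field(default_factory=list)
    method: str = ""

    def to_tsv(self, path: str | Path, n_axes: int | None = None) -> None:
        k = n_axes or self.scores.shape[1]
        df = pd.DataFrame(self.scores[:, :k],
                          columns=[f"axis{i+1}" for i in range(k)])
        df.insert(0, "id", self.ids if self.ids else range(len(df)))
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ClassEllipse:
    """Mahalanobis density-contour ellipse for one group's 2-D scores."""

    group: str
    center: np.ndarray          # (2,)
    covariance: np.ndarray      # (2, 2) symmetric PSD
    scale: float                # Mahalanobis radius c
    coverage: float             # 1 - exp(-c^2/2) under bivariate normality
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (<= c in Mahalanobis)."""
        pts = np.atleast_2d(points) - self.center
        inv = np.linalg.pinv(self.covariance)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= self.scale ** 2

    def to_dict(self) -> dict:
        return {"group": self.group, "center": np.asarray(self.center).tolist(),
                "covariance": np.asarray(self.covariance).tolist(),
                "scale": float(self.scale), "coverage": float(self.coverage),
                "degenerate": bool(self.degenerate)}


# ---------------------------------------------------------------------------

def genotype_dosage(genotypes: GenotypeTable) -> DosageMatrix:
    """Expand a genotype table into per-allele dosage indicators.

    One column per observed allele per locus; a heterozygote contributes
    (1, 1), a homozygote (2, 0).  Missing loci are mean-imputed per column
    (so PCA can use every individual) and flagged in ``imputed``.
    """
    if genotypes.n < 2:
        raise InputError("need >= 2 individuals")
    blocks, columns, masks = [], [], []
    for j, locus in enumerate(genotypes.loci):
        col = genotypes.calls[:, j, :]
        obs = np.unique(col[col != MISSING])
        if obs.size == 0:
            warnings.warn(f"locus {locus!r} has no observed alleles; dropped")
            continue
        block = np.zeros((genotypes.n, obs.size))
        for a_i, a in enumerate(obs):
            block[:, a_i] = (col == a).sum(axis=1)
        miss = (col == MISSING).all(axis=1)
        if miss.any():
            means = block[~miss].mean(axis=0)
            block[miss] = means
        blocks.append(block)
        columns += [(locus, int(a)) for a in obs]
        masks.append(np.tile(miss[:, None], (1, obs.size)))
    if not blocks:
        raise InputError("no typed loci")
    return DosageMatrix(np.hstack(blocks), columns, list(genotypes.ids),
                        np.hstack(masks))


def _orient(scores: np.ndarray, loadings: np.ndarray):
    """Sign convention: largest-|loading| entry of each axis positive."""
    for k in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, k]))
        if loadings[i, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def pca(dosage: DosageMatrix, center: bool = True,
        scale: bool = False) -> OrdinationResult:
    """Principal component analysis of the dosage matrix.

    Eigendecomposition of the (optionally scaled) covariance via SVD of the
    centred data; eigenvalues sum to the total column variance.
    """
    X = dosage.values.astype(float)
    if X.shape[0] < 2:
        raise InputError("need >= 2 individuals")
    mu = X.mean(axis=0)
    Xc = X - mu if center else X.copy()
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (X.shape[0] - 1)
    scores = U * s
    scores, _ = _orient(scores, Vt.T * 1.0)
    total = eig.sum()
    prop = eig / total if total > 0 else np.zeros_like(eig)
    return OrdinationResult(scores, eig, prop, list(dosage.ids), "pca")


def correspondence_analysis(counts: DosageMatrix | np.ndarray) -> OrdinationResult:
    """Correspondence analysis of a non-negative count table.

    SVD of the standardised residuals (P - r c') / sqrt(r c'); total
    inertia equals the Pearson chi-square statistic of the table divided by
    its grand total.  Zero rows/columns are dropped with a warning.
    """
    if isinstance(counts, DosageMatrix):
        N = counts.values.astype(float)
        ids = list(counts.ids)
    else:
        N = np.asarray(counts, dtype=float)
        ids = [str(i) for i in range(N.shape[0])]
    if np.any(N < 0):
        raise InputError("counts must be non-negative")
    total = N.sum()
    if total <= 0:
        raise InputError("table has zero grand total")
    keep_r = N.sum(axis=1) > 0
    keep_c = N.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("zero rows/columns dropped from correspondence analysis")
    N = N[np.ix_(keep_r, keep_c)]
    ids = [i for i, k in zip(ids, keep_r) if k]
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    nz = min(N.shape) - 1
    s = s[:nz] if nz > 0 else s[:0]
    U = U[:, : s.size]
    eig = s ** 2                               # principal inertias
    scores = (U * s) / np.sqrt(r)[:, None]     # row principal coordinates
    scores, _ = _orient(scores, Vt.T[:, : s.size] * 1.0)
    total_inertia = eig.sum()
    prop = eig / total_inertia if total_inertia > 0 else np.zeros_like(eig)
    return OrdinationResult(scores, eig, prop, ids, "coa")


def class_ellipse(scores: np.ndarray, labels: Sequence[str],
                  scale: float = 1.5) -> dict[str, ClassEllipse]:
    """Fit a Mahalanobis contour ellipse to each group's first two axes.

    Nominal bivariate-normal coverage is 1 - exp(-c^2/2); c = 1.5 gives
    0.6753.  Groups need >= 3 points; a singular covariance collapses the
    ellipse to a segment and is flagged degenerate.
    """
    pts = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels)
    coverage = 1.0 - np.exp(-scale ** 2 / 2.0)
    out: dict[str, ClassEllipse] = {}
    for g in dict.fromkeys(labels.tolist()):
        grp = pts[labels == g]
        if grp.shape[0] < 3:
            raise InputError(f"group {g!r} has < 3 points")
        cov = np.cov(grp, rowvar=False)
        degenerate = bool(np.linalg.matrix_rank(cov, tol=1e-12) < 2)
        out[g] = ClassEllipse(str(g), grp.mean(axis=0), cov, scale,
                              coverage, degenerate)
    return out


def nominal_coverage(scale: float) -> float:
    """Bivariate-normal mass inside a Mahalanobis-radius-c ellipse."""
    return 1.0 - np.exp(-scale ** 2 / 2.0)


def separation_summary(scores: np.ndarray, labels: Sequence[str],
                       ellipses: dict[str, ClassEllipse],
                       grid: int = 200) -> pd.DataFrame:
    """Pairwise group-separation report on the first two axes.

    For each group pair: an ellipse-overlap indicator (shared cells on a
    joint bounding-box grid) and a silhouette-style score (mean over points
    of (b - a)/max(a, b) with a = mean within-group distance, b = mean
    between-group distance; ~1 means clean separation, <= 0 heavy overlap).
    """
    pts = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels)
    groups = list(ellipses)
    rows = []
    for i, g in enumerate(groups):
        for h in groups[i + 1:]:
            eg, eh = ellipses[g], ellipses[h]
            # grid over the joint bounding box of the two ellipses
            ext_g = eg.scale * np.sqrt(np.maximum(np.diag(eg.covariance), 0))
            ext_h = eh.scale * np.sqrt(np.maximum(np.diag(eh.covariance), 0))
            lo = np.minimum(eg.center - ext_g, eh.center - ext_h)
            hi = np.maximum(eg.center + ext_g, eh.center + ext_h)
            xs = np.linspace(lo[0], hi[0], grid)
            ys = np.linspace(lo[1], hi[1], grid)
            gx, gy = np.meshgrid(xs, ys)
            cells = np.column_stack([gx.ravel(), gy.ravel()])
            overlap = bool(np.any(eg.contains(cells) & eh.contains(cells)))
            pg, ph = pts[labels == g], pts[labels == h]
            sil = _pair_silhouette(pg, ph)
            rows.append({"group_a": g, "group_b": h,
                         "ellipse_overlap": overlap, "silhouette": sil})
    return pd.DataFrame(rows)


def _pair_silhouette(a: np.ndarray, b: np.ndarray) -> float:
    vals = []
    for own, other in ((a, b), (b, a)):
        d_own = cdist(own, own)
        n = own.shape[0]
        within = d_own.sum(axis=1) / max(n - 1, 1)
        between = cdist(own, other).mean(axis=1)
        denom = np.maximum(np.maximum(within, between), 1e-300)
        vals.append((between - within) / denom)
    return float(np.concatenate(vals).mean())


def save_ellipses(ellipses: dict[str, ClassEllipse], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {g: e.to_dict() for g, e in ellipses.items()}, indent=2))


def plot_ordination(result: OrdinationResult, labels: Sequence[str],
                    ellipses: dict[str, ClassEllipse] | None,
                    path: str | Path) -> None:
    """Scatter of the first two axes with group ellipses (SVG/PNG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in dict.fromkeys(labels.tolist()):
        m = labels == g
        ax.scatter(result.scores[m, 0], result.scores[m, 1], s=14, label=g)
    if ellipses:
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        for e in ellipses.values():
            w, V = np.linalg.eigh(e.covariance)
            ring = e.center + e.scale * circle @ np.diag(np.sqrt(np.maximum(w, 0))) @ V.T
            ax.plot(ring[:, 0], ring[:, 1], lw=1)
    ax.set_xlabel(f"axis 1 ({100 * result.proportion[0]:.1f}%)")
    ax.set_ylabel(f"axis 2 ({100 * result.proportion[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
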