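# Methods

This note documents the models behind each stage, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
conventions. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Population Aggregation Analysis (paa)

PAA is run at the level of the individual: the profile of a group at a
site is the *set* of states observed across all of its sequences, so one
variant individual removes that site from the group's diagnostic
repertoire. Two rules are offered:

* **attribute** (default) — site s diagnoses group g iff cell(g,s) is
  disjoint from the union of the other groups' cells. A polymorphic focal
  set (e.g. {G,C}) can still diagnose a group when no state leaks.
* **strict-fixed** — additionally requires |cell(g,s)| = 1.

The attribute rule is the default because, applied to the packaged
three-species character matrices, it reproduces the published per-species
diagnostic counts for the Araguaia taxon in both gene regions; the printed
per-species counts for the other two species are not mutually consistent
under any single rule, so the package reports them but the test suite does
not assert them. `N` and `-` carry no state; a site where any group has
only ambiguous data is dropped globally, so missing data can never create
a phantom diagnostic. Positions are 1-based in alignment coordinates
(gene start for cytochrome *b*, amplicon start for the barcode region).

Morphological diagnosis uses strict range disjointness: two trait ranges
are diagnostic only if separated by a gap; a shared endpoint counts as
overlap.

## Admixture clustering (clustering)

The sampler implements the admixture model with correlated allele
frequencies. Latent variables: per-allele-copy cluster of origin z, per-
individual ancestry q_i ~ Dirichlet(α·1_K), per-cluster allele frequencies
P_kl ~ Dirichlet(p_l·(1−F)/F) around ancestral frequencies p_l. One sweep
updates z | (Q,P), then P and Q from their Dirichlet full conditionals,
then α by random-walk Metropolis (step 0.25) under a Uniform(0, 10) prior.
Deviations from the full reference sampler, chosen for desk-scale
stability and documented as such:

* ancestral frequencies are fixed at the pooled sample frequencies rather
  than sampled, and F is fixed at `F_init` (default 0.05);
* no location prior (sampling labels are used only for post-hoc accuracy
  scoring in tests);
* missing allele copies contribute nothing to the likelihood or the count
  vectors (no imputation).

Model support uses LnP(K) = mean(lnL) − var(lnL)/2 with the n−1 variance
denominator (the convention is not stated by the upstream software; n−1 is
our documented choice). The posterior over K is
posterior(K) ∝ prior(K)·exp(lnP(K)−max lnP), uniform prior by default.
Replicate runs are aligned to the first run by the cluster-column
permutation maximising the Frobenius inner product, searched exhaustively
over K! permutations (exact for K ≤ 8); the consensus Q is the mean of
aligned Q matrices. Individuals are non-admixed when max_k q_ik exceeds
0.90 (configurable).

Default chain lengths are desk-scale: 12,000 sweeps with 2,000 burn-in for
library defaults; the pipeline and acceptance checks use 1,200–1,500
sweeps with 300 burn-in, which the recovery tests show is ample at the
study's separation (F = 0.15, 10 loci). Convergence can be screened with
the exported lnL/α traces and a Geweke-style z-score.

## Ordination (ordination)

Genotypes are recoded as per-allele dosage columns (0/1/2). PCA runs on
centred, unscaled dosages by default (column scaling is available);
eigenvalues come from the SVD of the centred matrix and sum to the total
column variance. Individuals missing a locus are mean-imputed per column
and flagged. COA performs the SVD of (P − rcᵀ)/√(rcᵀ); total inertia
equals Pearson χ²/n, which the tests verify against an independent
chi-square computation. Axes are oriented so the largest-magnitude loading
is positive.

Group scatter ellipses are parameterized by Mahalanobis radius c around
the group mean and covariance. Under bivariate normality the enclosed mass
is 1 − exp(−c²/2); the default c = 1.5 gives 67.53%, the contour level of
the published ordination figures — the figure caption's value is thus
reproduced from first principles rather than copied. Pairwise separation
is reported as an ellipse-overlap indicator (200×200 grid over the joint
bounding box) and a silhouette-style score.

## Genotype QC (popgen_qc)

HWE uses the exact conditional test: the probability of the genotype
array given allele counts, P ∝ n!·2^h·∏n_j! / (∏n_jk!·(2n)!), with
p = Σ P(array ≤ observed). Biallelic configurations are enumerated exactly
over the heterozygote count; multi-allelic configurations use Monte-Carlo
shuffling of the 2n allele copies (enumerating multi-allelic genotype
arrays is combinatorially explosive, and the shuffling estimator converges
to the same conditional distribution). LD uses a genotypic permutation
test: the G statistic of the genotype×genotype contingency table against
the null obtained by permuting one locus across individuals. Monte-Carlo
p-values use (b+1)/(m+1), so p > 0 always. Holm correction is applied per
family: across loci within a group for HWE, across locus pairs within a
group for LD. All Monte-Carlo tests record their seed and replicate count.

## Synthetic data (simulate)

The microsatellite generator draws group allele frequencies from the
Balding–Nichols distribution, Dirichlet(p·(1−F)/F), giving across-group
variance F·p(1−p) — exactly the correlated-frequencies structure the
clustering model assumes. Defaults mirror the study design: 3 populations
of 45/44/32 individuals, 10 loci with 4–8 alleles each (flat-Dirichlet
ancestral frequencies drawn once per seed), F = 0.15. No mutation process
(stepwise or otherwise) is modelled: groups differ by drift alone, so
passing recovery tests demonstrates the sampler works when its model is
true, not robustness to microsatellite mutation dynamics.

The sequence generator evolves a uniform-random root sequence along
((A,B):T₁,C):T₂ with a Jukes–Cantor kernel (site differs from its ancestor
with probability ¾(1−e^{−4d/3})) at rate r, then adds independent
terminal-branch mutations at θ/2 per site, producing a star-like
within-lineage genealogy with expected pairwise diversity ≈ θ. Defaults:
T₁ = 2.08 My, T₂ = 2.87 My, r = 1.01×10⁻⁸/site/yr, 1,140 sites (the
cytochrome-*b* length), 8 samples per lineage, θ = 0.002. The within-
lineage diversity level is a free parameter (not published); θ = 0.002
(a few segregating sites per lineage) was chosen once as typical of
conspecific cytochrome-*b* variation. The generator has no coalescent
structure, recombination or migration; JC69 rather than GTR+G+I keeps
every expectation in closed form for the recovery tests.

## Dating (dating)

Distances: p, JC69 (−¾ln(1−4p/3)), K80; gap/ambiguous sites are excluded
pairwise; saturated pairs get an infinite sentinel. NJ trees come from
dendropy's neighbor-joining on our distance matrices. Fitch scoring uses
the set-based down-pass (multifurcations folded pairwise). Bootstrap
monophyly resamples alignment columns, rebuilds NJ trees, and counts the
fraction of replicates in which each labelled group forms one side of a
bipartition (unrooted monophyly, so rooting never matters); singleton
groups are reported as trivially monophyletic, and an all-zero distance
matrix sets a no-signal flag.

Calibration priors are offset-lognormal: support starts at the youngest
fossil age y; given log-sd σ, the log-location is μ = ln(old−y) − z·σ so
the older fossil age sits at the one-sided 95% bound (z = 1.645,
configurable). The published σ values are taken as given — the two stated
constraints underdetermine (μ, σ), so σ cannot be re-derived; the four
packaged calibrations are (33.5→40, σ=1.068), (23.7→30, σ=1.135),
(11.2→16.6, σ=1.223), (10→11.2, σ=1.061) My.

Strict-clock dating replaces the full Bayesian machinery (Yule prior,
partitioned GTR+G+I, 10⁸-state MCMC), which is out of desk scope: node m
gets u_m = mean(d_ij)/2 over pairs with MRCA m — the least-squares
solution of Σ(d_ij − 2u_m)² — and the root calibration converts u to ages
via r = u_root/root_age. Children exceeding their parent's age are
clipped down and flagged; a zero fitted root height raises. The fit is
exact on clock-like distances, and scale-consistent (scaling all distances
scales the rate, not the ages). Consequently the package's dating evidence
is parameter recovery on synthetic data, not a reproduction of the
published HPD intervals.

## Pipeline and conservation (pipeline, cli)

All stage seeds derive from one base seed by hashing (stage, item) tags,
so a report is byte-reproducible from its embedded config; the provenance
block records the config hash, seed and package version, and each stage
failure is isolated. The pipeline's dating stage takes the closest group
pair (mean JC distance) as sisters and dates the split against the
configured root age (default 2.87 My).

Conservation arithmetic is deliberately transparent: N = D·L·W with the
three published density scenarios (0.80, 0.98, 1.3 ind/km² over
1500 km × 0.5 km) as defaults, and survey density = count/(stretch×strip
width) with the strip-width convention exposed — the published "~1525
individuals" figure depends on an unstated convention and is therefore
computable but not asserted anywhere.

## Known limitations

* The packaged character matrices are transcriptions of printed tables;
  the real GenBank alignments are not fetched, so the observed haplotype
  counts (12/10/3 cytb etc.) are outside the testable surface.
* The Gibbs sampler fixes F and the ancestral frequencies; LnP(K) values
  are therefore not numerically comparable to the upstream software's on
  real data, though the Bayes-Rule machinery consuming them is identical.
* Recovery tests run at the generators' assumptions (drift-only
  differentiation, clock-like JC evolution, star genealogies); they
  validate correctness of the inference machinery, not robustness to
  model violation in field data.
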