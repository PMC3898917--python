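# botodelim

Multi-evidence species delimitation for river dolphins (*Inia*, the
"boto"), built as a reusable, fully offline-testable pipeline. The package
reimplements the analysis chain used to diagnose the Araguaia River boto as
a species distinct from its Amazonian congeners, with every stage runnable
on packaged tables or synthetic data:

* **Diagnostic-site analysis (PSC track).** Individual-level Population
  Aggregation Analysis: a site diagnoses a focal species when its observed
  state set is disjoint from the union of all other species' states,
  `cell(g,s) ∩ ⋃_{h≠g} cell(h,s) = ∅`. Includes morphological
  range-overlap diagnosis (e.g. tooth counts per hemimandible).
* **Bayesian admixture clustering (BSC track).** A Gibbs sampler for the
  admixture model with correlated allele frequencies (the F-model,
  Balding–Nichols prior around ancestral frequencies), model support
  `LnP(K) = mean(lnL) − var(lnL)/2`, a Bayes'-Rule posterior over the
  number of biological groups, exact label-switching alignment of
  replicate runs, and the 90% ancestry-coefficient admixture rule.
* **Ordination.** PCA of allele dosages and correspondence analysis under
  the chi-square metric, with 67.53% density-contour group ellipses
  (Mahalanobis radius c = 1.5, coverage `1 − e^{−c²/2}`).
* **Genotype QC.** Exact/Monte-Carlo Hardy–Weinberg tests, genotypic
  permutation LD tests, Holm correction.
* **Lineage dating.** JC69/K80 distances, neighbor joining, Fitch
  parsimony, bootstrap monophyly, offset-lognormal fossil-calibration
  priors, and strict-clock least-squares dating (`d_ij ≈ 2 r t_MRCA(i,j)`).
* **Conservation arithmetic.** Abundance extrapolation
  `N = density × river length × width` and survey-density conversion.

A synthetic-data module generates microsatellite genotypes (K populations
drift-diverged with parameter F) and three-lineage mtDNA alignments
(`((A,B):T₁,C):T₂` under a strict clock) at the study design: 45/44/32
individuals × 10 loci, and divergences T₁ = 2.08 My, T₂ = 2.87 My at
r = 1.01×10⁻⁸ substitutions/site/yr.

## Worked example

```python
from botodelim import load_table1, load_table2
from botodelim.clustering import bayes_rule_K
from botodelim.paa import find_diagnostic_sites

post = bayes_rule_K(load_table1())        # six mean LnP(K) values, K = 1..6
print(post.modal_K)                       # -> 3
print(f"{post.probability(2):.3g}")       # -> 4.23e-98

report = find_diagnostic_sites(load_table2(), mode="attribute")
print(report.counts())
#                cytb  coi
# araguaiaensis    28    9
# geoffrensis      17   15
# boliviensis      22   13
```

The posterior over K says the microsatellite data place essentially all
probability on three biological groups — the probability that the Araguaia
boto belongs to the same mating system as *I. geoffrensis* (K = 2) is
~4×10⁻⁹⁸. The diagnostic table shows 28 cytochrome-*b* and 9 COI-barcode
sites whose states are unique to the Araguaia species: fixed character
discontinuities, the phylogenetic-species criterion.

An end-to-end run on synthetic data (clustering → ordination → QC → PAA →
monophyly → dating → conservation scenarios):

```bash
botodelim --out-dir out --seed 1 simulate
botodelim --out-dir out --seed 1 report
```

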