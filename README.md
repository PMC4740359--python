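# provzone

Genetic delineation of seed-collection provenance zones from dominant-marker
(AFLP-style presence/absence) data.

Ecological restoration programmes need a defensible answer to "how far away
may seed be collected?". One quantitative approach scores anonymous dominant
markers in populations sampled along an environmental transect and reads the
transfer radius off the relationship between pairwise genetic differentiation
and geographic distance. `provzone` implements that full analysis as a tested
Python library with a CLI:

- **Diversity** — percent polymorphic loci (PLP), unbiased expected
  heterozygosity *H*<sub>e</sub> = 2n/(2n−1)·2p(1−p) with the square-root
  Hardy–Weinberg allele-frequency estimator q̂ = √(n_absent/n_total), locally
  common and private bands, and the diversity-vs-sample-size regression.
- **AMOVA** — Φ_PT (an *F*_ST analogue for binary band phenotypes) from the
  squared-distance partition of molecular variance with unequal sample sizes
  (n₀ correction), permutation tests, pairwise Φ_PT and the linearization
  Φ/(1−Φ).
- **ANOSIM** — Clarke's rank-based R = (r̄_between − r̄_within)/(M/2) with
  permutation or exhaustive-enumeration significance, globally and per
  population pair.
- **Provenance delineation** — pairwise R joined to great-circle distances,
  a polynomial fit of R on distance, and three headline radii: the minimum
  significant distance, the *global provenance distance* (where the fitted
  curve crosses the global R) and the full-differentiation threshold.
- **Outlier scan** — a Bayesian locus/population decomposition of
  differentiation, logit(F_ij) = α_i·δ_i + β_j, sampled by
  Metropolis-within-Gibbs with spike-and-slab model choice; loci with
  log₁₀ posterior odds > 2 for the selection model are called outliers, with
  a posterior-based FDR.
- **Mantel tests** — simple and partial matrix correlations among genetic,
  geographic and climate distances, with climate-variable pruning
  (|r| > 0.8), log₁₀(x+1) transforms and z-scored Euclidean distances.
- **Synthetic data** — a stepping-stone isolation-by-distance generator on a
  linear transect (drift as a logit-scale random walk per km, a minority of
  loci coupled to a noisy climate gradient, dominant band presence
  1−(1−p)² per diploid), so every stage is testable without external data.

## Worked example

The raw band matrix of the motivating 16-site survey was never archived, but
its printed per-site summary and AMOVA sums of squares ship with the package
and exercise the variance-component, aggregation and regression paths:

```bash
$ python analysis/01_reference_worked_examples.py
Reference worked examples
  AMOVA: n0=32.354, sigma2_within=16.38, sigma2_among=4.80, Phi_PT=0.23 (22.66% among populations)
  Table means: He=0.229, PLP=81.8%, n=32.4
  He ~ n: R^2=0.40, p=0.008 (matches the published 0.40 / 0.008)
  PLP ~ n: R^2=0.18, p=0.104 (weaker; the published prose transposes the two indices)
```

Here σ²_within and σ²_among are the within- and among-population variance
components recovered from the printed sums of squares with the unequal-sample
correction n₀ = (N − Σn_k²/N)/(k−1); Φ_PT = 0.23 says 23 % of band variance
lies among sites. The regression line shows which printed diversity index
actually carries the published sample-size association.

The remaining drivers run the full pipeline on a synthetic 160 km transect
(16 populations × 32 plants × 134 loci, 13 climate-coupled):

```bash
$ python analysis/04_structure_delineation.py
AMOVA: Phi_PT = 0.065 (6.5% among sites), p = 0.001
Global ANOSIM: R = 0.273, p = 0.001
114/120 pairs significantly differentiated (permutation)
minimum significant distance: 10.7 km (next: 10.7 km)
global provenance distance: 56.7 km
all pairs beyond 10.7 km differentiated
```

i.e. for this simulated species, collections within ~57 km of a restoration
site are predicted to avoid significant genetic divergence.

The same stages are available as CLI subcommands
(`provzone simulate | diversity | amova | anosim | provenance | outliers |
mantel | run`), with `provzone run --config cfg.yaml` executing everything —
including the outlier/neutral subset re-analysis — from one YAML file.

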