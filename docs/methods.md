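# Methods

This note documents the statistical models, estimators, numerical choices and
known limitations behind `provzone`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

The central object is a binary band-state matrix (individuals × loci) with a
population label per individual. Dominant markers hide the heterozygote:
a band is present whenever the individual carries at least one band allele,
so under random mating P(band) = 1 − (1 − p)² for band-allele frequency p.
All statistics below are phenotype-level (band) statistics unless an allele
frequency is explicitly estimated.

Missing data policy: the estimators require complete data. Inputs with
missing calls must pass through `MarkerMatrix.drop_missing(max_fraction)`
(default 0.05), which drops loci then individuals exceeding that missingness
and rejects anything left over. The default is strict because none of the
downstream permutation machinery has a principled treatment of missingness.

Geographic distances are great-circle (haversine) on a sphere of mean radius
6371.0088 km. At the ~160 km transect scale this differs from projected or
ellipsoidal distances by far less than the site-positioning error of field
GPS coordinates.

## Diversity

- Allele frequency: q̂ = √(n_absent/n_total) (Hardy–Weinberg square-root
  estimator), justified when the organism is an obligate outcrosser. The
  Lynch–Milligan first-order bias correction
  q̂ = √x / (1 − Var(x)/(8x²)) is available behind a flag and off by
  default, matching the convention of the widely used spreadsheet tools for
  dominant data.
- Unbiased expected heterozygosity: uHe = 2n/(2n−1) · 2p̂(1−p̂) with 2n gene
  copies (diploid). Values can marginally exceed 0.5 at small n; they are
  reported as computed.
- Polymorphism: a locus is polymorphic in a population when both band states
  are observed there; no frequency cutoff. PLP is the percentage of scored
  loci that are polymorphic.
- Locally common bands: band frequency ≥ 0.05 in the focal population while
  the band occurs in ≤ 50 % of populations (both thresholds exposed as
  parameters; the ≤ convention follows the printed-table definition).
- The diversity-vs-size regression is ordinary least squares; for a simple
  regression the slope t-test equals the F(1, n−2) test, so that p-value is
  reported. The worked-example check against the published per-site table
  found that the printed regression statistics (R² = 0.40, p = 0.008) are
  reproduced by the He column, not the PLP column the prose names — the two
  indices are evidently transposed in the source text. The package's
  regression operation is index-agnostic; the acceptance checks reproduce
  the published numbers through the He column and report the PLP fit
  alongside.

## AMOVA and Φ_PT

For 0/1 band vectors the squared Euclidean distance is the mismatch count.
With k populations and N individuals:

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_k (1/n_k) Σ_{i<j∈k} d²_ij
    n₀        = (N − Σ n_k²/N)/(k−1)
    σ²_within = SS_within/(N−k)
    σ²_among  = (SS_among/(k−1) − σ²_within)/n₀
    Φ_PT      = σ²_among / (σ²_among + σ²_within)

Negative σ²_among is preserved in the result object (diagnostic) but Φ_PT is
truncated at 0 for presentation and for the linearization Φ/(1−Φ), keeping
the delineation monotone. Permutation p-values use the +1 correction,
p = (1 + #{Φ* ≥ Φ})/(n_perm + 1), permuting individuals among populations
with sample sizes fixed. Ties at the observed statistic count as exceedances
(within 1e−12). Pairwise Φ_PT tests are uncorrected for multiple testing by
design (matching the field convention of reporting raw pairwise
significance); an FDR/Bonferroni pass can be applied downstream if desired.

The decomposition is verified against an independently coded
deviation-from-centroid formulation on random instances (tolerance 1e−8) and
against the published worked example: from printed sums of squares
(2574.99 / 8221.85), df (15 / 502) and the 16 printed sample sizes,
the component path returns n₀ = 32.354, σ²_within = 16.38, σ²_among = 4.80,
Φ_PT = 0.23, 22.66 % among populations.

## ANOSIM

R = (r̄_between − r̄_within)/(M/2) over average ranks of the M = n(n−1)/2
dissimilarities; ties get average ranks. The same global-M denominator is
used for two-group (pairwise) tests — Clarke's original definition — rather
than a group-size-specific variant. Significance is by label permutation
with the +1 correction; instances with ≤ 9 individuals can use exhaustive
enumeration (`method="exact"`), which the sampled test is validated against.
Because R is rank-based it is invariant under strictly monotone transforms
of the dissimilarities.

Two pairwise significance flags are carried throughout: the permutation
p < 0.05 rule (default driver of the delineation) and the global-R rule
(pairwise R ≥ global R), selectable via configuration, because published
practice is ambiguous about which defines a "significantly differentiated"
pair.

## Provenance delineation

Pairwise R values are joined to great-circle distances and a least-squares
polynomial (default degree 2, recorded in the result) is fitted to R as a
function of distance in raw km. The *global provenance distance* is the
smallest distance within the observed range where the fitted curve reaches
the global R; roots come from the polynomial companion matrix with a
dense-grid/bisection fallback, and extrapolation beyond the sampled range is
refused. Also extracted: the smallest (and second-smallest) distance among
significant pairs, the maximum distance among non-significant pairs (beyond
which all pairs differ), and distance-band summaries (fraction of pairs with
R below the global value).

A crossing is only read off when the global R itself is significant at α
(default 0.05, using the supplied global permutation p). Rationale: under
the null the fitted curve is near-flat around a near-zero global R and a
crossing exists in essentially every replicate, but it carries no
delineation meaning; a practitioner would not derive a seed-transfer radius
from a non-significant global test. With the gate, null data yield an
undefined provenance distance at rate ≈ 1 − α by construction, while
isolation-by-distance data (where the global test is overwhelmingly
significant) are unaffected. On synthetic transects the provenance distance
decreases as the drift scale increases, i.e. the delineation tracks the true
divergence-per-km.

## Outlier scan

The selection scan models band counts y_ij (locus i, population j) as
binomial with the dominant presence probability 1 − (1 − p_ij)², and local
frequencies as migration–drift Beta draws around an ancestral frequency:

    p_ij ~ Beta(θ_ij π_i, θ_ij (1 − π_i)),  θ_ij = 1/F_ij − 1
    logit(F_ij) = α_i δ_i + β_j

Priors: π_i ~ Uniform(0,1); β_j ~ N(−1, 1.8²) (population effects, the
conventional choice for this decomposition); α_i ~ N(0, 1) when included;
δ_i ~ Bernoulli(1/(1 + PO_neutral)) with prior odds for the neutral model
defaulting to 10. Only loci polymorphic across the whole dataset enter the
scan.

Sampling is Metropolis-within-Gibbs: logit-scale random walks for p_ij, π_i
(with the transform Jacobian included), Gaussian walks for β_j and included
α_i, and a spike-and-slab toggle for δ_i that proposes α from its prior so
prior and proposal cancel — posterior-equivalent to reversible jump between
the nested models and easier to verify. Pilot runs tune each proposal width
toward an acceptance rate in [0.25, 0.45] (×1.4 / ÷1.4 adjustments, widths
clamped to [0.02, 10]); a diagnostics flag is raised (not an error) if any
block's sampling-phase acceptance leaves [0.05, 0.9].

Schedules: the default profile is 20 pilot runs of 500 sweeps, 50 000
burn-in, 50 000 sampling iterations thinned by 10. The documented fast
profile (2 pilots of 300, 2 000 burn-in, 2 000 iterations, thinning 5) is
used by the test suite and the analysis drivers; at desk scale its posterior
inclusion probabilities agree with a dense-grid quadrature oracle to well
within 0.05 on single-locus instances, and two independent seeds correlate
above 0.9 locus-wise on 50-locus datasets.

Posterior odds are PO_i = P(δ_i=1|data)/(1 − P), with inclusion
probabilities clipped away from 0/1 by half a sample-count unit so PO stays
finite; calls use log₁₀ PO > 2 ("decisive"). The FDR of a call set is the
mean posterior neutrality probability among called loci. q-values are the
running mean of (1 − inclusion) down the PO ranking, with tie blocks sharing
the block-end FDR and a reverse cumulative minimum enforcing monotonicity.
Classification is by the sign of the posterior mean of α among included
samples: positive = diversifying (excess differentiation), negative =
balancing.

Absolute PO values are sensitive to the neutral prior odds, so the package's
guarantees are rank-based (true clinal loci occupy the top ranks) and
limit-based (prior odds → ∞ empties the call set; → 0 calls everything),
not absolute-threshold reproductions.

## Mantel analyses

Climate preparation: greedy left-to-right pruning drops any variable with
|Pearson r| > 0.8 against an already retained one (order-dependent; the
retained set is returned for auditability — the convention in the source
analyses is equally unspecified). Values are log₁₀(x+1) transformed,
z-scored per variable, and turned into Euclidean site distances. Geographic
distances enter Mantel tests as log₁₀(km + 1), keeping a zero diagonal.

The Mantel statistic is the Pearson correlation of upper-triangle entries;
p-values come from jointly permuting rows/columns of the first matrix, with
one-tailed (≥) tests by default to match directional isolation-by-distance
hypotheses (two-tailed by flag). The partial statistic is

    r_AB·C = (r_AB − r_AC r_BC) / √((1−r_AC²)(1−r_BC²))

recomputed in full for every permutation of A (the permutation scheme of the
standard vegan implementation; residual-permutation variants are out of
scope). Genetic distance at the population level is the linearized pairwise
Φ_PT matrix. Exhaustive enumeration is available for n ≤ 8 and validates the
sampled test.

## Synthetic data generator

The generator emulates the target sampling design: `n_pops` (16) sites
evenly spaced along a north–south line of `transect_km` (160 km),
`n_per_pop` (32) diploid outcrossing individuals, `n_loci` (134) dominant
markers of which `n_selected` (13) are climate-coupled. Ancestral
frequencies are Uniform(0.1, 0.9). Neutral divergence is a stepping-stone
random walk on the logit scale with per-step standard deviation
`drift_scale` × step-km (default 0.02 logit/km) — drift is parameterized as
divergence-per-km directly because that is the quantity the delineation
estimates, rather than via explicit Wright–Fisher generations. The climate
driver is a linear north–south gradient plus Gaussian noise
(`climate_noise`, default 0.3), standardized; selected loci shift by
`selection_slope` (default 1.5) logit units per standardized climate unit.
Band presence is Bernoulli(1 − (1 − p)²). Frequencies stay in (0,1) through
the inverse-logit map; nothing is truncated post hoc. One master seed spawns
independent per-component generators (sites, frequencies, drift walk,
climate, genotypes), so changing the locus count does not move the sites.

What the generator does **not** emulate: linkage between loci, mutation,
uneven or clustered sampling, range edges/2-D geography, temporal structure,
genotyping error or missing data, and selection regimes other than a single
linear climate cline. Passing tests therefore demonstrate that the
estimators and the delineation respond correctly to their target quantities
under a clean isolation-by-distance model — not that any particular field
dataset satisfies those assumptions. At the default drift scale the full
design produces Φ_PT around 0.07; the generator targets orders of magnitude,
not any specific published value.

## Problem sizes and schedules

The test suite and acceptance script run at desk scale by choice: property
tests use 5–8 populations of 10–16 individuals and 30–50 loci, permutation
counts of 99–4 999 with exact enumeration below 9 entities, 200 replicates
for type-I-error calibration, and the fast MCMC profile throughout; the
acceptance script runs the full 16×32×134 design with 999/199 permutations.
These sizes give Monte-Carlo error comfortably inside every asserted
tolerance while keeping a full run in minutes.

## Known limitations

- Single-level AMOVA only (no region/population hierarchy).
- The outlier model assumes independent loci and an island-style Beta
  equilibrium; strong spatial autocorrelation of neutral loci (the very
  signal the delineation uses) can inflate its false-positive rate on real
  transect data — the subset re-analysis is the mitigation, not a fix.
- Greedy climate pruning is order-dependent.
- Permutation p-values are one-tailed toward excess differentiation or
  positive matrix correlation; balancing-selection-style alternatives in the
  Mantel machinery require the two-tailed flag.
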