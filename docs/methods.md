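# Methods

This note documents the models implemented in `phylogap`, the defaults and
their units, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Admixture clustering

`clustering.fit_admixture` implements the independent-allele-frequency
admixture model: each of the two gene copies an individual carries at a
locus has a latent cluster of origin z; conditional on z the sampler draws
cluster allele frequencies P from Dirichlet(λ + counts) with λ = 1 and
individual memberships Q from Dirichlet(α + copy counts). The Dirichlet
parameter α is a single scalar shared by all clusters, updated by a
random-walk Metropolis step (normal proposal, sd 0.025–0.05 range; we use
0.05) under a uniform prior on (0, 10]; a fit whose α trace pins to the
upper bound records a warning.

The marginal likelihood ln Pr(X|K) is estimated from the post-burn-in
log-likelihood trace as mean − var/2. This estimator assumes the
likelihood values are approximately lognormal; it is mildly biased upward,
and on a two-individual toy it agrees with the exact Dirichlet-multinomial
marginal only to within about half a nat (the unit suite asserts exactly
that tolerance). Since model choice across K uses *differences* of lnPD
that are tens to hundreds of nats on realistic data, the bias is
immaterial for ΔK.

Deliberate deviations from the classic desktop defaults:

- The correlated-allele-frequency (F-model) prior is not implemented. It
  buys sensitivity at weak structure; the recovery scenarios this package
  is validated on have strong structure, where the independent-frequency
  model recovers the generating labels with ≥ 90% agreement.
- Desk-scale chain lengths: burn-in = reps = 5,000 by default (the classic
  recommendation is 50,000 each) and 5 replicate runs per K. All are
  overridable; the pipeline logs the settings it used.

ΔK follows the Evanno construction: ΔK(K) = |mean lnPD(K+1) − 2·mean
lnPD(K) + mean lnPD(K−1)| / sd(lnPD(K)), with means and sd over replicate
runs, defined only for interior K and flagged undefined when sd = 0.
Label switching is handled only at evaluation time by exhaustive
minimum-cost permutation matching (K! is tiny here); ties break to the
lexicographically smallest permutation.

## F-statistics and gene flow

Pairwise F_ST is the Weir–Cockerham (1984) θ: variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are accumulated over alleles and loci, and θ = Σa/Σ(a+b+c).
The estimator is the variance-component formulation used by Arlequin, so
it is the faithful choice where a source names only "pairwise F_ST".

R_ST follows Slatkin (1995): a one-way unbalanced ANOVA on allele *sizes*
treats each gene copy as an observation; the among-population component
σ²_a and within mean square are summed across loci (Arlequin convention)
before forming R = σ²_a/(σ²_a + σ²_w). Unbiased variance components can
be slightly negative, so R_ST of two finite identical samples is a small
negative number of order 1/N, not exactly zero.

Missing genotypes are dropped pairwise per locus everywhere.

Wright's island-model gene flow is Nm = (1−F)/(4F) migrants per
generation. F ≤ 0 is reported as an explicit error (differentiation
indistinguishable from zero ⇒ unbounded gene flow), never as a number.

## Rarefied allelic richness

Richness is rarefied to a common number of genes g (the FSTAT unit, 2n):
AR = Σ_alleles [1 − C(N−N_a, g)/C(N, g)], computed through log-gamma for
stability. g defaults to the smallest per-population gene count in the
dataset; asking for more names the limiting population in the error. The
cluster test statistic is the population-weighted variance of cluster
means of per-population mean richness; population labels are permuted
among clusters (1,000 permutations by default) and P is the fraction of
arrangements, observed included, with a statistic at least as large. The
variance statistic is direction-free, which is what makes the test
two-sided.

## Isolation by distance

Geographic distances are great-circle (haversine, R = 6371.0088 km).
Mantel tests correlate the off-diagonal upper triangles and permute one
matrix's rows and columns jointly; three transforms are provided —
distance vs statistic, ln distance vs statistic, and ln distance vs
R/(1−R) (pairs with R = 1 are excluded with a warning). P uses the
add-one convention (1 + hits)/(1 + permutations), which makes the null
distribution uniform on a lattice; an exact-enumeration mode exists for
small n. Default 1,000 permutations.

## Assignment and migrant detection

Two likelihood criteria: the *frequency* method multiplies reference
allele frequencies (heterozygotes get the factor 2), replacing zero
frequencies by a floor of 0.01 — the GeneClass/Paetkau convention,
configurable; and the *Rannala–Mountain* partial-Bayesian criterion, the
Dirichlet posterior predictive with prior 1/J per allele at a J-allele
locus. Likelihoods for an individual's own sampling population are
computed leave-one-out. Reported per-population scores are
percentage-normalized likelihoods summing to 100.

First-generation migrants use Λ = L_home/L_max (log10 scale, ≤ 0). The
null distribution is built per home population from 1,000 simulated
genotypes drawn allele-by-allele from the *observed* (not leave-one-out)
frequencies, matching the published resampling recommendation;
P(resident) is the fraction of simulated Λ at or below the observed, and
individuals with P < α (default 0.01) are flagged. Because the observed
individual is scored leave-one-out while simulated individuals are not,
the test is slightly anticonservative in small reference samples; the
calibration suite therefore checks the nominal rate at reference sizes of
100 diploids per population, where the realized rate sits inside the 99%
binomial band for 500 trials.

## mtDNA

p-distances are the proportion of differing sites among pairwise
comparable (non-gap, non-N) positions. TN93 distances use the closed-form
estimator with base frequencies taken from each pair (pairwise deletion,
no gamma correction — the plain distances are what the reported numbers
use even when a +G model wins a likelihood-ratio contest); saturated pairs
(log-domain failure) are flagged undefined, and TN93 ≥ p wherever defined.
An independent implementation (the R `ape` package) was used to freeze
oracle values for the unit tests; agreement is to ~1e-3, the residual
coming from frequency-estimation details.

Divergence time is T = p/(2r), with the per-lineage clock rate r = 0.007
substitutions/site/Myr (amphibian mtDNA consensus); the pairwise rate is
2r = 0.014/Myr. On the generator's output, T estimated from
between-cluster mean p recovers the generating split time within 15% at
487 bp and 10 sequences per cluster (the ~5% shortfall is multiple-hit
loss, since p is uncorrected).

Diversity indices follow the standard sample formulas: Hd = n(1 −
Σp_i²)/(n−1) over haplotype frequencies with the Nei (1987) eq. 8.12
variance; π is the mean pairwise p-distance with the Nei eq. 10.7
(stochastic + sampling, no recombination) variance. Printed SDs for π in
legacy tables vary by program convention; only the indices themselves are
treated as comparable quantities.

The statistical-parsimony connection limit is operationalized as a
per-site Poisson single-hit criterion: with j observed differences over m
sites, the per-site substitution rate is the moment estimator
μ = −ln(1 − j/m), the probability that a changed site changed exactly
once is μe^(−μ)/(1 − e^(−μ)), and the limit is the largest j whose j-th
power of that probability still meets the confidence level (0.95 default).
This is a deliberate, well-defined reformulation of the original 1992
recursion — it preserves the properties that matter here (monotone in
confidence, non-decreasing in length; limit 7 at 487 bp and 95%) and is
verified against an independent reimplementation. The haplotype network
is a minimum spanning network: edge weights are mutational steps, weight
classes are processed in ascending order against the partition as it
stood before the class (so equal-weight alternatives create
reticulations), edges above the connection limit are omitted (subnetworks
allowed), and edges longer than one step carry materialized unobserved
intermediates.

## Niche model

The suitability model maximizes the regularized maxent objective
mean_presences(λ·f) − log Z(λ) − β Σ_j r_j|λ_j| by convex optimization
(L-BFGS-B on the positive/negative split of λ), with linear and quadratic
features of each climate variable standardized on the training
background. The per-feature regularization scale is r_j = 1/√m for m
presences, so the penalty relaxes as evidence accumulates — without this
scaling an L1 weight of β = 1 on standardized features suppresses even a
one-standard-deviation signal. Feature classes stop at quadratic (no
hinge/product/threshold): the fit stays convex and desk-scale, at the
cost of less flexible response curves than Maxent 3.x defaults.

The logistic output is LV = e^H q/(1 + e^H q), where q is the normalized
exponential-family density over the training background and H its
entropy; a uniform model therefore outputs LV = 0.5 everywhere.
Projection to another climate stack (the LGM scenario) reuses the
training normalizer and entropy so the two maps share one calibration.
Variable clamping to the training range during projection is available
but off by default; with band-shaped (negative-quadratic) responses
extrapolation is already monotone-decreasing away from the optimum.
Monotone responses fitted from one-sided extreme presences can acquire a
positive quadratic term and then extrapolate pathologically into novel
climates — a known failure mode of quadratic maxent, and the reason the
clamp option exists.

Evaluation: the binomial test compares the fraction of test presences at
or above a threshold with the suitable fraction a of the background,
P = P(X ≥ k | n, a); the default threshold set is {0.05, 0.10, 0.15,
0.20, 0.25, 0.30, 0.40, 0.50, 0.60, 0.70}; AUC is rank-based
(Mann–Whitney, ties half). Suitable area counts cells with LV ≥ 0.1
times the cell area (100 km² for 10-km cells). Train/test splits are
random halves under a stated seed; the background is every valid cell
(no subsampling), which keeps fits deterministic.

## Connectivity

Habitat resistance is 1 − LV cellwise (nodata propagates). The least-cost
distance between the two lineages' range borders is Dijkstra over the
8-connected grid with move cost = mean of the two cells' resistances ×
step length (1 orthogonal, √2 diagonal) — the ArcGIS cost-distance
convention; 4-connectivity is a flag. Costs are unitless accumulated
resistance-steps, the convention of the published connectivity metric.
Border cells are explicit inputs (the generator derives them from the
true-suitability 0.5 contour flanking the gap), since no published rule
delineates them. The paired t-test of gap suitability under two climates
runs over overlapping valid gap pixels; identical rasters return t = 0,
P = 1 by convention rather than the 0/0 a naive implementation produces.

## Synthetic-data generator

The generator's defaults encode the motivating study design: 4 clusters
(one northern, three southern) with 25 localities split (8, 6, 6, 5),
19 diploids per locality, 6 microsatellite loci, 487-bp mtDNA at
r = 0.007/site/Myr per lineage, split times (5.2, 3.5, 1.5) Myr, and a
10-column gap band on a 40 × 60 climate grid.

*Microsatellites.* Each locus starts from an ancestral distribution over
5 adjacent repeat sizes. The deep lineages are separated by shared ±1
stepwise random walks with Poisson(8) steps per locus; southern clusters
add shallow Poisson(2) walks on a common southern ancestor, reproducing
the hierarchy of a deep two-lineage split over shallow sub-clusters —
and, because divergence lives in allele *size*, R_ST exceeds F_ST under
deep divergence exactly as the stepwise-mutation argument predicts.
Within clusters, localities form a serial founder chain: each locality's
frequencies are a Dirichlet perturbation (concentration 2/slope) of its
neighbor's, so genetic distance grows along the line and Mantel r rises
with the slope parameter. Individuals are Hardy–Weinberg draws from
their locality's frequencies; admixture localities draw from a stated
mixture of two cluster pools and record the generating Q.

*mtDNA.* Sequences evolve by Poisson substitutions (Jukes–Cantor moves,
optional transition bias κ) along a caterpillar tree with the stated
split times; the expected between-cluster p-distance is ≈ 2rT less
multiple-hit loss, and the unit suite checks the exact Poisson law
3/4(1 − e^(−8rT/3)) over 200 replicates.

*Landscape.* Precipitation rises west→east (1,200–3,600 mm); temperature
is an independent north–south gradient and altitude is noise, so the
model-selection machinery has irrelevant variables to ignore. Each
lineage's true suitability is logistic in a quadratic of precipitation —
a band with optimum at 32% (dry-adapted) or 68% (wet-adapted) of the
gradient, width 1/8 of the range, peak LV 0.9 — so the two ranges abut
at mid-gradient and the model family can represent the truth exactly.
The gap multiplies precipitation by 0.95 today and 0.45 at the LGM, and
glacial climate is 30% drier and 3 °C colder overall; by construction
the southern lineage's gap suitability falls from ~0.28 to ~0.0 at the
LGM and its least-cost crossing rises, while a "northern" preset with
identical scenarios leaves costs equal. Presences are sampled from the
top decile of true suitability outside the gap (core habitat), which
bounds recoverable AUC near 0.95.

What the generator does *not* emulate: coalescent gene genealogies and
recombination, selection, demographic growth, linkage between loci,
spatially autocorrelated climate noise, georeferencing error, and the
real 11-bioclim covariance structure. Passing recovery tests therefore
demonstrates estimator correctness under the stated generating laws, not
robustness to every property of field data.

## Determinism and problem sizes

All randomness flows through explicitly passed seeded generators;
per-stage seeds derive from the global seed and the stage name, and every
generator is byte-reproducible under a fixed seed. The test and
demonstration problem sizes — 60–500 diploids, chains of a few hundred to
a few thousand sweeps, 40 × 60 grids, 200–1,000 permutations or
simulations — were chosen so each property runs in seconds while leaving
the statistical signal far above its decision threshold; all are
parameters, not constants.

## Known limitations

- The admixture sampler has no linkage model, no LOCPRIOR, no
  USEPOPINFO-style ancestry testing.
- lnPD's mean − var/2 estimator is biased for small data (documented
  above); use replicate spread, not single-run values.
- The migrant test's Λ null ignores the leave-one-out asymmetry (small-n
  anticonservatism documented above).
- The parsimony limit is a reformulation, not a line-by-line port, of the
  1992 recursion; absolute limits may differ from TCS by a few steps.
- The maxent fit offers linear + quadratic features only; strongly skewed
  or multimodal responses need a richer feature basis.
- Least-cost costs depend on the neighborhood convention; published
  magnitudes from other tools are comparable only directionally.
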