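# phylogap

A toolkit for two-lineage phylogeography: it asks whether two genetic
lineages of a species separated by a gap in their distribution — the
motivating case is the Middle American túngara frog, whose Northern and
Southern lineages are split by a ~200 km gap in central Costa Rica — are
(1) genetically structured into distinct population clusters, (2) connected
by measurable gene flow, and (3) kept apart by unsuitable habitat that
persisted through the Last Glacial Maximum (LGM).

It is written for population geneticists and landscape ecologists who want
the whole inference chain — from genotype tables and sequence alignments to
a landscape-connectivity verdict — as tested, scriptable Python instead of
a relay of desktop programs (STRUCTURE, Arlequin, GENECLASS2, FSTAT, MEGA,
TCS, DnaSP, Maxent, ArcGIS).

## What it computes

**Microsatellites** (`popgen`, `clustering`, `assignment`)

- Bayesian admixture clustering: a Gibbs sampler for the classic admixture
  model (membership Q with Dirichlet(α) prior, allele frequencies P with
  Dirichlet(λ=1) prior, α updated by Metropolis), ln Pr(X|K) estimated as
  mean − var/2 of the likelihood trace, and the Evanno
  ΔK(K) = |L″(K)|/sd(K) table for choosing K.
- Pairwise Weir–Cockerham θ (F_ST) and Slatkin R_ST from variance
  components of allele size; Wright's island-model gene flow
  Nm = (1−F)/(4F).
- Rarefied allelic richness AR = Σ_a [1 − C(N−N_a, g)/C(N, g)] with a
  permutation test of cluster differences; Mantel isolation-by-distance
  tests (distance, ln distance, and R/(1−R) transforms).
- GeneClass-style assignment (frequency and Rannala–Mountain criteria) and
  first-generation migrant detection with Λ = L_home/L_max against a Monte
  Carlo null.

**mtDNA** (`mtdna`): uncorrected p and Tamura–Nei (1993) distances,
molecular-clock dating T = p/(2r) with r = 0.007 substitutions/site/Myr per
lineage, DnaSP-style diversity indices (h, s, Hd ± SD, π ± SD), a
statistical-parsimony connection limit and a minimum-spanning haplotype
network.

**Niche and connectivity** (`niche`, `connectivity`): a maxent-style
suitability model (linear + quadratic features, L1 regularization, convex
fit) with logistic output LV = e^H q/(1 + e^H q); binomial threshold tests,
ROC/AUC, projection to LGM climate and suitable-area summaries; habitat
resistance 1 − LV and the least-cost path across the distribution gap
(Dijkstra, 8-connected, √2 diagonals).

**Synthetic data** (`simulate`): a generator producing genotypes with a
hierarchical two-lineage / four-cluster structure under stepwise mutation
and serial-founder isolation by distance, clock-like mtDNA, and a
two-gradient climate landscape whose gap band deepens at the LGM — every
estimator above is validated by recovering this generator's parameters.

## Worked example

Simulate a study and run the core analyses:

```sh
phylogap simulate --seed 1 --outdir fix
phylogap clock --p 0.078
```

The clock verb prints `5.57` — the divergence time in Myr for a
between-cluster p-distance of 0.078 at the default pairwise rate
2 × 0.007/Myr. Continuing in Python:

```python
from phylogap import *

gm  = read_genotypes("fix/genotypes.str")
lt  = read_localities("fix/localities.csv")
rst = rst_pairwise(gm, lt.cluster_of())
print(rst.get("North", "South_1"))          # 0.825  (deep lineage split)
print(rst.get("South_1", "South_2"))        # 0.610  (shallower, same lineage)
print(nm_from_fixation(rst.get("North", "South_1")))   # 0.053 migrants/gen

aln    = read_fasta("fix/mtdna.fasta")
groups = {sid: sid.rsplit("_s", 1)[0] for sid in aln.ids}
p_ns   = group_mean_distance(p_distance(aln), groups).loc["North", "South_1"]
print(round(p_ns, 3), round(divergence_time(p_ns), 2))  # 0.061  4.34 Myr
```

The R_ST hierarchy (0.83 between lineages vs 0.61 within the southern
lineage) and the ~4–5 Myr mtDNA divergence mirror what the generator was
told to produce. The landscape side:

```python
from phylogap.simulate import Scenario, simulate_landscape

land  = simulate_landscape(Scenario(seed=1))
model = fit_maxent(land.presences["south"], land.current)
cur   = predict_logistic(model, land.current)
lgm   = predict_logistic(model, land.lgm)
print(auc(cur, land.presences["south"]))    # 0.926
rep = gap_connectivity_report(cur, lgm, land.gap_mask,
                              land.borders["east"], land.borders["west"])
print(rep["cost_current"], rep["cost_lgm"])  # 5.90  10.92
print(rep["verdict"])
# gap resistance higher at the glacial maximum: the barrier persisted and deepened
```

The wet-adapted southern lineage's least-cost crossing of the gap almost
doubles under glacial climate — the gap persisted, supporting divergence in
allopatry. `phylogap run-all --seed 1 --outdir out` runs the whole chain
and writes per-stage CSV/JSON artifacts plus `summary.json`; a rerun with
the same seed is byte-identical.

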