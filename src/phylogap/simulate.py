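"""Synthetic data with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs:

* hierarchical microsatellite genotypes — clusters diverge by a shared
  stepwise-mutation random walk, localities within a cluster drift serially
  along a line so isolation by distance emerges;
* clock-like mtDNA — Poisson substitutions along a caterpillar cluster tree
  with branch lengths in Myr times a per-lineage rate, so the expected
  between-cluster p-distance is ~2·r·T for small distances;
* a two-gradient climate landscape — a dry-to-wet precipitation gradient
  with a low-suitability band (the distribution gap) separating a
  dry-adapted western lineage from a wet-adapted eastern one, plus an LGM
  scenario in which the gap may deepen.

All randomness flows through one explicitly passed seeded generator; a fixed
seed reproduces every output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (MISSING, ClimateStack, GenotypeMatrix, LocalityTable,
                 Raster, SequenceAlignment)

__all__ = [
    "Scenario", "LandscapeSim", "simulate_microsatellites", "simulate_mtdna",
    "simulate_landscape", "locality_table",
]


@dataclass
class Scenario:
    """Parameters of one synthetic study.

    Defaults mirror the sampling design of the motivating system: four
    population clusters, 19 diploids per locality, six microsatellite loci,
    a 487-bp mtDNA fragment evolving at 0.007 substitutions/site/Myr per
    lineage, and split times of ~5 Myr between the two main lineages and
    ~1.4–3.9 Myr among the southern clusters.
    """

    seed: int = 0
    n_clusters: int = 4
    localities_per_cluster: tuple[int, ...] | int = (8, 6, 6, 5)
    individuals_per_locality: int = 19
    n_loci: int = 6
    #: expected net stepwise-mutation displacement (shared random-walk steps)
    #: separating the two main lineages from the common ancestor
    divergence_steps: float = 8.0
    #: expected walk depth separating clusters *within* the southern
    #: lineage (only used when n_clusters >= 3), so the hierarchy of a
    #: deep two-lineage split over shallow sub-clusters is reproduced
    within_lineage_steps: float = 2.0
    #: serial-founder drift intensity along the within-cluster locality line;
    #: 0 disables drift (no isolation by distance)
    ibd_slope: float = 0.05
    #: per-gene stepwise noise (Poisson mean), keeps loci polymorphic
    within_noise: float = 0.6
    n_ancestral_alleles: int = 5
    missing_rate: float = 0.0
    #: extra localities drawing genes from two clusters: (cluster_a,
    #: cluster_b, weight of a)
    admixture_localities: tuple[tuple[int, int, float], ...] = ()

    # mtDNA
    mtdna_length: int = 487
    #: per-lineage substitution rate, substitutions/site/Myr
    rate_per_lineage: float = 0.007
    #: caterpillar split times (Myr), deepest first; length n_clusters - 1
    split_times_myr: tuple[float, ...] = (5.2, 3.5, 1.5)
    within_cluster_myr: float = 0.15
    mt_samples_per_cluster: int = 10
    #: transition/transversion weight (1 = Jukes-Cantor-like symmetry)
    kappa: float = 1.0

    # landscape
    grid_nrows: int = 40
    grid_ncols: int = 60
    cellsize: float = 0.1
    xllcorner: float = -86.0
    yllcorner: float = 7.0
    nodata_value: float = -9999.0
    precip_range: tuple[float, float] = (1200.0, 3600.0)
    temp_range: tuple[float, float] = (24.0, 28.0)
    #: gap band: center column fraction, width in columns
    gap_center_frac: float = 0.5
    gap_width_cols: int = 10
    #: multiplicative precipitation drop inside the gap, current scenario
    gap_factor_current: float = 0.95
    #: same for the LGM scenario (lower ⇒ gap deepens during the glacial)
    gap_factor_lgm: float = 0.45
    #: global LGM precipitation scaling (glacial-maximum drying)
    lgm_precip_scale: float = 0.70
    lgm_temp_shift: float = -3.0
    climate_noise_sd: float = 15.0
    n_presences_per_lineage: int = 40
    #: presences are sampled uniformly from the top fraction of
    #: true-suitability cells (core habitat) outside the gap
    presence_top_fraction: float = 0.10

    def localities_counts(self) -> tuple[int, ...]:
        if isinstance(self.localities_per_cluster, int):
            return (self.localities_per_cluster,) * self.n_clusters
        if len(self.localities_per_cluster) != self.n_clusters:
            # the class default encodes the 4-cluster sampling design; any
            # other K falls back to 6 localities per cluster
            if self.localities_per_cluster == (8, 6, 6, 5):
                return (6,) * self.n_clusters
            raise ValueError("localities_per_cluster length != n_clusters")
        return tuple(self.localities_per_cluster)

    def validate(self) -> None:
        counts = self.localities_counts()
        if self.n_clusters < 1 or any(c < 1 for c in counts):
            raise ValueError("cluster and locality counts must be positive")
        if self.individuals_per_locality < 1 or self.n_loci < 1:
            raise ValueError("sample sizes must be positive")
        if self.n_clusters > 1 and len(self.split_times_myr) < self.n_clusters - 1:
            raise ValueError("need n_clusters - 1 split times")
        if any(t < 0 for t in self.split_times_myr[: self.n_clusters - 1]):
            raise ValueError("split times must be non-negative")
        if self.rate_per_lineage <= 0:
            raise ValueError("substitution rate must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stream generator derived from the scenario seed."""
        import zlib
        sub = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence((self.seed, sub)))


def _cluster_names(k: int) -> list[str]:
    if k == 2:
        return ["North", "South"]
    if k == 4:
        return ["North", "South_1", "South_2", "South_3"]
    return [f"C{i}" for i in range(k)]


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

def simulate_microsatellites(sc: Scenario) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate diploid genotypes; returns (matrix, true membership Q).

    Per locus an ancestral allele-size distribution is drawn; each cluster
    shifts it by a shared ±1 random walk with Poisson(divergence_steps)
    steps (the stepwise-mutation divergence signal, visible to both F_ST-
    and R_ST-type statistics) and adds small per-gene stepwise noise.
    Localities within a cluster form a serial chain of Dirichlet
    drift steps so allele frequencies — hence genetic distance — change
    gradually along the line (isolation by distance).
    """
    sc.validate()
    rng = sc.rng("microsat")
    K = sc.n_clusters
    names = _cluster_names(K)
    counts = sc.localities_counts()
    base_sizes = 100 + 10 * np.arange(sc.n_loci)

    # per-locus ancestral allele-size frequencies
    anc_sizes, anc_freqs = [], []
    for l in range(sc.n_loci):
        sizes = base_sizes[l] + np.arange(sc.n_ancestral_alleles)
        f = rng.dirichlet(np.full(sc.n_ancestral_alleles, 2.0))
        anc_sizes.append(sizes)
        anc_freqs.append(f)

    # cluster-level frequencies: shared SMM shift + per-gene noise smear
    # represented over an expanded size support
    def smear(sizes: np.ndarray, freqs: np.ndarray, shift: int,
              noise: float) -> tuple[np.ndarray, np.ndarray]:
        # exact distribution of size + shift + (sum of Poisson(noise) ±1 steps)
        span = int(np.ceil(3 * np.sqrt(noise + 1))) + 1
        offs = np.arange(-span, span + 1)
        # displacement distribution of a lazy ±1 walk with Poisson(noise)
        # steps: approximate by discretized Skellam(noise/2, noise/2)
        from scipy.stats import skellam
        w = skellam.pmf(offs, noise / 2 + 1e-12, noise / 2 + 1e-12)
        w = w / w.sum()
        out: dict[int, float] = {}
        for s, f in zip(sizes, freqs):
            for o, pw in zip(offs, w):
                out[int(s + shift + o)] = out.get(int(s + shift + o), 0.0) + f * pw
        ks = np.array(sorted(out))
        return ks, np.array([out[k] for k in ks])

    def walk(depth: float) -> int:
        n_steps = rng.poisson(depth)
        return int(rng.choice([-1, 1], size=n_steps).sum()) if n_steps else 0

    # cluster 0 is the deeply diverged lineage; clusters 1..K-1 share a
    # second-lineage ancestor and differ only by shallow walks; every
    # locus takes its own walk
    shifts = np.zeros((K, sc.n_loci), dtype=int)
    if K >= 3:
        shifts[0] = [walk(sc.divergence_steps) for _ in range(sc.n_loci)]
        south_anc = np.array([walk(sc.divergence_steps)
                              for _ in range(sc.n_loci)])
        for c in range(1, K):
            shifts[c] = south_anc + np.array(
                [walk(sc.within_lineage_steps) for _ in range(sc.n_loci)])
    else:
        shifts = np.array([[walk(sc.divergence_steps)
                            for _ in range(sc.n_loci)] for _ in range(K)])

    cluster_freqs: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for c in range(K):
        per_locus = []
        for l in range(sc.n_loci):
            per_locus.append(
                smear(anc_sizes[l], anc_freqs[l], int(shifts[c, l]),
                      sc.within_noise))
        cluster_freqs.append(per_locus)

    ind_ids, loc_ids, rows, q_rows = [], [], [], []
    conc = (2.0 / sc.ibd_slope) if sc.ibd_slope > 0 else None

    def sample_locality(freq_by_locus, n_ind, loc_name, q_row):
        for i in range(n_ind):
            genos = np.empty((sc.n_loci, 2), dtype=np.int64)
            for l, (sizes, f) in enumerate(freq_by_locus):
                genos[l] = rng.choice(sizes, size=2, p=f)
            ind_ids.append(f"{loc_name}_i{i}")
            loc_ids.append(loc_name)
            rows.append(genos)
            q_rows.append(q_row)

    for c in range(K):
        freq_chain = cluster_freqs[c]
        for j in range(counts[c]):
            if conc is not None and j > 0:
                drifted = []
                for sizes, f in freq_chain:
                    f2 = rng.dirichlet(np.maximum(f * conc, 1e-6))
                    drifted.append((sizes, f2))
                freq_chain = drifted
            q = np.zeros(K)
            q[c] = 1.0
            sample_locality(freq_chain, sc.individuals_per_locality,
                            f"{names[c]}_L{j}", q)

    for a, b, w in sc.admixture_localities:
        mixed = []
        for l in range(sc.n_loci):
            sa, fa = cluster_freqs[a][l]
            sb, fb = cluster_freqs[b][l]
            allsz = np.union1d(sa, sb)
            fm = (w * np.array([fa[np.searchsorted(sa, s)] if s in sa else 0.0
                                for s in allsz])
                  + (1 - w) * np.array([fb[np.searchsorted(sb, s)] if s in sb
                                        else 0.0 for s in allsz]))
            mixed.append((allsz, fm / fm.sum()))
        q = np.zeros(K)
        q[a], q[b] = w, 1 - w
        sample_locality(mixed, sc.individuals_per_locality,
                        f"Admix_{names[a]}x{names[b]}", q)

    alleles = np.stack(rows)
    if sc.missing_rate > 0:
        drop = rng.random(alleles.shape[:2]) < sc.missing_rate
        alleles[drop] = MISSING
    gm = GenotypeMatrix(ind_ids, loc_ids, [f"Loc{l}" for l in range(sc.n_loci)],
                        alleles)
    return gm, np.array(q_rows)


def locality_table(sc: Scenario) -> LocalityTable:
    """Deterministic coordinates: clusters along a west-east line with a
    gap between clusters 0 and 1; localities evenly spaced within."""
    names = _cluster_names(sc.n_clusters)
    counts = sc.localities_counts()
    recs = []
    lon = -85.0
    for c in range(sc.n_clusters):
        if c == 1:
            lon += 2.0  # the distribution gap
        for j in range(counts[c]):
            recs.append({"locality_id": f"{names[c]}_L{j}", "latitude": 9.0,
                         "longitude": round(lon, 4), "cluster_label": names[c]})
            lon += 0.3
        lon += 0.6
    return LocalityTable(pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutate(seq: np.ndarray, expected: float, rng: np.random.Generator,
            kappa: float) -> np.ndarray:
    """Poisson substitutions; multiple hits at one site are allowed."""
    seq = seq.copy()
    n_mut = rng.poisson(expected)
    if n_mut == 0:
        return seq
    sites = rng.integers(0, seq.size, size=n_mut)
    for s in sites:
        cur = seq[s]
        ti = _TRANSITION[cur]
        tv = [b for b in "ACGT" if b != cur and b != ti]
        probs = np.array([kappa, 1.0, 1.0])
        probs = probs / probs.sum()
        seq[s] = rng.choice([ti] + tv, p=probs)
    return seq


def simulate_mtdna(sc: Scenario) -> SequenceAlignment:
    """Clock-like sequences along a caterpillar cluster tree.

    Cluster ``i`` (i < K-1) splits from the remaining lineages ``t_i`` Myr
    ago; tips within a cluster radiate ``within_cluster_myr`` ago.  Branch
    substitution counts are Poisson with mean rate × Δt × length, so the
    expected pairwise p-distance between clusters i<j is ≈ 2·r·t_i while
    distances stay small.
    """
    sc.validate()
    rng = sc.rng("mtdna")
    K, L, r = sc.n_clusters, sc.mtdna_length, sc.rate_per_lineage
    names = _cluster_names(K)
    root = rng.choice(_BASES, size=L)

    times = list(sc.split_times_myr[: max(K - 1, 0)])
    # ancestor sequence of each cluster at its split from the backbone
    cluster_anc: list[tuple[str, np.ndarray, float]] = []
    backbone, t_prev = root, times[0] if times else sc.within_cluster_myr
    if K == 1:
        cluster_anc.append((names[0], root, sc.within_cluster_myr))
    else:
        for i in range(K - 1):
            if i > 0:
                backbone = _mutate(backbone, r * (times[i - 1] - times[i]) * L,
                                   rng, sc.kappa)
            split = _mutate(backbone, 0.0, rng, sc.kappa)
            cluster_anc.append((names[i], split, times[i]))
            if i == K - 2:
                cluster_anc.append((names[i + 1], backbone.copy(), times[i]))

    ids, seqs = [], []
    tw = min(sc.within_cluster_myr, min(times) if times else np.inf)
    for name, anc, t_split in cluster_anc:
        # evolve the cluster stem down to the within-cluster radiation
        stem = _mutate(anc, r * max(t_split - tw, 0.0) * L, rng, sc.kappa)
        for m in range(sc.mt_samples_per_cluster):
            tip = _mutate(stem, r * tw * L, rng, sc.kappa)
            ids.append(f"{name}_s{m}")
            seqs.append("".join(tip))
    return SequenceAlignment(ids, seqs)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeSim:
    """Bundle returned by :func:`simulate_landscape`."""

    current: ClimateStack
    lgm: ClimateStack
    true_suitability: dict[str, Raster]        # keys north/south × current/lgm
    presences: dict[str, list[tuple[int, int]]]  # lineage -> (row, col) cells
    gap_mask: np.ndarray                       # bool (nrows, ncols)
    borders: dict[str, list[tuple[int, int]]]  # west/east range border cells


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_landscape(sc: Scenario) -> LandscapeSim:
    """Two-gradient landscape with a low-precipitation gap band.

    Precipitation rises west→east; the dry-adapted (northern/western)
    lineage is suited to the west, the wet-adapted (southern/eastern)
    lineage to the east, and a band of ``gap_width_cols`` columns in the
    middle has its precipitation reduced by ``gap_factor_current`` (current)
    or ``gap_factor_lgm`` (glacial).  True suitability of each lineage is a
    known logistic of precipitation, so recovery of the generator's band by
    the niche model can be tested against ground truth.
    """
    sc.validate()
    rng = sc.rng("landscape")
    nr, ncol = sc.grid_nrows, sc.grid_ncols
    x = np.linspace(0, 1, ncol)[None, :].repeat(nr, axis=0)
    y = np.linspace(0, 1, nr)[:, None].repeat(ncol, axis=1)

    p_lo, p_hi = sc.precip_range
    t_lo, t_hi = sc.temp_range
    precip_base = p_lo + (p_hi - p_lo) * x
    temp = t_lo + (t_hi - t_lo) * y + rng.normal(0, 0.1, size=x.shape)
    alt = 200 + 150 * rng.random(size=x.shape)

    center = int(round(sc.gap_center_frac * ncol))
    half = sc.gap_width_cols // 2
    gap_mask = np.zeros((nr, ncol), dtype=bool)
    if sc.gap_width_cols > 0:
        gap_mask[:, max(center - half, 0): center - half + sc.gap_width_cols] = True

    def build(gap_factor: float, precip_scale: float, temp_shift: float,
              stream: str) -> tuple[ClimateStack, np.ndarray]:
        noise = sc.rng(stream).normal(0, sc.climate_noise_sd, size=x.shape)
        precip = precip_base * precip_scale + noise
        precip = np.where(gap_mask, precip * gap_factor, precip)
        layers = {
            "precip": Raster(ncol, nr, sc.xllcorner, sc.yllcorner, sc.cellsize,
                             sc.nodata_value, precip),
            "temp": Raster(ncol, nr, sc.xllcorner, sc.yllcorner, sc.cellsize,
                           sc.nodata_value, temp + temp_shift),
            "alt": Raster(ncol, nr, sc.xllcorner, sc.yllcorner, sc.cellsize,
                          sc.nodata_value, alt),
        }
        return ClimateStack(layers), precip

    current, precip_cur = build(sc.gap_factor_current, 1.0, 0.0, "noise-cur")
    lgm, precip_lgm = build(sc.gap_factor_lgm, sc.lgm_precip_scale,
                            sc.lgm_temp_shift, "noise-lgm")

    # each lineage occupies a precipitation band: suitability is logistic in
    # a quadratic of precipitation, LV = σ(h − ((p − p_opt)/w)²), so the two
    # ranges abut at the middle of the gradient and a maxent fit with
    # linear + quadratic features can represent the truth exactly
    rng_p = p_hi - p_lo
    p_opt = {"south": p_lo + 0.68 * rng_p, "north": p_lo + 0.32 * rng_p}
    width = rng_p / 8.0
    height = 2.2          # peak suitability σ(h) ≈ 0.90

    def suit(precip: np.ndarray, lineage: str) -> np.ndarray:
        return _logistic(height - ((precip - p_opt[lineage]) / width) ** 2)

    ref = current.ref
    truth = {
        "north_current": ref.like(suit(precip_cur, "north")),
        "south_current": ref.like(suit(precip_cur, "south")),
        "north_lgm": ref.like(suit(precip_lgm, "north")),
        "south_lgm": ref.like(suit(precip_lgm, "south")),
    }

    presences: dict[str, list[tuple[int, int]]] = {}
    for lineage in ("north", "south"):
        s = truth[f"{lineage}_current"].values
        pool = s[~gap_mask]
        cut = np.quantile(pool, 1.0 - sc.presence_top_fraction)
        good = np.argwhere((s >= cut) & ~gap_mask)
        take = min(sc.n_presences_per_lineage, len(good))
        idx = rng.choice(len(good), size=take, replace=False)
        presences[lineage] = [tuple(c) for c in good[idx]]

    # range borders flanking the gap: the easternmost high-suitability
    # column of the western lineage and vice versa, one cell per row
    west_col = np.full(nr, -1)
    east_col = np.full(nr, -1)
    sn = truth["north_current"].values
    ss = truth["south_current"].values
    for i in range(nr):
        wn = np.where((sn[i] >= 0.5) & ~gap_mask[i])[0]
        es = np.where((ss[i] >= 0.5) & ~gap_mask[i])[0]
        if wn.size:
            west_col[i] = wn.max()
        if es.size:
            east_col[i] = es.min()
    borders = {
        "west": [(i, int(west_col[i])) for i in range(nr) if west_col[i] >= 0],
        "east": [(i, int(east_col[i])) for i in range(nr) if east_col[i] >= 0],
    }
    return LandscapeSim(current, lgm, truth, presences, gap_mask, borders)
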