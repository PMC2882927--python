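"""Classical microsatellite statistics.

Pairwise Weir–Cockerham θ (F_ST) and Slatkin R_ST from variance components,
Wright's island-model migrant estimate Nm = (1−F)/(4F), Hurlbert-rarefied
allelic richness with a cluster permutation test, great-circle distances and
Mantel isolation-by-distance tests with the three standard transforms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix, LocalityTable

__all__ = [
    "PairwiseMatrix", "RichnessTable", "fst_pairwise", "rst_pairwise",
    "nm_from_fixation", "allelic_richness", "richness_permutation_test",
    "geographic_distance_km", "mantel_test",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class PairwiseMatrix:
    """Symmetric statistic matrix over populations or sequences."""

    labels: list[str]
    values: np.ndarray
    statistic: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i<j) values as a flat vector."""
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]


@dataclass
class RichnessTable:
    """Rarefied allelic richness per population × locus at g genes."""

    per_locus: pd.DataFrame       # populations × loci
    g: int

    @property
    def mean(self) -> pd.Series:
        return self.per_locus.mean(axis=1)


# ---------------------------------------------------------------------------
# grouping helpers
# ---------------------------------------------------------------------------

def _groups(gm: GenotypeMatrix, grouping: dict[str, str] | None) -> dict[str, list[int]]:
    """Map group label -> individual row indices.

    ``grouping`` maps locality id -> group label; None groups by locality.
    """
    out: dict[str, list[int]] = {}
    for i, loc in enumerate(gm.locality_ids):
        label = grouping.get(loc, None) if grouping is not None else loc
        if label is None:
            continue
        out.setdefault(str(label), []).append(i)
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def _locus_genes(gm: GenotypeMatrix, rows: list[int], locus: int) -> np.ndarray:
    """Non-missing gene copies of one group at one locus."""
    g = gm.alleles[rows, locus, :].ravel()
    return g[g != MISSING]


# ---------------------------------------------------------------------------
# F_ST (Weir & Cockerham 1984 theta)
# ---------------------------------------------------------------------------

def _wc_components(pops: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed variance components (a, b, c) over alleles at one locus.

    ``pops`` holds per-population (n_i, 2) diploid genotype arrays with
    missing individuals already dropped.
    """
    r = len(pops)
    n_i = np.array([p.shape[0] for p in pops], dtype=float)
    if (n_i < 1).any() or r < 2:
        return 0.0, 0.0, 0.0
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    a = b = c = 0.0
    for al in alleles:
        p_i = np.array([(p == al).mean() for p in pops])
        h_i = np.array([((p[:, 0] == al) ^ (p[:, 1] == al)).mean() for p in pops])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a += (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                  - hbar / 4) / (nbar - 1))
        b += (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                    - hbar * (2 * nbar - 1) / (4 * nbar))
        c += hbar / 2
    return a, b, c


def _pair_diploids(gm: GenotypeMatrix, rows: list[int], locus: int) -> np.ndarray:
    g = gm.alleles[rows, locus, :]
    keep = (g != MISSING).all(axis=1)
    return g[keep]


def fst_pairwise(gm: GenotypeMatrix,
                 grouping: dict[str, str] | None = None) -> PairwiseMatrix:
    """Pairwise multi-locus Weir–Cockerham θ; missing genotypes dropped
    per locus (pairwise deletion).  Groups with no data at any locus yield
    NaN entries."""
    groups = _groups(gm, grouping)
    labels = list(groups)
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        num = den = 0.0
        any_data = False
        for l in range(gm.n_loci):
            pops = [_pair_diploids(gm, groups[labels[i]], l),
                    _pair_diploids(gm, groups[labels[j]], l)]
            if any(p.shape[0] < 1 for p in pops):
                continue
            a, b, c = _wc_components(pops)
            num += a
            den += a + b + c
            any_data = True
        theta = num / den if (any_data and den != 0) else np.nan
        out[i, j] = out[j, i] = theta
    return PairwiseMatrix(labels, out, "fst")


# ---------------------------------------------------------------------------
# R_ST (Slatkin 1995 via allele-size variance components)
# ---------------------------------------------------------------------------

def _rst_components(pops: list[np.ndarray]) -> tuple[float, float]:
    """(among, within) variance components of allele size at one locus.

    One-way unbalanced ANOVA on gene copies (haploid observations).
    """
    sizes = [p.astype(float) for p in pops if p.size > 0]
    if len(sizes) < 2:
        return 0.0, 0.0
    n_i = np.array([s.size for s in sizes], dtype=float)
    N = n_i.sum()
    r = len(sizes)
    means = np.array([s.mean() for s in sizes])
    grand = np.concatenate(sizes).mean()
    ss_within = sum(((s - m) ** 2).sum() for s, m in zip(sizes, means))
    ss_among = (n_i * (means - grand) ** 2).sum()
    df_w, df_a = N - r, r - 1
    if df_w <= 0 or df_a <= 0:
        return 0.0, 0.0
    ms_w = ss_within / df_w
    ms_a = ss_among / df_a
    n0 = (N - (n_i ** 2).sum() / N) / df_a
    sigma_a = (ms_a - ms_w) / n0
    return sigma_a, ms_w


def rst_pairwise(gm: GenotypeMatrix,
                 grouping: dict[str, str] | None = None) -> PairwiseMatrix:
    """Pairwise multi-locus R_ST; components summed over loci (Arlequin
    convention)."""
    groups = _groups(gm, grouping)
    labels = list(groups)
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        among = within = 0.0
        any_data = False
        for l in range(gm.n_loci):
            pops = [_locus_genes(gm, groups[labels[i]], l),
                    _locus_genes(gm, groups[labels[j]], l)]
            if any(p.size < 2 for p in pops):
                continue
            sa, sw = _rst_components(pops)
            among += sa
            within += sw
            any_data = True
        tot = among + within
        rst = among / tot if (any_data and tot != 0) else (
            0.0 if any_data else np.nan)
        out[i, j] = out[j, i] = rst
    return PairwiseMatrix(labels, out, "rst")


# ---------------------------------------------------------------------------
# Wright's island-model gene flow
# ---------------------------------------------------------------------------

def nm_from_fixation(f: float) -> float:
    """Migrants per generation, Nm = (1−F)/(4F), for a fixation index F.

    F ≤ 0 means no detectable differentiation: gene flow is effectively
    unbounded, signalled explicitly with ValueError.
    """
    if not np.isfinite(f) or f <= 0:
        raise ValueError(
            f"fixation index {f!r} <= 0: Nm undefined (unbounded gene flow)")
    if f > 1:
        raise ValueError(f"fixation index {f!r} > 1")
    return (1.0 - f) / (4.0 * f)


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def _rarefied_richness(genes: np.ndarray, g: int) -> float:
    """Hurlbert rarefaction: expected allele count in a subsample of g genes,
    AR = Σ_alleles [1 − C(N−N_i, g)/C(N, g)]."""
    N = genes.size
    if g > N:
        raise ValueError(f"rarefaction size {g} exceeds sample of {N} genes")
    _, counts = np.unique(genes, return_counts=True)

    def log_comb(n: float, k: float) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for ni in counts:
        if N - ni < g:
            total += 1.0
        else:
            total += 1.0 - np.exp(log_comb(N - ni, g) - log_comb(N, g))
    return total


def allelic_richness(gm: GenotypeMatrix, g: int | None = None,
                     grouping: dict[str, str] | None = None) -> RichnessTable:
    """Rarefied allelic richness per population × locus at g genes.

    ``g`` defaults to the smallest per-population gene count observed at
    any locus across the dataset (FSTAT convention; the unit is genes, 2n).
    """
    groups = _groups(gm, grouping)
    gene_counts = {
        (label, l): _locus_genes(gm, rows, l).size
        for label, rows in groups.items() for l in range(gm.n_loci)
    }
    min_label, min_g = min(gene_counts.items(), key=lambda kv: kv[1])
    if g is None:
        g = min_g
    elif g > min_g:
        raise ValueError(
            f"g={g} exceeds the {min_g} genes available in population "
            f"{min_label[0]!r} at locus index {min_label[1]}")
    table = {
        label: [_rarefied_richness(_locus_genes(gm, rows, l), g)
                for l in range(gm.n_loci)]
        for label, rows in groups.items()
    }
    frame = pd.DataFrame.from_dict(table, orient="index",
                                   columns=list(gm.loci))
    return RichnessTable(frame, g)


def richness_permutation_test(richness: RichnessTable,
                              clusters: dict[str, str],
                              n_perm: int = 1000,
                              seed: int | None = None) -> float:
    """Permutation P for differences in mean richness among clusters.

    The statistic is the population-weighted variance of cluster means of
    per-population mean richness; populations are permuted among clusters.
    The test is two-sided by construction: the variance statistic is large
    whenever cluster means differ in either direction, and P is the
    fraction of permutations (the observed arrangement included) with a
    statistic at least as large as observed.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation P", UserWarning)
    means = richness.mean
    pops = list(means.index)
    labels = np.array([clusters[p] for p in pops])
    values = means.to_numpy()

    def stat(lab: np.ndarray) -> float:
        total = 0.0
        grand = values.mean()
        for cl in np.unique(lab):
            sel = values[lab == cl]
            total += sel.size * (sel.mean() - grand) ** 2
        return total / values.size

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    hits = 1  # the identity arrangement
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= observed - 1e-15:
            hits += 1
    return hits / (n_perm + 1)


# ---------------------------------------------------------------------------
# Geographic distance and Mantel tests
# ---------------------------------------------------------------------------

def geographic_distance_km(table: LocalityTable) -> PairwiseMatrix:
    """Great-circle (haversine) distances in km between localities."""
    coords = np.radians(table.coords())
    lat, lon = coords[:, 0], coords[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(table.ids, d, "km")


def _mantel_r(a: np.ndarray, b: np.ndarray, iu) -> float:
    x, y = a[iu], b[iu]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def mantel_test(geo: PairwiseMatrix, gen: PairwiseMatrix,
                transform: str = "linear", n_perm: int = 1000,
                seed: int | None = None,
                exact: bool = False) -> tuple[float, float, float]:
    """Mantel correlation between a geographic and a genetic matrix.

    transforms: ``linear`` (straight-line distance vs statistic), ``log_distance``
    (ln km vs statistic), ``fst_linearized`` (ln km vs F/(1−F)).  Returns
    (r, R², P) with P from jointly permuting one matrix's rows/columns
    (one-sided, large positive r extreme).  ``exact=True`` enumerates all
    permutations instead of sampling (small n only).
    """
    if geo.labels != gen.labels:
        raise ValueError("matrices must share labels in order")
    n = len(geo.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 populations")
    A = geo.values.astype(float).copy()
    B = gen.values.astype(float).copy()
    iu = np.triu_indices(n, 1)
    if transform in ("log_distance", "fst_linearized"):
        with np.errstate(divide="ignore"):
            A = np.where(A > 0, np.log(A), np.nan)
    if transform == "fst_linearized":
        if np.any(B[iu] >= 1):
            warnings.warn("pairs with statistic = 1 are undefined after "
                          "linearization and were excluded", UserWarning)
        with np.errstate(divide="ignore", invalid="ignore"):
            B = B / (1.0 - B)
        B[~np.isfinite(B)] = np.nan
    elif transform != "linear" and transform != "log_distance":
        raise ValueError(f"unknown transform {transform!r}")

    valid = np.isfinite(A) & np.isfinite(B)
    np.fill_diagonal(valid, False)

    def corr(perm: np.ndarray) -> float:
        Bp = B[np.ix_(perm, perm)]
        Vp = valid & np.isfinite(Bp)
        x = A[np.triu_indices(n, 1)]
        mask = Vp[np.triu_indices(n, 1)]
        y = Bp[np.triu_indices(n, 1)]
        x, y = x[mask], y[mask]
        if x.size < 3 or x.std() == 0 or y.std() == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    ident = np.arange(n)
    r_obs = corr(ident)
    if exact:
        rs = [corr(np.array(p)) for p in itertools.permutations(range(n))]
        hits = sum(1 for r in rs if r >= r_obs - 1e-12)
        p = hits / len(rs)
    else:
        rng = np.random.default_rng(seed)
        hits = 1
        for _ in range(n_perm):
            if corr(rng.permutation(n)) >= r_obs - 1e-12:
                hits += 1
        p = hits / (n_perm + 1)
    return r_obs, r_obs ** 2, p
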