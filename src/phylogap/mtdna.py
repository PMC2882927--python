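"""Mitochondrial sequence analyses.

Uncorrected p and Tamura–Nei (1993) distances with pairwise deletion,
molecular-clock divergence dating (T = p / 2r with a per-lineage rate r),
DnaSP-style diversity indices (haplotypes, polymorphic sites, Hd and π with
Nei 1987 standard errors), a statistical-parsimony connection limit, and a
minimum-spanning haplotype network with TCS-style edge truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .io import SequenceAlignment

__all__ = [
    "ClockConfig", "HaplotypeTable", "DiversityReport", "p_distance",
    "tn93_distance", "divergence_time", "diversity_indices",
    "collapse_haplotypes", "parsimony_connection_limit",
    "build_haplotype_network", "group_mean_distance",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ClockConfig:
    """Molecular clock: per-lineage substitution rate in subs/site/Myr."""

    rate_per_lineage: float = 0.007

    def __post_init__(self) -> None:
        if self.rate_per_lineage <= 0:
            raise ValueError("clock rate must be positive")

    @property
    def pairwise_rate(self) -> float:
        return 2.0 * self.rate_per_lineage


@dataclass
class HaplotypeTable:
    ids: list[str]                       # haplotype labels, H1..Hk
    sequences: list[str]                 # representative sequences
    members: list[list[str]]             # sample ids per haplotype
    counts: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = [len(m) for m in self.members]

    @property
    def n_haplotypes(self) -> int:
        return len(self.ids)


@dataclass
class DiversityReport:
    n: int
    h: int
    s: int
    hd: float
    hd_sd: float
    pi: float
    pi_sd: float


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _pair_sites(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mask of sites comparable in both sequences (no gap/N)."""
    return np.isin(a, _VALID) & np.isin(b, _VALID)


def p_distance(aln: SequenceAlignment) -> "PairwiseMatrix":
    """Uncorrected proportion of differing sites, pairwise deletion.

    Pairs with zero comparable sites get NaN.
    """
    from .popgen import PairwiseMatrix
    arr = aln.array()
    n = aln.n
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        m = _pair_sites(arr[i], arr[j])
        if not m.any():
            out[i, j] = out[j, i] = np.nan
            continue
        d = float((arr[i][m] != arr[j][m]).mean())
        out[i, j] = out[j, i] = d
    return PairwiseMatrix(aln.ids, out, "p_dist")


def _tn93_pair(a: np.ndarray, b: np.ndarray) -> float:
    m = _pair_sites(a, b)
    if not m.any():
        return np.nan
    x, y = a[m], b[m]
    L = x.size
    # base frequencies estimated from the pair (both sequences pooled)
    both = np.concatenate([x, y])
    gA, gC, gG, gT = [(both == s).mean() for s in (b"A", b"C", b"G", b"T")]
    gR, gY = gA + gG, gC + gT
    diff = x != y
    pur = {b"A", b"G"}
    is_ag = diff & (np.isin(x, [b"A", b"G"]) & np.isin(y, [b"A", b"G"]))
    is_ct = diff & (np.isin(x, [b"C", b"T"]) & np.isin(y, [b"C", b"T"]))
    P1 = is_ag.mean()
    P2 = is_ct.mean()
    Q = (diff & ~is_ag & ~is_ct).mean()
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0
    if min(gR, gY) <= 0:
        return np.nan
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gT * gC / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
        w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
        w3 = 1 - Q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        return np.nan          # saturation: log-domain failure
    d = 0.0
    if k1 > 0:
        d -= k1 * np.log(w1)
    if k2 > 0:
        d -= k2 * np.log(w2)
    d -= k3 * np.log(w3)
    return float(d)


def tn93_distance(aln: SequenceAlignment) -> "PairwiseMatrix":
    """Tamura–Nei (1993) distance, no gamma correction, pairwise deletion."""
    from .popgen import PairwiseMatrix
    arr = aln.array()
    n = aln.n
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        out[i, j] = out[j, i] = _tn93_pair(arr[i], arr[j])
    return PairwiseMatrix(aln.ids, out, "tn93")


def group_mean_distance(matrix: "PairwiseMatrix",
                        groups: dict[str, str]) -> pd.DataFrame:
    """Within- (diagonal) and between-group (off-diagonal) mean distances.

    ``groups`` maps sequence id -> group label.
    """
    labels = sorted(set(groups.values()))
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    idx = {g: [i for i, sid in enumerate(matrix.labels)
               if groups.get(sid) == g] for g in labels}
    for gi in labels:
        for gj in labels:
            if gi == gj:
                pairs = [(a, b) for a, b in combinations(idx[gi], 2)]
            else:
                pairs = [(a, b) for a in idx[gi] for b in idx[gj]]
            vals = [matrix.values[a, b] for a, b in pairs]
            vals = [v for v in vals if np.isfinite(v)]
            if vals:
                out.loc[gi, gj] = float(np.mean(vals))
    return out


def divergence_time(p: float, clock: ClockConfig | None = None) -> float:
    """Myr since divergence: T = p / (2·r) with r the per-lineage rate."""
    if p < 0:
        raise ValueError("distance must be non-negative")
    clock = clock or ClockConfig()
    return p / clock.pairwise_rate


# ---------------------------------------------------------------------------
# haplotypes and diversity
# ---------------------------------------------------------------------------

def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes (exact string match,
    order-invariant numbering by first appearance)."""
    seen: dict[str, int] = {}
    seqs: list[str] = []
    members: list[list[str]] = []
    for sid, seq in zip(aln.ids, aln.sequences):
        if seq not in seen:
            seen[seq] = len(seqs)
            seqs.append(seq)
            members.append([])
        members[seen[seq]].append(sid)
    ids = [f"H{k + 1}" for k in range(len(seqs))]
    return HaplotypeTable(ids, seqs, members)


def _num_diffs(a: str, b: str) -> int:
    aa = np.frombuffer(a.encode(), dtype="S1")
    bb = np.frombuffer(b.encode(), dtype="S1")
    m = _pair_sites(aa, bb)
    return int((aa[m] != bb[m]).sum())


def diversity_indices(aln: SequenceAlignment) -> DiversityReport:
    """Haplotype and nucleotide diversity with Nei (1987) standard errors.

    Hd = n(1 − Σp_i²)/(n−1); π is the mean pairwise proportion of
    differences (pairwise deletion).  For a single sequence Hd and π are
    undefined and reported as NaN.
    """
    n = aln.n
    hap = collapse_haplotypes(aln)
    h = hap.n_haplotypes
    arr = aln.array()
    valid = np.isin(arr, _VALID)
    s = 0
    for site in range(aln.length):
        col = arr[valid[:, site], site]
        if np.unique(col).size > 1:
            s += 1
    if n < 2:
        return DiversityReport(n, h, s, np.nan, np.nan, np.nan, np.nan)

    freqs = np.array(hap.counts) / n
    sum2 = float((freqs ** 2).sum())
    hd = n * (1.0 - sum2) / (n - 1)
    sum3 = float((freqs ** 3).sum())
    # Nei 1987 eq. 8.12
    var_hd = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2)
    hd_sd = float(np.sqrt(max(var_hd, 0.0)))

    pmat = p_distance(aln)
    iu = np.triu_indices(n, 1)
    vals = pmat.values[iu]
    pi = float(np.nanmean(vals))
    # Nei 1987 eq. 10.7: stochastic + sampling variance, no recombination
    var_pi = ((n + 1) / (3.0 * (n - 1)) * pi / aln.length
              + 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1)) * pi ** 2)
    pi_sd = float(np.sqrt(max(var_pi, 0.0)))
    return DiversityReport(n, h, s, hd, hd_sd, pi, pi_sd)


# ---------------------------------------------------------------------------
# statistical parsimony
# ---------------------------------------------------------------------------

def _parsimony_probability(j: int, length: int) -> float:
    """Probability that j observed differences over ``length`` sites each
    arose from exactly one substitution.

    Per-site substitution counts are modelled as Poisson with rate
    μ = −ln(1 − j/length) (the moment estimator matching the observed
    fraction of changed sites); the probability that a changed site changed
    exactly once is μ·e^{−μ}/(1 − e^{−μ}), and sites are independent.
    """
    if j <= 0:
        return 1.0
    frac = j / length
    if frac >= 1:
        return 0.0
    mu = -np.log1p(-frac)
    single = mu * np.exp(-mu) / (1.0 - np.exp(-mu))
    return float(single ** j)


def parsimony_connection_limit(length: int, confidence: float = 0.95) -> int:
    """Largest number of mutational steps connectable with probability of
    parsimony ≥ ``confidence``.  Monotone: the limit grows as confidence
    falls and never decreases as sequences get longer."""
    if length <= 0:
        raise ValueError("alignment length must be positive")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    j = 0
    while j + 1 < length and _parsimony_probability(j + 1, length) >= confidence:
        j += 1
    return j


def build_haplotype_network(hap: HaplotypeTable, limit: int | None = None
                            ) -> nx.Graph:
    """Minimum-spanning haplotype network with TCS-style truncation.

    Edges are weighted by mutational steps (pairwise differences between
    representative sequences).  Kruskal-style construction processes weights
    in ascending order and, within one weight class, keeps *every* edge
    joining components as they stood before that class (ties create
    reticulations).  Edges longer than ``limit`` are omitted, so the network
    may fall apart into subnetworks.  Edges of length > 1 carry
    materialized unobserved intermediate nodes named ``<u>-<v>-m<i>``.
    """
    if limit is not None and limit < 1:
        raise ValueError("limit must be >= 1")
    g = nx.Graph()
    for hid, count, members in zip(hap.ids, hap.counts, hap.members):
        g.add_node(hid, count=count, members=tuple(members), inferred=False)
    dist = {}
    for (i, a), (j, b) in combinations(enumerate(hap.sequences), 2):
        dist[(hap.ids[i], hap.ids[j])] = _num_diffs(a, b)

    weights = sorted({w for w in dist.values()
                      if limit is None or w <= limit})
    comp = {hid: {hid} for hid in hap.ids}

    def find(x):
        for root, members in comp.items():
            if x in members:
                return root
        raise KeyError(x)

    kept: list[tuple[str, str, int]] = []
    for w in weights:
        # decide against the partition as of the start of this weight class
        snapshot = {x: find(x) for x in hap.ids}
        batch = [(u, v) for (u, v), d in dist.items()
                 if d == w and snapshot[u] != snapshot[v]]
        for u, v in batch:
            kept.append((u, v, w))
        for u, v in batch:
            ru, rv = find(u), find(v)
            if ru != rv:
                comp[ru] |= comp.pop(rv)

    for u, v, w in kept:
        if w <= 1:
            g.add_edge(u, v, steps=w)
        else:
            prev = u
            for i in range(1, w):
                mid = f"{u}-{v}-m{i}"
                g.add_node(mid, count=0, members=(), inferred=True)
                g.add_edge(prev, mid, steps=1)
                prev = mid
            g.add_edge(prev, v, steps=1)
        g.graph.setdefault("edges", []).append((u, v, w))
    return g
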