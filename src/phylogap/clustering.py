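"""Bayesian admixture-model clustering of multilocus genotypes.

A Gibbs sampler in the style of the classic admixture model: each gene copy
carries a latent cluster of origin z; cluster allele frequencies P get a
Dirichlet(λ=1) prior, individual membership vectors Q a symmetric
Dirichlet(α) prior with α itself updated by a Metropolis step under a
uniform prior on (0, 10].  The marginal likelihood ln Pr(X|K) is estimated
from the post-burn-in likelihood trace as mean − var/2, and the Evanno ΔK
statistic selects K from replicate runs.

The correlated-allele-frequency (F-model) prior is deliberately not
implemented: it matters for sensitivity at weak structure, while the
recovery scenarios this package targets have strong structure.  Label
switching is handled only at evaluation time, by exhaustive cost-minimal
permutation matching with lexicographic tie-breaking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix, LocalityTable

__all__ = ["ClusterFit", "DeltaKTable", "fit_admixture", "delta_k",
           "membership_by_locality", "match_labels"]

ALPHA_MAX = 10.0
ALPHA_PROPOSAL_SD = 0.05


@dataclass
class ClusterFit:
    K: int
    Q: np.ndarray                  # (n, K) posterior-mean memberships
    P: list[np.ndarray]            # per locus (K, n_alleles) posterior means
    lnPD: float                    # estimated ln Pr(X|K) = mean − var/2
    lnL_trace: np.ndarray
    alpha_trace: np.ndarray
    burnin: int
    reps: int
    seed: int | None
    allele_codes: list[np.ndarray] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)


@dataclass
class DeltaKTable:
    frame: pd.DataFrame            # index K; columns mean, sd, lprime, lsecond, delta_k

    def best_k(self) -> int:
        dk = self.frame["delta_k"].dropna()
        if dk.empty:
            raise ValueError("no interior K with defined delta K")
        return int(dk.idxmax())


def _encode(gm: GenotypeMatrix) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per locus: sorted unique allele sizes and (n, 2) integer codes
    (-1 = missing)."""
    codes, alphabets = [], []
    for l in range(gm.n_loci):
        col = gm.alleles[:, l, :]
        present = np.unique(col[col != MISSING])
        lookup = {int(a): k for k, a in enumerate(present)}
        c = np.full(col.shape, -1, dtype=np.int64)
        for a, k in lookup.items():
            c[col == a] = k
        alphabets.append(present)
        codes.append(c)
    return codes, alphabets


def fit_admixture(gm: GenotypeMatrix, K: int, burnin: int = 5000,
                  reps: int = 5000, seed: int | None = None,
                  alpha_init: float = 1.0) -> ClusterFit:
    """Run the admixture Gibbs sampler for a fixed number of clusters K.

    Sweeps alternate (i) allele-origin assignments z | Q, P; (ii) P | z with
    a Dirichlet(1) prior; (iii) Q | z with a Dirichlet(α) prior; (iv) a
    Metropolis update of α.  Q and P are posterior means over the
    post-burn-in sweeps.  Same data, seed and settings reproduce the fit to
    full precision.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if burnin <= 0 or reps <= 0:
        raise ValueError("burnin and reps must be positive")
    rng = np.random.default_rng(seed)
    n, L = gm.n_individuals, gm.n_loci
    codes, alphabets = _encode(gm)
    n_alleles = [a.size for a in alphabets]

    if K == 1:
        return _fit_single_population(gm, codes, alphabets, burnin, reps, seed)

    Q = rng.dirichlet(np.full(K, 1.0), size=n)
    P = [rng.dirichlet(np.ones(j), size=K) for j in n_alleles]
    alpha = float(alpha_init)

    Q_sum = np.zeros((n, K))
    P_sum = [np.zeros((K, j)) for j in n_alleles]
    lnL_trace = np.empty(burnin + reps)
    alpha_trace = np.empty(burnin + reps)
    warn: list[str] = []

    obs = [codes[l] for l in range(L)]                 # (n, 2) codes
    masks = [o >= 0 for o in obs]

    for sweep in range(burnin + reps):
        counts_kla = [np.zeros((K, j)) for j in n_alleles]
        n_ik = np.zeros((n, K))
        lnL = 0.0
        for l in range(L):
            o, m = obs[l], masks[l]
            if not m.any():
                continue
            # P[l][:, o] -> (K, n, 2); probability of each origin
            pa = P[l][:, np.where(m, o, 0)]            # (K, n, 2)
            w = Q.T[:, :, None] * pa                   # (K, n, 2)
            tot = w.sum(axis=0)                        # (n, 2)
            lnL += float(np.log(tot[m]).sum())
            probs = np.where(m[None], w / np.maximum(tot[None], 1e-300), 0.0)
            cum = probs.cumsum(axis=0)
            u = rng.random((n, 2))
            z = (u[None] > cum).sum(axis=0)            # (n, 2) in 0..K-1
            z = np.clip(z, 0, K - 1)
            zm = z[m]
            om = o[m]
            np.add.at(counts_kla[l], (zm, om), 1.0)
            ind = np.nonzero(m)[0] if m.ndim == 1 else np.repeat(
                np.arange(n)[:, None], 2, axis=1)[m]
            np.add.at(n_ik, (ind, zm), 1.0)
        # P | z
        for l in range(L):
            P[l] = rng.gamma(counts_kla[l] + 1.0)
            P[l] /= P[l].sum(axis=1, keepdims=True)
        # Q | z  (tiny floor guards against gamma-draw underflow at small α)
        Q = rng.gamma(n_ik + alpha) + 1e-300
        Q /= Q.sum(axis=1, keepdims=True)
        # alpha | Q (Metropolis, uniform prior on (0, ALPHA_MAX])
        prop = alpha + rng.normal(0, ALPHA_PROPOSAL_SD)
        if 0 < prop <= ALPHA_MAX:
            logq = float(np.log(np.maximum(Q, 1e-300)).sum())
            def logdens(a: float) -> float:
                return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1) * logq
            if np.log(rng.random()) < logdens(prop) - logdens(alpha):
                alpha = prop
        lnL_trace[sweep] = lnL
        alpha_trace[sweep] = alpha
        if sweep >= burnin:
            Q_sum += Q
            for l in range(L):
                P_sum[l] += P[l]

    post = lnL_trace[burnin:]
    lnPD = float(post.mean() - post.var() / 2.0)
    if alpha_trace[burnin:].std() > 0 and (
            alpha_trace[burnin:].max() >= ALPHA_MAX - ALPHA_PROPOSAL_SD):
        warn.append("alpha drifted to its upper prior bound; membership "
                    "prior may be poorly identified")
        warnings.warn(warn[-1], UserWarning)
    return ClusterFit(K, Q_sum / reps, [s / reps for s in P_sum], lnPD,
                      lnL_trace, alpha_trace, burnin, reps, seed,
                      alphabets, warn)


def _fit_single_population(gm, codes, alphabets, burnin, reps, seed):
    """K = 1: Q is exactly 1; sample P from its posterior for the trace."""
    rng = np.random.default_rng(seed)
    n, L = gm.n_individuals, gm.n_loci
    lnL_trace = np.empty(burnin + reps)
    P_sum = [np.zeros((1, a.size)) for a in alphabets]
    counts = []
    for l in range(L):
        o = codes[l]
        om = o[o >= 0]
        counts.append(np.bincount(om, minlength=alphabets[l].size).astype(float))
    for sweep in range(burnin + reps):
        lnL = 0.0
        for l in range(L):
            p = rng.gamma(counts[l] + 1.0)
            p /= p.sum()
            lnL += float((counts[l] * np.log(p)).sum())
            if sweep >= burnin:
                P_sum[l] += p
        lnL_trace[sweep] = lnL
    post = lnL_trace[burnin:]
    lnPD = float(post.mean() - post.var() / 2.0)
    return ClusterFit(1, np.ones((n, 1)), [s / reps for s in P_sum], lnPD,
                      lnL_trace, np.full(burnin + reps, np.nan), burnin,
                      reps, seed, alphabets, [])


# ---------------------------------------------------------------------------
# Evanno delta K
# ---------------------------------------------------------------------------

def delta_k(runs: dict[int, list[float]] | list[tuple[int, list[float]]]) -> DeltaKTable:
    """Evanno table from replicate ln Pr(X|K) estimates per K.

    ΔK(K) = |mean(K+1) − 2·mean(K) + mean(K−1)| / sd(K), defined for
    interior K only; sd is over replicate runs at K (ddof=1).  A zero sd
    leaves ΔK undefined (NaN) at that K.
    """
    if not isinstance(runs, dict):
        runs = dict(runs)
    ks = sorted(runs)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicate runs per K")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for idx, k in enumerate(ks):
        lprime = mean[k] - mean[ks[idx - 1]] if idx > 0 else np.nan
        if 0 < idx < len(ks) - 1:
            lsecond = abs(mean[ks[idx + 1]] - 2 * mean[k] + mean[ks[idx - 1]])
            dk = lsecond / sd[k] if sd[k] > 0 else np.nan
        else:
            lsecond = dk = np.nan
        rows.append({"K": k, "mean_lnPD": mean[k], "sd_lnPD": sd[k],
                     "lprime": lprime, "lsecond": lsecond, "delta_k": dk})
    frame = pd.DataFrame(rows).set_index("K")
    return DeltaKTable(frame)


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def membership_by_locality(fit: ClusterFit, gm: GenotypeMatrix) -> pd.DataFrame:
    """Mean membership proportions per sample locality (rows sum to 1)."""
    frame = pd.DataFrame(fit.Q, index=gm.locality_ids)
    out = frame.groupby(level=0, sort=False).mean()
    out.columns = [f"cluster_{k}" for k in range(fit.K)]
    return out


def match_labels(Q: np.ndarray, true_Q: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Cost-minimal permutation of inferred clusters onto true clusters.

    Returns (permutation, agreement) where permutation[k] is the true
    cluster matched to inferred cluster k and agreement is the fraction of
    individuals whose permuted argmax matches the true argmax.  Among
    equal-cost matchings the lexicographically smallest permutation wins.
    """
    K = Q.shape[1]
    if true_Q.shape[1] != K:
        raise ValueError("Q matrices must share K")
    best: tuple[float, tuple[int, ...]] | None = None
    for perm in itertools.permutations(range(K)):
        cost = float(np.abs(Q[:, list(perm)] - true_Q).sum())
        if best is None or cost < best[0] - 1e-12:
            best = (cost, perm)
    assert best is not None
    perm = best[1]
    agree = float(
        (Q[:, list(perm)].argmax(axis=1) == true_Q.argmax(axis=1)).mean())
    return perm, agree
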