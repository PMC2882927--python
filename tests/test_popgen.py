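"""Fixation indices, gene flow, rarefaction, distances and Mantel tests
against hand and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from phylogap.io import MISSING, LocalityTable
from phylogap.popgen import (PairwiseMatrix, allelic_richness, fst_pairwise,
                             geographic_distance_km, mantel_test,
                             nm_from_fixation, richness_permutation_test,
                             rst_pairwise)
from phylogap.simulate import (Scenario, locality_table,
                               simulate_microsatellites)

A, B, C = 100, 102, 104


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _wc_theta_oracle(pops):
    """Straight transcription of the Weir-Cockerham (1984) estimator for
    diploid data, coded independently of the implementation."""
    r = len(pops)
    n_i = np.array([len(p) for p in pops], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted({a for p in pops for g in p for a in g})
    num = den = 0.0
    for al in alleles:
        p_i = np.array([np.mean([g.count(al) / 2 for g in p]) for p in pops])
        h_i = np.array([np.mean([g.count(al) == 1 for g in p]) for p in pops])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a_ = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                  - hbar / 4) / (nbar - 1))
        b_ = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                    - hbar * (2 * nbar - 1) / (4 * nbar))
        c_ = hbar / 2
        num += a_
        den += a_ + b_ + c_
    return num / den


def test_fst_matches_weir_cockerham_hand_oracle():
    # pop1 carries 8 A / 2 B gene copies, pop2 the reverse
    pop1 = [[A, A], [A, A], [A, A], [A, B], [A, B]]
    pop2 = [[B, B], [B, B], [B, B], [A, B], [A, B]]
    gm = make_matrix({"p1": [[g] for g in pop1], "p2": [[g] for g in pop2]})
    got = fst_pairwise(gm).values[0, 1]
    want = _wc_theta_oracle([[tuple(g) for g in pop1],
                             [tuple(g) for g in pop2]])
    assert got == pytest.approx(want, rel=1e-12)
    assert got == pytest.approx(0.4852941176470589)


def test_fst_fixed_difference_is_one():
    gm = make_matrix({
        "p1": [[[A, A], [C, C]]] * 4,
        "p2": [[[B, B], [A, A]]] * 4,
    })
    assert fst_pairwise(gm).values[0, 1] == pytest.approx(1.0)


def test_fst_null_two_samples_one_pool():
    rng = np.random.default_rng(3)
    draws = rng.choice([A, B, C], p=[0.5, 0.3, 0.2], size=(100, 3, 2))
    gm = make_matrix({"p1": draws[:50].tolist(), "p2": draws[50:].tolist()})
    assert abs(fst_pairwise(gm).values[0, 1]) < 0.02


def test_fst_invariant_to_allele_relabeling():
    rng = np.random.default_rng(9)
    draws = rng.choice([A, B, C], size=(30, 2, 2))
    gm = make_matrix({"p1": draws[:15].tolist(), "p2": draws[15:].tolist()})
    relabel = {A: 200, B: 317, C: 55}
    shuffled = np.vectorize(relabel.get)(draws)
    gm2 = make_matrix({"p1": shuffled[:15].tolist(),
                       "p2": shuffled[15:].tolist()})
    assert fst_pairwise(gm).values[0, 1] == pytest.approx(
        fst_pairwise(gm2).values[0, 1])


# ---------------------------------------------------------------------------
# R_ST
# ---------------------------------------------------------------------------

def test_rst_identical_distributions_near_zero():
    # unbiased variance components carry an O(1/N) negative bias, so a
    # large identical composition is needed for a tight zero
    geno = ([[[A, B]], [[A, A]], [[B, B]], [[A, B]]]) * 15
    gm = make_matrix({"p1": geno, "p2": geno})
    assert rst_pairwise(gm).values[0, 1] == pytest.approx(0.0, abs=0.02)


def test_rst_all_variance_among_groups_is_one():
    gm = make_matrix({"p1": [[[100, 100]]] * 3, "p2": [[[110, 110]]] * 3})
    assert rst_pairwise(gm).values[0, 1] == pytest.approx(1.0)


def test_rst_matches_direct_variance_component_oracle():
    g1 = [[100, 102], [102, 102], [100, 100]]
    g2 = [[106, 108], [108, 108], [106, 110]]
    gm = make_matrix({"p1": [[g] for g in g1], "p2": [[g] for g in g2]})
    x1 = np.array(g1, dtype=float).ravel()
    x2 = np.array(g2, dtype=float).ravel()
    grand = np.concatenate([x1, x2]).mean()
    ssw = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    ssa = 6 * ((x1.mean() - grand) ** 2 + (x2.mean() - grand) ** 2)
    msw, msa = ssw / 10, ssa / 1
    n0 = (12 - (36 + 36) / 12) / 1
    sa = (msa - msw) / n0
    assert rst_pairwise(gm).values[0, 1] == pytest.approx(sa / (sa + msw))


def test_rst_invariant_to_affine_size_shift():
    rng = np.random.default_rng(1)
    draws = rng.integers(100, 110, size=(20, 2, 2))
    gm = make_matrix({"p1": draws[:10].tolist(), "p2": draws[10:].tolist()})
    gm2 = make_matrix({"p1": (draws[:10] + 50).tolist(),
                       "p2": (draws[10:] + 50).tolist()})
    assert rst_pairwise(gm).values[0, 1] == pytest.approx(
        rst_pairwise(gm2).values[0, 1])


# ---------------------------------------------------------------------------
# Nm
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("f, want", [
    (0.0300, 8.0833),      # printed migration-rate cell from R_ST 0.0300
    (0.7810, 0.0701),      # printed cell from R_ST 0.7810
    (0.2, 1.0),            # closed form
])
def test_nm_island_model_values(f, want):
    assert nm_from_fixation(f) == pytest.approx(want, abs=5e-5)


def test_nm_rejects_non_positive_fixation():
    with pytest.raises(ValueError, match="unbounded"):
        nm_from_fixation(0.0)
    with pytest.raises(ValueError):
        nm_from_fixation(-0.1)


def test_nm_inverse_round_trip():
    for f in np.linspace(0.01, 1.0, 25):
        nm = nm_from_fixation(f)
        assert 1.0 / (4.0 * nm + 1.0) == pytest.approx(f)


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------

def test_richness_monomorphic_locus_is_one():
    gm = make_matrix({"p1": [[[A, A]]] * 5, "p2": [[[A, A]]] * 5})
    table = allelic_richness(gm, g=4)
    assert (table.per_locus.to_numpy() == 1.0).all()


def test_richness_at_full_sample_equals_observed_alleles():
    gm = make_matrix({"p1": [[[A, A]], [[A, B]], [[B, C]]],
                      "p2": [[[A, A]], [[A, A]], [[A, A]]]})
    table = allelic_richness(gm, g=6)
    assert table.per_locus.loc["p1"].iloc[0] == pytest.approx(3.0)
    assert table.per_locus.loc["p2"].iloc[0] == pytest.approx(1.0)


def test_richness_equals_exhaustive_subsample_enumeration():
    # 6 genes A,A,A,B,B,C rarefied to g = 4: compare with the average
    # allele count over all C(6,4) subsamples
    genes = [A, A, A, B, B, C]
    gm = make_matrix({"p1": [[[A, A]], [[A, B]], [[B, C]]],
                      "p2": [[[A, A]], [[A, A]], [[A, A]]]})
    want = np.mean([len(set(sub))
                    for sub in itertools.combinations(genes, 4)])
    got = allelic_richness(gm, g=4).per_locus.loc["p1"].iloc[0]
    assert got == pytest.approx(want)


def test_richness_g_too_large_names_limiting_population():
    gm = make_matrix({"p1": [[[A, B]]] * 4, "tiny": [[[A, MISSING]]]})
    with pytest.raises(ValueError, match="tiny"):
        allelic_richness(gm, g=4)


def test_richness_permutation_identical_values_p_one():
    table = allelic_richness(
        make_matrix({f"p{k}": [[[A, B]], [[A, B]]] for k in range(6)}), g=2)
    p = richness_permutation_test(
        table, {f"p{k}": "x" if k < 3 else "y" for k in range(6)},
        n_perm=200, seed=0)
    assert p == 1.0


def test_richness_permutation_detects_cluster_offset():
    # 10 populations per cluster; one cluster much richer
    pops = {}
    rng = np.random.default_rng(0)
    for k in range(10):
        pops[f"lo{k}"] = [[[A, A]], [[A, A]], [[A, B]]]
    for k in range(10):
        pops[f"hi{k}"] = [[[A, B]], [[C, 106]], [[108, 110]]]
    table = allelic_richness(make_matrix(pops), g=4)
    clusters = {p: ("lo" if p.startswith("lo") else "hi") for p in pops}
    p1 = richness_permutation_test(table, clusters, n_perm=999, seed=1)
    p2 = richness_permutation_test(table, clusters, n_perm=999, seed=1)
    assert p1 < 0.01
    assert p1 == p2                       # seeded determinism


def test_richness_warns_for_few_permutations():
    table = allelic_richness(
        make_matrix({"p1": [[[A, B]]] * 2, "p2": [[[A, A]]] * 2}), g=2)
    with pytest.warns(UserWarning):
        richness_permutation_test(table, {"p1": "x", "p2": "y"}, n_perm=50,
                                  seed=0)


# ---------------------------------------------------------------------------
# geography and Mantel
# ---------------------------------------------------------------------------

def test_haversine_degree_of_longitude_at_equator():
    table = LocalityTable(pd.DataFrame({
        "locality_id": ["o", "e"], "latitude": [0.0, 0.0],
        "longitude": [0.0, 1.0]}))
    d = geographic_distance_km(table)
    assert d.values[0, 0] == 0.0
    assert d.values[0, 1] == pytest.approx(111.195, abs=1e-3)


def test_haversine_symmetric_on_random_points():
    rng = np.random.default_rng(2)
    table = LocalityTable(pd.DataFrame({
        "locality_id": [f"l{k}" for k in range(8)],
        "latitude": rng.uniform(-60, 60, 8),
        "longitude": rng.uniform(-170, 170, 8)}))
    d = geographic_distance_km(table).values
    np.testing.assert_allclose(d, d.T)
    assert (np.diag(d) == 0).all()


def _toy_matrices(n=5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    labels = [f"p{k}" for k in range(n)]
    return (PairwiseMatrix(labels, a, "km"),
            PairwiseMatrix(labels, a.copy(), "rst"))


def test_mantel_self_correlation_is_one_with_smallest_p():
    geo, gen = _toy_matrices()
    r, r2, p = mantel_test(geo, gen, n_perm=99, seed=0)
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)
    assert p == pytest.approx(1.0 / 100.0)


def test_mantel_exact_enumeration_matches_independent_oracle():
    rng = np.random.default_rng(4)
    labels = list("abcd")
    a = rng.random((4, 4)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
    b = rng.random((4, 4)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
    geo = PairwiseMatrix(labels, a, "km")
    gen = PairwiseMatrix(labels, b, "rst")
    _, _, p = mantel_test(geo, gen, exact=True)
    iu = np.triu_indices(4, 1)

    def corr(perm):
        bp = b[np.ix_(perm, perm)]
        return np.corrcoef(a[iu], bp[iu])[0, 1]

    r_obs = corr([0, 1, 2, 3])
    perms = list(itertools.permutations(range(4)))
    want = np.mean([corr(list(pm)) >= r_obs - 1e-12 for pm in perms])
    assert p == pytest.approx(want)


def test_mantel_linearized_transform_warns_on_unit_statistic():
    geo, gen = _toy_matrices()
    gen.values[0, 1] = gen.values[1, 0] = 1.0
    with pytest.warns(UserWarning):
        mantel_test(geo, gen, transform="fst_linearized", n_perm=49, seed=0)


def test_mantel_r_increases_with_generator_ibd_slope():
    """Serial-founder drift along the locality line yields isolation by
    distance whose Mantel correlation strengthens with the drift slope
    (averaged over a handful of generator seeds)."""
    def mean_r(slope):
        out = []
        for seed in range(5):
            sc = Scenario(seed=seed, n_clusters=1, localities_per_cluster=10,
                          individuals_per_locality=15, ibd_slope=slope,
                          divergence_steps=0, split_times_myr=())
            gm, _ = simulate_microsatellites(sc)
            geo = geographic_distance_km(locality_table(sc))
            gen = rst_pairwise(gm)
            gen = PairwiseMatrix(
                geo.labels,
                gen.to_frame().loc[geo.labels, geo.labels].to_numpy(), "rst")
            out.append(mantel_test(geo, gen, n_perm=49, seed=1)[0])
        return float(np.mean(out))

    r0, r1, r2 = (mean_r(s) for s in (0.0, 0.02, 0.08))
    assert r0 < r1 < r2
    assert r2 > 0.3
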