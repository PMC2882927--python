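"""Sequence distances, clock dating, diversity and the parsimony network."""

import math

import numpy as np
import pytest

from phylogap.io import SequenceAlignment
from phylogap.mtdna import (ClockConfig, build_haplotype_network,
                            collapse_haplotypes, divergence_time,
                            diversity_indices, group_mean_distance,
                            p_distance, parsimony_connection_limit,
                            tn93_distance)
from phylogap.simulate import Scenario, simulate_mtdna

# 5-sequence alignment with the TN93 matrix computed by an independent
# implementation of the same published estimator (frozen oracle values)
_ORACLE_SEQS = [
    "CTTATAACCTACAAGCGGAGGACAGTGGCCGGGCTACGTTTGCAGTGTTATGTAAATCATCGTTCTCACGAATGTCCATCCCACAGTGTGTCGGGTGGGTGTTGAACTACATCTGGCTAG",
    "CCTATCATATACCCGCTGGGGACAGTGGCCGGGCTACGCTCGCATTGTTGTGTATATTATCGATTTCCCGAATGTCCATCCCACAGTTTGTCGGGTGGGCGTTGTACAAAAACTGGATAG",
    "CCTATCATCTCCCCGCAGAGGACAGGGCCCGGGCTCCGCTGGCATTGTCATGTAAAACGTAGATCTGACGAATGTCCATCCCCCAGTGTGTCTGGTGGGTGTTGTGCTAAATCGGGATAC",
    "CCTATAATATCGCCGAAGAGGACAGTCGCCGGGCTACGCTCTCATTGTTATATAACTCAGTGATTTCACGAATGTACATTCCACAGGGGGGCGGGTGGGTGTTGTACCCAATCTAACTAG",
    "GCTCGAATCTACCAGCCGAGGACAATTGCTGGGGTAAGCGCGAATTGTAATGTAAATCATCCATGTCACGAATATCCATCCTACAGTATGTCCGGTGGGAGTTGTATTGAATCTGGTTAG",
]
_ORACLE_TN93 = np.array([
    [0.0000000, 0.2360461, 0.2681384, 0.3198022, 0.3198022],
    [0.2360461, 0.0000000, 0.2676979, 0.2920278, 0.3297164],
    [0.2681384, 0.2676979, 0.0000000, 0.3569388, 0.3989900],
    [0.3198022, 0.2920278, 0.3569388, 0.0000000, 0.4420236],
    [0.3198022, 0.3297164, 0.3989900, 0.4420236, 0.0000000],
])
_ORACLE_P = np.array([
    [0.0000000, 0.2000000, 0.2250000, 0.2583333, 0.2583333],
    [0.2000000, 0.0000000, 0.2250000, 0.2416667, 0.2666667],
    [0.2250000, 0.2250000, 0.0000000, 0.2833333, 0.3083333],
    [0.2583333, 0.2416667, 0.2833333, 0.0000000, 0.3333333],
    [0.2583333, 0.2666667, 0.3083333, 0.3333333, 0.0000000],
])


def _aln(*seqs, ids=None):
    return SequenceAlignment(ids or [f"s{k}" for k in range(len(seqs))],
                             list(seqs))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_p_distance_identical_sequences_zero():
    aln = _aln("ACGTACGT", "ACGTACGT")
    assert p_distance(aln).values[0, 1] == 0.0


def test_p_distance_nine_differences_over_487_sites():
    base = ("ACGT" * 122)[:487]
    mutated = list(base)
    for pos in (3, 50, 100, 150, 200, 250, 300, 400, 486):
        mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
    aln = _aln(base, "".join(mutated))
    assert p_distance(aln).values[0, 1] == pytest.approx(9 / 487)
    assert round(p_distance(aln).values[0, 1], 4) == 0.0185


def test_p_distance_matches_brute_force_site_count():
    rng = np.random.default_rng(8)
    a = rng.choice(list("ACGT"), 300)
    b = a.copy()
    idx = rng.choice(300, 40, replace=False)
    for i in idx:
        b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
    b[[5, 17]] = "-", "N"
    aln = _aln("".join(a), "".join(b))
    comparable = [(x, y) for x, y in zip(a, b) if y in "ACGT"]
    want = sum(x != y for x, y in comparable) / len(comparable)
    assert p_distance(aln).values[0, 1] == pytest.approx(want)


def test_p_distance_gap_only_overlap_flagged():
    aln = _aln("AC--", "--GT")
    assert np.isnan(p_distance(aln).values[0, 1])


def test_tn93_matches_independent_oracle():
    aln = _aln(*_ORACLE_SEQS)
    got = tn93_distance(aln).values
    np.testing.assert_allclose(got, _ORACLE_TN93, atol=2e-3)
    np.testing.assert_allclose(p_distance(aln).values, _ORACLE_P, atol=1e-7)


def test_tn93_transversion_only_reduces_to_kimura_form():
    # equal base frequencies, only transversions: TN93 collapses to the
    # two-parameter closed form with P = 0,
    # d = -1/2 ln(1-Q) - 1/4 ln(1-2Q)
    a = list("ACGT" * 30)
    b = a.copy()
    swaps = {"A": "C", "C": "A", "G": "T", "T": "G"}   # transversions,
    for pos in range(12):                              # frequency-balanced
        b[pos] = swaps[b[pos]]
    aln = _aln("".join(a), "".join(b))
    q = 12 / 120
    want = -0.5 * math.log(1 - q) - 0.25 * math.log(1 - 2 * q)
    got = tn93_distance(aln).values[0, 1]
    assert got == pytest.approx(want, rel=1e-9)


def test_tn93_never_below_p_distance():
    aln = simulate_mtdna(Scenario(seed=3, n_clusters=2,
                                  split_times_myr=(5.0,), kappa=4.0))
    tn = tn93_distance(aln).values
    p = p_distance(aln).values
    ok = np.isfinite(tn)
    assert (tn[ok] + 1e-12 >= p[ok]).all()


def test_group_mean_distance_within_and_between():
    aln = _aln("AAAA", "AAAT", "TTTT", "TTTA", ids=list("abcd"))
    groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
    out = group_mean_distance(p_distance(aln), groups)
    assert out.loc["g1", "g1"] == pytest.approx(0.25)
    assert out.loc["g2", "g2"] == pytest.approx(0.25)
    assert out.loc["g1", "g2"] == pytest.approx((1.0 + 0.75 + 0.75 + 1.0) / 4)


# ---------------------------------------------------------------------------
# molecular clock
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p, want", [(0.078, 5.57), (0.020, 1.43), (0.0, 0.0)])
def test_divergence_time_table_values(p, want):
    assert round(divergence_time(p, ClockConfig(0.007)), 2) == want


def test_divergence_time_linear_in_distance():
    clock = ClockConfig(0.007)
    ps = np.linspace(0, 0.1, 7)
    ts = [divergence_time(p, clock) for p in ps]
    np.testing.assert_allclose(ts, ps / 0.014)


def test_clock_recovers_generating_split_time():
    """Between-cluster mean p converted by T = p/2r recovers the
    generating split within 15% averaged over 20 seeds (JC multiple-hit
    loss at these depths is ~5%)."""
    r, T_true = 0.007, 5.0
    estimates = []
    for seed in range(20):
        sc = Scenario(seed=seed, n_clusters=2, split_times_myr=(T_true,),
                      within_cluster_myr=0.05, mt_samples_per_cluster=10)
        aln = simulate_mtdna(sc)
        groups = {sid: sid.rsplit("_s", 1)[0] for sid in aln.ids}
        mean_p = group_mean_distance(p_distance(aln), groups).loc[
            "North", "South"]
        estimates.append(divergence_time(mean_p, ClockConfig(r)))
    assert abs(np.mean(estimates) - T_true) / T_true < 0.15


# ---------------------------------------------------------------------------
# haplotypes, diversity
# ---------------------------------------------------------------------------

def test_haplotype_collapse_counts_and_idempotence():
    aln = _aln("AAAA", "AAAT", "AAAA", "AAAT", "AAAA", ids=list("abcde"))
    hap = collapse_haplotypes(aln)
    assert hap.counts == [3, 2]
    assert sum(hap.counts) == aln.n
    rev = collapse_haplotypes(
        SequenceAlignment(aln.ids[::-1], aln.sequences[::-1]))
    assert sorted(rev.counts) == sorted(hap.counts)


def test_diversity_ten_identical_sequences():
    aln = _aln(*["ACGT" * 20] * 10)
    d = diversity_indices(aln)
    assert (d.n, d.h, d.s) == (10, 1, 0)
    assert d.hd == 0.0 and d.pi == 0.0
    assert d.hd_sd == 0.0 and d.pi_sd == 0.0


def test_diversity_two_sequences_nine_differences():
    base = ("ACGT" * 122)[:487]
    mutated = list(base)
    for pos in range(9):
        mutated[pos * 30] = {"A": "C", "C": "G", "G": "T",
                             "T": "A"}[mutated[pos * 30]]
    d = diversity_indices(_aln(base, "".join(mutated)))
    assert (d.n, d.h, d.s) == (2, 2, 9)
    assert d.hd == pytest.approx(1.0)
    assert d.hd_sd == pytest.approx(0.5)
    assert round(d.pi, 4) == 0.0185


def test_diversity_two_plus_two_split_closed_form():
    aln = _aln("AAAA", "AAAA", "TTTT", "TTTT")
    d = diversity_indices(aln)
    assert d.hd == pytest.approx((4 / 3) * 0.5)


def test_single_sequence_diversity_undefined():
    d = diversity_indices(_aln("ACGT"))
    assert (d.h, d.s) == (1, 0)
    assert np.isnan(d.hd) and np.isnan(d.pi)


# ---------------------------------------------------------------------------
# statistical parsimony and network
# ---------------------------------------------------------------------------

def _limit_oracle(length, confidence):
    """Independent straight-line reimplementation of the connection limit."""
    j = 0
    while True:
        cand = j + 1
        frac = cand / length
        if frac >= 1:
            break
        mu = -math.log(1 - frac)
        prob = (mu * math.exp(-mu) / (1 - math.exp(-mu))) ** cand
        if prob < confidence:
            break
        j = cand
    return j


def test_connection_limit_matches_dual_implementation():
    for length in (100, 360, 487, 1000):
        assert parsimony_connection_limit(length, 0.95) == \
            _limit_oracle(length, 0.95)


def test_connection_limit_monotone_in_confidence_and_length():
    limits = [parsimony_connection_limit(487, c)
              for c in (0.99, 0.95, 0.90, 0.50)]
    assert limits == sorted(limits)
    assert parsimony_connection_limit(974, 0.95) >= \
        parsimony_connection_limit(487, 0.95)


def test_network_single_step_edge():
    hap = collapse_haplotypes(_aln("AAAA", "AAAT", ids=["x", "y"]))
    g = build_haplotype_network(hap)
    assert g.number_of_edges() == 1
    assert g.edges["H1", "H2"]["steps"] == 1


def test_network_excludes_redundant_long_edge():
    # pairwise steps (1, 1, 2): the 2-step edge is redundant in the MSN
    hap = collapse_haplotypes(_aln("AAAA", "AAAT", "AATT",
                                   ids=["x", "y", "z"]))
    g = build_haplotype_network(hap)
    kept = {tuple(sorted((u, v))) for u, v, w in g.graph["edges"]}
    assert ("H1", "H3") not in kept
    assert len(g.graph["edges"]) == 2


def test_network_materializes_intermediates():
    hap = collapse_haplotypes(_aln("AAAA", "AATT", ids=["x", "y"]))
    g = build_haplotype_network(hap, limit=5)
    inferred = [n for n, d in g.nodes(data=True) if d["inferred"]]
    assert len(inferred) == 1
    assert g.number_of_edges() == 2       # H1 - mid - H2


def test_network_components_recover_generating_clades():
    sc = Scenario(seed=6, n_clusters=3, split_times_myr=(8.0, 6.0),
                  within_cluster_myr=0.1, mt_samples_per_cluster=5,
                  mtdna_length=487)
    aln = simulate_mtdna(sc)
    hap = collapse_haplotypes(aln)
    limit = parsimony_connection_limit(aln.length, 0.95)
    g = build_haplotype_network(hap, limit)
    import networkx as nx
    comps = list(nx.connected_components(g))
    assert len(comps) >= 3
    # members of one haplotype component share their generating cluster
    for comp in comps:
        clades = set()
        for node in comp:
            for member in g.nodes[node]["members"]:
                clades.add(member.rsplit("_s", 1)[0])
        assert len(clades) == 1
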