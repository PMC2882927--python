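import numpy as np
import pytest

from phylogap.io import GenotypeMatrix
from phylogap.simulate import Scenario, simulate_microsatellites


@pytest.fixture(scope="session")
def two_cluster_scenario() -> Scenario:
    """Strong two-cluster structure, small enough for MCMC in seconds."""
    return Scenario(seed=42, n_clusters=2, localities_per_cluster=3,
                    individuals_per_locality=10, divergence_steps=10,
                    split_times_myr=(5.2,))


@pytest.fixture(scope="session")
def two_cluster_data(two_cluster_scenario):
    return simulate_microsatellites(two_cluster_scenario)


def make_matrix(pop_genotypes: dict[str, list[list[list[int]]]],
                loci: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {pop: [[ [a,b] per locus ] per ind]}."""
    ids, locs, rows = [], [], []
    for pop, inds in pop_genotypes.items():
        for k, geno in enumerate(inds):
            ids.append(f"{pop}_i{k}")
            locs.append(pop)
            rows.append(geno)
    alleles = np.asarray(rows)
    n_loci = alleles.shape[1]
    return GenotypeMatrix(ids, locs, loci or [f"L{l}" for l in range(n_loci)],
                          alleles)
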