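import itertools

import numpy as np
import pytest

import gbdtax as gx
from gbdtax.simulate import SimConfig, simulate_taxon_set

COHORT_SEED = 1


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted cohort (3 species x 2 subspecies x 4 strains,
    50 kb genomes) with its distance matrix and HSP cache.

    Session-scoped: the pairwise matrix is the expensive step and several
    test modules inspect the same cohort.
    """
    genomes, truth = simulate_taxon_set(SimConfig(seed=COHORT_SEED))
    matrix, cache = gx.pairwise_matrix(genomes, "identities_per_hsp")
    return genomes, truth, matrix, cache


@pytest.fixture(scope="session")
def model():
    return gx.default_model()


def pair_level(a: str, b: str) -> str:
    """Planted relationship of two strain ids of the default cohort."""
    pa, pb = a.split("-"), b.split("-")
    if pa[0] != pb[0]:
        return "species"
    if pa[1] != pb[1]:
        return "subspecies"
    return "strain"


def band_distances(matrix: gx.DistanceMatrix) -> dict[str, list[float]]:
    bands: dict[str, list[float]] = {"species": [], "subspecies": [], "strain": []}
    for i, j in itertools.combinations(range(len(matrix)), 2):
        bands[pair_level(matrix.labels[i], matrix.labels[j])].append(
            float(matrix.values[i, j])
        )
    return bands
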