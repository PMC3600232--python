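import itertools

import numpy as np
import pytest

from rindom import ResidueNetwork, SyntheticSpec, generate


def make_network(n, edges, structure_id="test"):
    """Residue network over n dummy residues A/1..A/n with the given edges."""
    return ResidueNetwork(
        vertices=[("A", i + 1, "") for i in range(n)],
        edges={tuple(sorted(e)) for e in edges},
        structure_id=structure_id,
    )


def clique_pair_network(k, bridge=((0, None),)):
    """Two k-cliques on vertices 0..k-1 and k..2k-1 joined by bridge edges.

    ``bridge`` pairs are (i, j) with j offset into the second clique; j=None
    means the mirror vertex i+k.
    """
    edges = set(itertools.combinations(range(k), 2))
    edges |= {(i + k, j + k) for i, j in itertools.combinations(range(k), 2)}
    for i, j in bridge:
        edges.add((i, (i if j is None else j) + k))
    return make_network(2 * k, edges)


@pytest.fixture(scope="session")
def graph_factory():
    return make_network


@pytest.fixture(scope="session")
def bridged_cliques():
    """Two 8-cliques joined by a single bridge edge (0, 8)."""
    return clique_pair_network(8)


@pytest.fixture(scope="session")
def synthetic_two_domain():
    """Default two-domain synthetic chain (60+60 residues, 6-residue linker)."""
    return generate(SyntheticSpec(seed=1))


TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.400   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.200   0.900   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       0.500   0.800   1.200  1.00  0.00           C
ATOM      6  N   ALA A   2       3.000   0.500   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
TER       8      ALA A   2
END
"""


@pytest.fixture()
def two_residue_pdb(tmp_path):
    path = tmp_path / "two_res.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


def random_network(rng, max_n=12, p=None):
    """Seeded Erdos-Renyi-style network with 4..max_n vertices."""
    n = int(rng.integers(4, max_n + 1))
    p = float(rng.uniform(0.15, 0.7)) if p is None else p
    edges = {
        (i, j)
        for i, j in itertools.combinations(range(n), 2)
        if rng.uniform() < p
    }
    return make_network(n, edges)
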