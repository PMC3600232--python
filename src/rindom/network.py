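"""Build residue interaction networks from a structure model.

A residue interaction network (RIN) has one vertex per representable residue
and an undirected, unweighted edge between every residue pair whose distance
under the chosen vertex strategy is within the cutoff:

* ``CA`` / ``CENTROID`` — Euclidean distance between the single representative
  points (alpha carbon / side-chain centroid);
* ``ANYATOM`` — the minimum surface gap over all heavy-atom pairs, i.e. the
  center distance minus both van der Waals radii, floored at zero.  A cutoff
  of 0 therefore means "the atomic surfaces touch or overlap", which is why
  the anyatom cutoff grid starts at 0 A.

Distances are compared with ``<= cutoff`` (boundary inclusive) and sequence
neighbours get no special treatment: an (i, i+1) pair within the cutoff is an
edge like any other.  At a Ca cutoff below the ~3.8 A backbone spacing the
network is consequently (near-)edgeless.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    RadiusTable,
    ResidueKey,
    StructureModel,
    VDW_RADII,
    VertexStrategy,
    representative_points,
)

logger = logging.getLogger(__name__)

#: Cutoff grid for the CA and CENTROID strategies: 3-10 A in 0.5 A steps.
CA_CENT_CUTOFFS: tuple[float, ...] = tuple(3.0 + 0.5 * i for i in range(15))
#: Cutoff grid for the ANYATOM (surface gap) strategy: 0-6 A in 0.5 A steps.
ANYATOM_CUTOFFS: tuple[float, ...] = tuple(0.5 * i for i in range(13))

DEFAULT_CUTOFF_GRIDS: dict[VertexStrategy, tuple[float, ...]] = {
    VertexStrategy.CA: CA_CENT_CUTOFFS,
    VertexStrategy.CENTROID: CA_CENT_CUTOFFS,
    VertexStrategy.ANYATOM: ANYATOM_CUTOFFS,
}


class NetworkError(ValueError):
    """Problem constructing a residue network."""


class EmptyNetworkError(NetworkError):
    """No representable residues were available for the network."""


@dataclass(frozen=True)
class NetworkBuildConfig:
    """Vertex strategy plus distance cutoff (Angstrom)."""

    strategy: VertexStrategy
    cutoff: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", VertexStrategy(self.strategy))
        if not (math.isfinite(self.cutoff) and self.cutoff >= 0.0):
            raise NetworkError(f"cutoff must be finite and >= 0, got {self.cutoff}")


@dataclass
class ResidueNetwork:
    """Undirected residue network: vertex keys plus index-pair edges."""

    vertices: list[ResidueKey]
    edges: set[tuple[int, int]]
    config: NetworkBuildConfig | None = None
    structure_id: str = ""
    distances: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.vertices)
        for i, j in self.edges:
            if i == j:
                raise NetworkError(f"self-edge on vertex {i}")
            if not (0 <= i < j < n):
                raise NetworkError(f"edge ({i}, {j}) out of range or unordered")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        for nbrs in adj:
            nbrs.sort()
        return adj

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_vertices, self.n_vertices))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


# ---------------------------------------------------------------------------
# Distances


def pair_distance(
    points_a: list[tuple[np.ndarray, float]],
    points_b: list[tuple[np.ndarray, float]],
    strategy: VertexStrategy,
) -> float:
    """Distance between two residues' representative point sets.

    CA/CENTROID: Euclidean distance between the single points.  ANYATOM: the
    minimum over atom pairs of (center distance - radius_a - radius_b),
    floored at 0 (overlapping surfaces count as contact).
    """
    if not points_a or not points_b:
        raise NetworkError("representative point lists must be non-empty")
    strategy = VertexStrategy(strategy)
    if strategy in (VertexStrategy.CA, VertexStrategy.CENTROID):
        return float(np.linalg.norm(points_a[0][0] - points_b[0][0]))
    pa = np.array([p for p, _ in points_a])
    pb = np.array([p for p, _ in points_b])
    ra = np.array([r for _, r in points_a])
    rb = np.array([r for _, r in points_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    gap = d - ra[:, None] - rb[None, :]
    return float(max(gap.min(), 0.0))


# ---------------------------------------------------------------------------
# Construction


def build_network(
    model: StructureModel,
    config: NetworkBuildConfig,
    chain_ids: list[str] | None = None,
    radii: RadiusTable = VDW_RADII,
) -> ResidueNetwork:
    """Build the residue network of *model* under *config*.

    Vertices are all representable residues of the selected chains in
    chain-then-sequence (file) order; an edge joins residues i < j whenever
    their :func:`pair_distance` is <= the cutoff.  Residues that cannot be
    represented under the strategy are excluded and logged.
    """
    keys: list[ResidueKey] = []
    reps: list[list[tuple[np.ndarray, float]]] = []
    for res in model.residues(chain_ids):
        pts = representative_points(res, config.strategy, radii)
        if pts is None:
            logger.info(
                "%s: residue %s/%s%s not representable under %s; excluded",
                model.structure_id, res.chain_id, res.seq_num, res.icode,
                config.strategy.value,
            )
            continue
        keys.append(res.key)
        reps.append(pts)
    if not keys:
        raise EmptyNetworkError(
            f"{model.structure_id}: no representable residues for "
            f"{config.strategy.value}"
        )

    edges: set[tuple[int, int]] = set()
    distances: dict[tuple[int, int], float] = {}
    if config.strategy in (VertexStrategy.CA, VertexStrategy.CENTROID):
        coords = np.array([pts[0][0] for pts in reps])
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(config.cutoff):
            i, j = (i, j) if i < j else (j, i)
            edges.add((i, j))
            distances[(i, j)] = float(np.linalg.norm(coords[i] - coords[j]))
    else:
        atom_xyz = np.array([p for pts in reps for p, _ in pts])
        atom_rad = np.array([r for pts in reps for _, r in pts])
        atom_res = np.array(
            [vi for vi, pts in enumerate(reps) for _ in pts], dtype=int
        )
        # surface gap <= cutoff implies center distance <= cutoff + 2*rmax
        search_r = config.cutoff + 2.0 * float(atom_rad.max(initial=0.0))
        tree = cKDTree(atom_xyz)
        for a, b in tree.query_pairs(search_r):
            i, j = atom_res[a], atom_res[b]
            if i == j:
                continue
            gap = max(
                float(np.linalg.norm(atom_xyz[a] - atom_xyz[b]))
                - atom_rad[a] - atom_rad[b],
                0.0,
            )
            if gap <= config.cutoff:
                i, j = (int(i), int(j)) if i < j else (int(j), int(i))
                if (i, j) not in edges or gap < distances[(i, j)]:
                    edges.add((i, j))
                    distances[(i, j)] = gap

    return ResidueNetwork(
        vertices=keys,
        edges=edges,
        config=config,
        structure_id=model.structure_id,
        distances=distances,
    )


# ---------------------------------------------------------------------------
# Edge-list TSV interface

_EDGE_COLUMNS = [
    "structure_id",
    "chain_i", "resnum_i", "icode_i",
    "chain_j", "resnum_j", "icode_j",
    "distance",
]


def write_edges_tsv(network: ResidueNetwork, path: str | Path) -> None:
    """Write the edge list as TSV in deterministic vertex-index order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EDGE_COLUMNS)
        for i, j in sorted(network.edges):
            ci, ni, ii = network.vertices[i]
            cj, nj, ij = network.vertices[j]
            d = network.distances.get((i, j), float("nan"))
            writer.writerow(
                [network.structure_id, ci, ni, ii, cj, nj, ij, f"{d:.3f}"]
            )


def read_edges_tsv(path: str | Path) -> ResidueNetwork:
    """Read an edge-list TSV back into a :class:`ResidueNetwork`.

    Vertices are recovered from edge endpoints in order of first appearance;
    isolated vertices are not represented in this format.
    """
    vertices: list[ResidueKey] = []
    index: dict[ResidueKey, int] = {}
    edges: set[tuple[int, int]] = set()
    distances: dict[tuple[int, int], float] = {}
    structure_id = ""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            structure_id = row["structure_id"]
            ki = (row["chain_i"], int(row["resnum_i"]), row["icode_i"])
            kj = (row["chain_j"], int(row["resnum_j"]), row["icode_j"])
            for k in (ki, kj):
                if k not in index:
                    index[k] = len(vertices)
                    vertices.append(k)
            i, j = index[ki], index[kj]
            i, j = (i, j) if i < j else (j, i)
            edges.add((i, j))
            distances[(i, j)] = float(row["distance"])
    return ResidueNetwork(
        vertices=vertices,
        edges=edges,
        config=None,
        structure_id=structure_id,
        distances=distances,
    )
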