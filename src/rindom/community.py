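"""Community division of residue networks.

Two algorithms split a residue network into putative domains:

* **Edge-betweenness (divisive).**  The betweenness of an edge is the number
  of shortest paths between all vertex pairs that traverse it, with the count
  split equally among equal-length alternatives.  Edges that bridge densely
  connected groups carry most shortest paths, so repeatedly removing the
  single highest-betweenness edge (recomputing betweenness after every
  removal) peels the network apart along group boundaries.  The removal
  history with its component splits forms a divisive dendrogram.

* **Short random walks (agglomerative).**  A t-step random walk started
  inside a dense group tends to stay in it, so the t-step transition
  probability profiles of two vertices in the same group look alike.  The
  walk distance r between vertices (or communities) is the degree-weighted
  Euclidean distance between their t-step profiles; communities start as
  singletons and adjacent pairs are merged greedily, each step choosing the
  merge that minimally increases the total within-community squared distance
  (Ward-style criterion).  Probabilities are propagated exactly (matrix
  powers of the degree-normalised adjacency), never sampled, so the whole
  procedure is deterministic.

Both dendrograms can be cut at a requested community count K; in the domain
pipeline K is the number of annotated domains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .network import ResidueNetwork

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


class Method(str, Enum):
    """Community-division algorithm tag."""

    EDGE_BETWEENNESS = "EDGE_BETWEENNESS"
    RANDOM_WALK = "RANDOM_WALK"


#: Random-walk lengths swept in the evaluation harness.
DEFAULT_STEP_GRID: tuple[int, ...] = tuple(range(3, 11))


@dataclass(frozen=True)
class WalktrapConfig:
    """Random-walk length t used for the agglomerative division."""

    steps: int = 4

    def __post_init__(self) -> None:
        if not (isinstance(self.steps, int) and self.steps >= 1):
            raise ValueError(f"steps must be an integer >= 1, got {self.steps!r}")


@dataclass
class Partition:
    """Community id per vertex index; ids contiguous from 0."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")

    @property
    def n_communities(self) -> int:
        return 0 if self.labels.size == 0 else int(self.labels.max()) + 1

    def communities(self) -> list[list[int]]:
        groups: list[list[int]] = [[] for _ in range(self.n_communities)]
        for v, c in enumerate(self.labels):
            groups[c].append(v)
        return groups


def _normalize_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel community ids to be contiguous, ordered by first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


# ---------------------------------------------------------------------------
# Connected components (BFS; used by both algorithms)


def _components(n: int, adj: list[set[int]]) -> np.ndarray:
    labels = np.full(n, -1, dtype=int)
    nxt = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = nxt
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if labels[v] < 0:
                    labels[v] = nxt
                    stack.append(v)
        nxt += 1
    return labels


# ---------------------------------------------------------------------------
# Edge betweenness (Brandes-style, vectorised over sources)


def _edge_betweenness_arrays(adj_matrix: np.ndarray, edges: list[Edge]) -> dict[Edge, float]:
    """Exact edge betweenness on an unweighted graph.

    Level-synchronous BFS from every source at once: ``sigma[s, v]`` counts
    shortest s->v paths and ``dist[s, v]`` their length; the backward sweep
    accumulates the path-counting dependencies level by level.  Each unordered
    vertex pair is counted once (ordered-pair totals are halved).
    """
    n = adj_matrix.shape[0]
    if not edges:
        return {}
    a = adj_matrix.astype(float)

    dist = np.full((n, n), -1, dtype=int)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    np.fill_diagonal(dist, 0)
    frontier = np.eye(n, dtype=bool)
    level = 0
    while frontier.any():
        contrib = (sigma * frontier) @ a
        new = (contrib > 0) & (dist < 0)
        sigma[new] = contrib[new]
        dist[new] = level + 1
        frontier = new
        level += 1

    inv_sigma = np.zeros_like(sigma)
    nz = sigma > 0
    inv_sigma[nz] = 1.0 / sigma[nz]

    delta = np.zeros((n, n))
    for lvl in range(level, 0, -1):
        at = dist == lvl
        if not at.any():
            continue
        coef = np.where(at, (1.0 + delta) * inv_sigma, 0.0)
        back = coef @ a
        pred = dist == lvl - 1
        delta += np.where(pred, back * sigma, 0.0)

    scores: dict[Edge, float] = {}
    one_plus = 1.0 + delta
    for u, v in edges:
        m_uv = dist[:, v] == dist[:, u] + 1  # u precedes v
        m_vu = dist[:, u] == dist[:, v] + 1
        s = np.where(m_uv, sigma[:, u] * inv_sigma[:, v] * one_plus[:, v], 0.0).sum()
        s += np.where(m_vu, sigma[:, v] * inv_sigma[:, u] * one_plus[:, u], 0.0).sum()
        scores[(u, v)] = float(s) / 2.0
    return scores


def edge_betweenness(network: ResidueNetwork) -> dict[Edge, float]:
    """Betweenness score of every edge of *network*.

    The score of edge e is the number of shortest paths between unordered
    vertex pairs passing through e, shares split equally among equal-length
    shortest paths.  Disconnected networks are handled per component.
    """
    edges = sorted(network.edges)
    return _edge_betweenness_arrays(network.adjacency_matrix(), edges)


# ---------------------------------------------------------------------------
# Dendrogram


@dataclass
class Dendrogram:
    """Merge/removal history of a community-division run.

    For ``EDGE_BETWEENNESS`` the history is the ordered list of removed edges
    plus component snapshots taken whenever a removal split a component; for
    ``RANDOM_WALK`` it is the ordered list of community merges.  ``cut``
    reconstructs the partition at a requested community count.
    """

    n_vertices: int
    method: Method
    # EDGE_BETWEENNESS
    removals: list[Edge] = field(default_factory=list)
    snapshots: list[tuple[int, np.ndarray, int]] = field(default_factory=list)
    complete: bool = True
    # RANDOM_WALK: (community_a, community_b, merged_id)
    merges: list[tuple[int, int, int]] = field(default_factory=list)

    def cut(self, k: int) -> Partition:
        """Partition at community count *k*.

        Edge-betweenness: the connected components at the first point in the
        removal history with >= k components (the initial components if the
        graph already starts above k).  Random walk: the agglomerative state
        with exactly k communities when reachable, otherwise the closest
        reachable count above k (components never merge).
        """
        if not (1 <= k <= self.n_vertices):
            raise ValueError(
                f"k must be in [1, {self.n_vertices}], got {k}"
            )
        if self.method is Method.EDGE_BETWEENNESS:
            for _, labels, count in self.snapshots:
                if count >= k:
                    return Partition(_normalize_labels(labels))
            if not self.complete:
                raise ValueError(
                    f"dendrogram was truncated before reaching {k} communities"
                )
            # a complete run always ends with all singletons
            return Partition(np.arange(self.n_vertices))

        # RANDOM_WALK: replay merges until k communities remain
        parent: dict[int, int] = {}
        count = self.n_vertices
        for a, b, new in self.merges:
            if count <= k:
                break
            parent[a] = new
            parent[b] = new
            count -= 1
        raw = np.empty(self.n_vertices, dtype=int)
        for v in range(self.n_vertices):
            c = v
            while c in parent:
                c = parent[c]
            raw[v] = c
        return Partition(_normalize_labels(raw))


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> Partition:
    """Cut *dendrogram* at *k* communities (see :meth:`Dendrogram.cut`)."""
    return dendrogram.cut(k)


# ---------------------------------------------------------------------------
# Girvan-Newman divisive clustering


def girvan_newman(
    network: ResidueNetwork,
    stop_at_components: int | None = None,
) -> Dendrogram:
    """Divisive edge-betweenness clustering of *network*.

    Repeatedly recomputes edge betweenness on the current graph and removes
    the single maximum-scoring edge (ties broken by the lexicographically
    smallest vertex-index pair), recording a component snapshot at every
    split.  Runs until no edges remain, or — when *stop_at_components* is
    given — until the graph has at least that many components (the dendrogram
    is then marked incomplete and can only be cut at counts it reached).
    """
    n = network.n_vertices
    if n == 0:
        raise ValueError("cannot divide an empty network")
    adj: list[set[int]] = [set() for _ in range(n)]
    edges: set[Edge] = set(network.edges)
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)

    labels = _components(n, adj)
    n_comp = int(labels.max()) + 1
    removals: list[Edge] = []
    snapshots = [(0, labels.copy(), n_comp)]

    a = network.adjacency_matrix()
    while edges and (stop_at_components is None or n_comp < stop_at_components):
        scores = _edge_betweenness_arrays(a, sorted(edges))
        best: Edge | None = None
        best_score = -math.inf
        for e in sorted(edges):
            s = scores[e]
            if s > best_score:
                best, best_score = e, s
        assert best is not None
        u, v = best
        edges.discard(best)
        adj[u].discard(v)
        adj[v].discard(u)
        a[u, v] = a[v, u] = 0.0
        removals.append(best)

        # did removing (u, v) split their component?
        reached = {u}
        stack = [u]
        found = False
        while stack:
            x = stack.pop()
            if x == v:
                found = True
                break
            for y in adj[x]:
                if y not in reached:
                    reached.add(y)
                    stack.append(y)
        if not found:
            # v-side of the old component gets a fresh label
            side = {v}
            stack = [v]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in side:
                        side.add(y)
                        stack.append(y)
            labels[list(side)] = n_comp
            n_comp += 1
            snapshots.append((len(removals), labels.copy(), n_comp))

    return Dendrogram(
        n_vertices=n,
        method=Method.EDGE_BETWEENNESS,
        removals=removals,
        snapshots=snapshots,
        complete=not edges,
    )


# ---------------------------------------------------------------------------
# Walktrap agglomerative clustering


@dataclass
class WalkProfiles:
    """Exact t-step walk probability profiles of a network's vertices.

    ``profiles[i, k]`` is the probability that a t-step random walk started
    at vertex i ends at vertex k.  The walk distance between two vertices is
    the degree-weighted Euclidean distance between their profiles; vertices
    in different components (including isolated vertices) are at infinite
    distance and are never merged.
    """

    profiles: np.ndarray
    degrees: np.ndarray
    component: np.ndarray
    steps: int

    def distance(self, i: int, j: int) -> float:
        if self.component[i] != self.component[j]:
            return math.inf
        if self.degrees[i] == 0 or self.degrees[j] == 0:
            return math.inf if i != j else 0.0
        w = np.zeros_like(self.degrees, dtype=float)
        nz = self.degrees > 0
        w[nz] = 1.0 / self.degrees[nz]
        diff = self.profiles[i] - self.profiles[j]
        return float(np.sqrt(np.sum(diff * diff * w)))

    def distance_matrix(self) -> np.ndarray:
        n = self.profiles.shape[0]
        out = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                out[i, j] = self.distance(i, j) if i != j else 0.0
        return out


def walktrap_distances(
    network: ResidueNetwork, config: WalktrapConfig
) -> WalkProfiles:
    """Exact t-step probability profiles for the walktrap division."""
    n = network.n_vertices
    if n == 0:
        raise ValueError("cannot analyse an empty network")
    a = network.adjacency_matrix()
    deg = a.sum(axis=1)
    m = np.zeros_like(a)
    nz = deg > 0
    m[nz] = a[nz] / deg[nz, None]
    pt = np.linalg.matrix_power(m, config.steps)
    adj = [set(np.flatnonzero(a[i]).tolist()) for i in range(n)]
    comp = _components(n, adj)
    return WalkProfiles(profiles=pt, degrees=deg, component=comp, steps=config.steps)


def walktrap(network: ResidueNetwork, config: WalktrapConfig) -> Dendrogram:
    """Agglomerative random-walk clustering of *network*.

    Starts from singleton communities and repeatedly merges the adjacent pair
    whose merge minimally increases the total within-community squared walk
    distance (Ward-style increment ``|C1||C2|/(|C1|+|C2|) * r(C1,C2)^2 / n``,
    with community profiles the mean of their member profiles).  Ties are
    broken by the smallest community-id pair.  Isolated vertices form
    permanent singleton communities; merging never crosses components.
    """
    n = network.n_vertices
    prof = walktrap_distances(network, config)
    w = np.zeros(n)
    nz = prof.degrees > 0
    w[nz] = 1.0 / prof.degrees[nz]

    size: dict[int, int] = {v: 1 for v in range(n)}
    profile: dict[int, np.ndarray] = {v: prof.profiles[v] for v in range(n)}
    adjacency: dict[int, set[int]] = {v: set() for v in range(n)}
    for i, j in network.edges:
        adjacency[i].add(j)
        adjacency[j].add(i)

    def delta_sigma(a_id: int, b_id: int) -> float:
        diff = profile[a_id] - profile[b_id]
        r2 = float(np.sum(diff * diff * w))
        sa, sb = size[a_id], size[b_id]
        return (sa * sb) / (sa + sb) * r2 / n

    pairs: dict[tuple[int, int], float] = {}
    for i, j in sorted(network.edges):
        pairs[(i, j)] = delta_sigma(i, j)

    merges: list[tuple[int, int, int]] = []
    next_id = n
    while pairs:
        best_pair = min(pairs, key=lambda p: (pairs[p], p))
        a_id, b_id = best_pair
        new = next_id
        next_id += 1
        sa, sb = size[a_id], size[b_id]
        size[new] = sa + sb
        profile[new] = (sa * profile[a_id] + sb * profile[b_id]) / (sa + sb)
        adjacency[new] = (adjacency[a_id] | adjacency[b_id]) - {a_id, b_id}
        for x in adjacency[new]:
            adjacency[x].discard(a_id)
            adjacency[x].discard(b_id)
            adjacency[x].add(new)
        for old in (a_id, b_id):
            for x in list(adjacency[old]):
                adjacency[x].discard(old)
            stale = [p for p in pairs if old in p]
            for p in stale:
                del pairs[p]
            del size[old], profile[old], adjacency[old]
        # keep ids ordered inside the pair key for deterministic tie-breaks
        for x in sorted(adjacency[new]):
            key = (x, new) if x < new else (new, x)
            pairs[key] = delta_sigma(x, new)
        merges.append((a_id, b_id, new))

    return Dendrogram(n_vertices=n, method=Method.RANDOM_WALK, merges=merges)
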