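"""Markov Cluster algorithm on sparse stochastic matrices.

Alternates expansion (matrix squaring: random-walk flow), inflation
(elementwise power followed by column renormalization: flow contrast) and
pruning of negligible entries until the matrix stops changing. Clusters are
read off the converged matrix from its attractors (nodes retaining positive
return probability). The implementation is fully deterministic: node order
is the sorted node list and every tie-break is lexicographic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .similarity import ScoreGraph

logger = logging.getLogger(__name__)


@dataclass
class MclParams:
    inflation: float = 2.0
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-8
    self_loop: str = "max-edge"  # or "unit"

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.self_loop not in ("max-edge", "unit"):
            raise ValueError("self_loop must be 'max-edge' or 'unit'")


@dataclass
class Clustering:
    """A partition of the node set into clusters."""

    clusters: list[frozenset[str]] = field(default_factory=list)

    @property
    def singleton_count(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)

    def membership(self) -> dict[str, int]:
        return {node: i for i, cluster in enumerate(self.clusters)
                for node in cluster}

    def sort(self) -> None:
        self.clusters.sort(key=lambda c: (-len(c), min(c)))


def _column_normalize(matrix: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(matrix.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    inv = sp.diags(1.0 / sums)
    return (matrix @ inv).tocsc()


def _prune(matrix: sp.csc_matrix, threshold: float) -> sp.csc_matrix:
    if threshold <= 0:
        return matrix
    matrix = matrix.copy()
    matrix.data[matrix.data < threshold] = 0.0
    matrix.eliminate_zeros()
    return matrix


def _build_matrix(score_graph: ScoreGraph, params: MclParams
                  ) -> tuple[sp.csc_matrix, list[str]]:
    nodes = score_graph.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    max_incident = np.zeros(n)
    for a, b, data in score_graph.graph.edges(data=True):
        w = float(data["weight"])
        if w <= 0:
            continue
        ia, ib = idx[a], idx[b]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
        max_incident[ia] = max(max_incident[ia], w)
        max_incident[ib] = max(max_incident[ib], w)
    if params.self_loop == "unit":
        loops = np.ones(n)
    else:
        loops = np.where(max_incident > 0, max_incident, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loops)
    matrix = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return _column_normalize(matrix), nodes


def mcl(score_graph: ScoreGraph, params: MclParams | None = None) -> Clustering:
    """Run MCL on a ScoreGraph and return the partition it converges to."""
    params = params or MclParams()
    if score_graph.graph.number_of_nodes() == 0:
        return Clustering(clusters=[])
    matrix, nodes = _build_matrix(score_graph, params)
    converged = False
    for _ in range(params.max_iterations):
        previous = matrix
        matrix = matrix @ matrix  # expansion
        matrix.data **= params.inflation  # inflation
        matrix = _column_normalize(matrix)
        matrix = _column_normalize(_prune(matrix, params.prune_threshold))
        if _max_change(matrix, previous) < params.convergence_tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; "
                       "extracting clusters from the final matrix",
                       params.max_iterations)
    return _extract_clusters(matrix.tocsr(), nodes)


def _max_change(a: sp.csc_matrix, b: sp.csc_matrix) -> float:
    diff = (a - b).tocoo()
    if diff.nnz == 0:
        return 0.0
    return float(np.max(np.abs(diff.data)))


def _extract_clusters(matrix: sp.csr_matrix, nodes: list[str]) -> Clustering:
    """Read clusters from a converged MCL matrix.

    Attractors are nodes with positive diagonal mass. Attractors exchanging
    mass form attractor systems (the cluster cores); every other node joins
    the system receiving the largest share of its column mass, ties broken
    toward the lexicographically smallest system. Nodes whose column carries
    no attractor mass (a pruning artefact) follow their strongest outflow.
    """
    n = len(nodes)
    diag = matrix.diagonal()
    attractors = np.flatnonzero(diag > 0)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    attractor_set = set(attractors.tolist())
    csc = matrix.tocsc()
    # attractor systems: attractors connected by flow in either direction
    for j in attractor_set:
        col = csc.getcol(j)
        for i in col.nonzero()[0]:
            if i in attractor_set and i != j:
                union(int(i), int(j))

    # assign non-attractors to the system receiving most of their column mass
    for j in range(n):
        if j in attractor_set:
            continue
        col = csc.getcol(j)
        rows = col.nonzero()[0]
        if len(rows) == 0:
            continue  # isolated: stays its own singleton
        mass: dict[int, float] = {}
        fallback_row, fallback_val = None, -1.0
        for i, v in zip(rows, col.data):
            if i in attractor_set:
                root = find(int(i))
                mass[root] = mass.get(root, 0.0) + float(v)
            if float(v) > fallback_val:
                fallback_row, fallback_val = int(i), float(v)
        if mass:
            best = max(mass.items(),
                       key=lambda kv: (kv[1], -_rank(nodes, kv[0])))
            union(j, best[0])
        elif fallback_row is not None and fallback_row != j:
            union(j, fallback_row)

    groups: dict[int, set[str]] = {}
    for i, node in enumerate(nodes):
        groups.setdefault(find(i), set()).add(node)
    clustering = Clustering(clusters=[frozenset(g) for g in groups.values()])
    clustering.sort()
    return clustering


def _rank(nodes: list[str], idx: int) -> int:
    # nodes is sorted, so index order == lexicographic order
    return idx


def cluster_connected_components(score_graph: ScoreGraph) -> Clustering:
    """Weakly connected components: the coarse partition MCL always refines."""
    import networkx as nx

    comps = [frozenset(c) for c in nx.connected_components(score_graph.graph)]
    clustering = Clustering(clusters=comps)
    clustering.sort()
    return clustering


def write_clusters(clustering: Clustering, path) -> None:
    """mcl-native output: one cluster per line, tab-separated ids."""
    with open(path, "w") as fh:
        for cluster in clustering.clusters:
            fh.write("\t".join(sorted(cluster)) + "\n")
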