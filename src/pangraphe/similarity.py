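"""All-vs-all similarity graph with normalized bit-score weights.

Representatives are scored pairwise by exact local alignment; bit scores are
normalized by the larger self-score so edge weights fall in (0, 1], the form
MCL expects for orthology graphs. Cluster members then inherit their
representative's edges so the graph covers every locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from ._align import KmerIndex, align_pair, bit_score, self_score
from .annotation_io import Locus
from .config import PipelineConfig
from .dereplication import RepCluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityHit:
    """One directed alignment hit between two loci."""

    query: str
    subject: str
    bit_score: float
    pct_identity: float
    query_coverage: float
    subject_coverage: float


@dataclass
class ScoreGraph:
    """Symmetric weighted graph over loci.

    Edge attributes: ``weight`` (normalized bit score in (0, 1]),
    ``identity`` (percent over aligned columns), ``coverage`` (min of the two
    directions' query coverages). Self-edges are implied with weight 1 and
    not stored.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, nodes) -> "ScoreGraph":
        return ScoreGraph(self.graph.subgraph(nodes).copy())

    def to_abc(self, path) -> None:
        """Dump as the 3-column ABC edge list mcl reads natively."""
        with open(path, "w") as fh:
            for a, b, data in sorted(self.graph.edges(data=True)):
                fh.write(f"{a}\t{b}\t{data['weight']:.6g}\n")

    @classmethod
    def from_abc(cls, path) -> "ScoreGraph":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 3:
                    g.add_edge(parts[0], parts[1], weight=float(parts[2]),
                               identity=100.0, coverage=1.0)
        return cls(g)


def all_vs_all(reps: list[Locus], config: PipelineConfig,
               min_shared_kmers: int = 2) -> list[SimilarityHit]:
    """Score every representative pair by exact local alignment.

    Self-hits are always included (they anchor normalization). Cross pairs
    are prescreened by shared 4-mers; pairs passing the screen are aligned
    in both directions implicitly (one alignment yields both coverages), and
    zero-score pairs are dropped.
    """
    if not reps:
        raise ValueError("no representatives to search")
    space = config.sequence_space
    seqs = {r.locus_id: r.analysis_seq(space) for r in reps}
    hits: list[SimilarityHit] = []
    for locus_id, seq in sorted(seqs.items()):
        if not seq or _all_ambiguous(seq, space):
            logger.warning("sequence %s is empty/ambiguous; node isolated",
                           locus_id)
            continue
        raw = self_score(seq, space)
        hits.append(SimilarityHit(
            query=locus_id, subject=locus_id,
            bit_score=bit_score(raw, space), pct_identity=100.0,
            query_coverage=1.0, subject_coverage=1.0))

    index = KmerIndex(k=4, min_shared=min_shared_kmers)
    for locus_id in sorted(seqs):
        index.add(locus_id, seqs[locus_id])
    for a, b in sorted(index.candidate_pairs()):
        stats = align_pair(seqs[a], seqs[b], space=space, mode="local")
        if stats is None or stats.bit_score <= 0:
            continue
        hits.append(SimilarityHit(
            query=a, subject=b, bit_score=stats.bit_score,
            pct_identity=stats.pct_identity,
            query_coverage=stats.query_coverage,
            subject_coverage=stats.subject_coverage))
        hits.append(SimilarityHit(
            query=b, subject=a, bit_score=stats.bit_score,
            pct_identity=stats.pct_identity,
            query_coverage=stats.subject_coverage,
            subject_coverage=stats.query_coverage))
    return hits


def _all_ambiguous(seq: str, space: str) -> bool:
    if space == "aa":
        return set(seq) <= {"X"}
    return set(seq) <= {"N"}


def normalize_and_expand(hits: list[SimilarityHit],
                         clusters: list[RepCluster],
                         config: PipelineConfig) -> ScoreGraph:
    """Normalize bit scores and expand representative edges to all members.

    weight(a, b) = bit(a, b) / max(bit(a, a), bit(b, b)), symmetrized by the
    larger direction and capped at 1. Hits whose query coverage falls below
    ``config.hsp_coverage`` are discarded before symmetrization. Members of
    one dereplication cluster are joined by weight-1 edges carrying the
    cluster's join identity.
    """
    self_bits: dict[str, float] = {}
    for h in hits:
        if h.query == h.subject:
            self_bits[h.query] = h.bit_score

    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.query == h.subject:
            continue
        if h.query_coverage < config.hsp_coverage:
            continue
        key = (min(h.query, h.subject), max(h.query, h.subject))
        prev = best.get(key)
        if prev is None or h.bit_score > prev.bit_score:
            best[key] = h

    graph = nx.Graph()
    rep_of: dict[str, str] = {}
    for cluster in clusters:
        for member in cluster.member_ids:
            rep_of[member] = cluster.rep_id
        for member in sorted(cluster.member_ids):
            graph.add_node(member)
    reps_seen = {h.query for h in hits if h.query == h.subject}
    for cluster in clusters:
        if cluster.rep_id not in reps_seen:
            raise RuntimeError(
                f"missing self-hit for representative {cluster.rep_id}; "
                "normalization undefined")

    # representative-level normalized edges
    rep_edges: dict[tuple[str, str], tuple[float, float, float]] = {}
    for (a, b), h in best.items():
        denom = max(self_bits.get(a, 0.0), self_bits.get(b, 0.0))
        if denom <= 0:
            continue
        weight = min(1.0, h.bit_score / denom)
        coverage = min(h.query_coverage, h.subject_coverage)
        rep_edges[(a, b)] = (weight, h.pct_identity, coverage)

    members_of = {c.rep_id: sorted(c.member_ids) for c in clusters}
    cluster_identity = {c.rep_id: c.identity_level for c in clusters}

    # within-cluster edges: members are near-identical by construction
    for rep, members in sorted(members_of.items()):
        ident = cluster_identity[rep]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                graph.add_edge(a, b, weight=1.0, identity=ident, coverage=1.0)

    # expand representative edges to all member pairs across clusters
    for (ra, rb), (weight, ident, cov) in sorted(rep_edges.items()):
        for a in members_of.get(ra, (ra,)):
            for b in members_of.get(rb, (rb,)):
                if a == b:
                    continue
                prev = graph.get_edge_data(a, b)
                if prev is None or weight > prev["weight"]:
                    graph.add_edge(a, b, weight=weight, identity=ident,
                                   coverage=cov)
    logger.info("score graph: %d nodes, %d edges",
                graph.number_of_nodes(), graph.number_of_edges())
    return ScoreGraph(graph)


def filter_by_identity(score_graph: ScoreGraph, threshold: float) -> ScoreGraph:
    """Keep edges with identity >= threshold; nodes are preserved.

    The boundary is inclusive: an edge at exactly the threshold survives.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    g = nx.Graph()
    g.add_nodes_from(score_graph.graph.nodes)
    for a, b, data in score_graph.graph.edges(data=True):
        if data["identity"] >= threshold:
            g.add_edge(a, b, **data)
    return ScoreGraph(g)
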