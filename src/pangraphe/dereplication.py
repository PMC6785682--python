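"""Greedy incremental identity clustering to shrink the search set.

Mirrors CD-HIT's behaviour at the contract level: sequences are sorted by
decreasing length and each joins the first cluster whose representative it
matches at the required identity over at least 80% of the shorter sequence
(containment), otherwise it founds a new cluster. A cascade of decreasing
identity levels (100, 98, 95 by default) composes cluster memberships
transitively, and the longest member represents each final cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from ._align import KmerIndex, align_pair
from .annotation_io import Locus
from .config import PipelineConfig

logger = logging.getLogger(__name__)

#: minimum fraction of the shorter sequence that must be aligned for a
#: containment match during greedy clustering
CONTAINMENT_COVERAGE = 0.80


@dataclass
class RepCluster:
    """A dereplication cluster: representative plus absorbed members."""

    rep_id: str
    member_ids: set[str] = field(default_factory=set)
    identity_level: float = 100.0  # minimum level at which any member joined

    def __post_init__(self) -> None:
        self.member_ids = set(self.member_ids) | {self.rep_id}


#: slack (identity points) granted to the edit-distance prescreen before a
#: candidate is rejected without exact alignment
_PRESCREEN_MARGIN = 6.0


def _containment_match(short_seq: str, long_seq: str, identity: float,
                       space: str) -> bool:
    # cheap prescreen: best-infix edit distance bounds attainable identity;
    # clear rejections (the common case) never reach the exact aligner
    result = edlib.align(short_seq, long_seq, mode="HW", task="distance")
    dist = result["editDistance"]
    if dist >= 0:
        identity_bound = 100.0 * (len(short_seq) - dist) / len(short_seq)
        if identity_bound < identity - _PRESCREEN_MARGIN:
            return False
    stats = align_pair(short_seq, long_seq, space=space, mode="local")
    if stats is None:
        return False
    return (stats.pct_identity >= identity
            and stats.query_coverage >= CONTAINMENT_COVERAGE)


def greedy_cluster(loci: list[Locus], identity: float,
                   config: PipelineConfig) -> list[RepCluster]:
    """One pass of greedy length-sorted clustering at a single identity.

    The output clusters partition the input. A k-mer prescreen restricts
    exact alignment to representatives sharing at least two 4-mers with the
    candidate sequence; at the identities used here (>= 95%) a true match
    always shares far more.
    """
    if not (0 < identity <= 100):
        raise ValueError("identity must lie in (0, 100]")
    space = config.sequence_space
    order = sorted(
        loci,
        key=lambda l: (-len(l.analysis_seq(space)), l.locus_id))
    index = KmerIndex(k=4, min_shared=2)
    clusters: dict[str, RepCluster] = {}
    rep_seqs: dict[str, str] = {}
    for locus in order:
        seq = locus.analysis_seq(space)
        placed = False
        for rep_id in index.candidates(seq):
            # rep is at least as long as locus, so locus is the shorter side
            if _containment_match(seq, rep_seqs[rep_id], identity, space):
                clusters[rep_id].member_ids.add(locus.locus_id)
                clusters[rep_id].identity_level = min(
                    clusters[rep_id].identity_level, identity)
                placed = True
                break
        if not placed:
            # founders start at 100; the level drops only when a member joins
            clusters[locus.locus_id] = RepCluster(rep_id=locus.locus_id)
            rep_seqs[locus.locus_id] = seq
            index.add(locus.locus_id, seq)
    return list(clusters.values())


def iterative_dereplicate(loci: list[Locus],
                          config: PipelineConfig) -> list[RepCluster]:
    """Cascade greedy clustering at decreasing identities, composing members.

    Levels below ``max(base_threshold, 95)`` are skipped so dereplication
    never collapses sequences the family-level clustering must still see
    apart.
    """
    floor = max(config.base_threshold, 95)
    levels = [lvl for lvl in config.derep_cascade if lvl >= floor]
    by_id = {l.locus_id: l for l in loci}
    current: dict[str, RepCluster] = {
        l.locus_id: RepCluster(rep_id=l.locus_id) for l in loci}
    current_loci = list(loci)
    for level in sorted(set(levels), reverse=True):
        passes = greedy_cluster(current_loci, level, config)
        merged: dict[str, RepCluster] = {}
        for cluster in passes:
            members: set[str] = set()
            ident = cluster.identity_level
            for rep in cluster.member_ids:
                members |= current[rep].member_ids
                ident = min(ident, current[rep].identity_level)
            merged[cluster.rep_id] = RepCluster(
                rep_id=cluster.rep_id, member_ids=members,
                identity_level=ident)
        current = merged
        current_loci = [by_id[rep] for rep in sorted(current)]
    clusters = sorted(current.values(), key=lambda c: c.rep_id)
    n_members = sum(len(c.member_ids) for c in clusters)
    logger.info("dereplication: %d loci -> %d representatives",
                n_members, len(clusters))
    return clusters
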