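"""Paralog classification: duplications, gene-fission fragments, and
splitting of over-clustered families.

A family holding more than one locus in some genome either contains real
duplications, fragments of a single disrupted gene (fission), or two genes
that should never have co-clustered. Copies are compared by local alignment:
duplicates overlap each other over most of their length, while fission
fragments cover disjoint parts of a full-length reference. Fragment
combinations are scored against the longest locus of the family and the most
parsimonious covering combination is reported as one fission locus. After
fission merging, families that are still multi-copy are split on the first
ladder threshold whose allele clusters are single-copy in every genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from ._align import align_pair
from .annotation_io import Locus
from .config import PipelineConfig
from .hierarchy import AlleleCluster, GeneFamily, Hierarchy

logger = logging.getLogger(__name__)

DUPLICATION = "duplication"
FISSION_FRAGMENT = "fission_fragment"


@dataclass
class FissionGroup:
    """Fragments of one disrupted gene in one genome, ordered along the
    full-length reference locus they jointly cover."""

    group_id: str
    genome_id: str
    fragment_loci: list[str]
    reference_locus: str
    reference_coverage: float


@dataclass
class ParalogAnnotation:
    locus_id: str
    classification: str  # duplication | fission_fragment
    dup_ordinal: int | None = None
    group_id: str | None = None


def detect_paralog_families(hierarchy: Hierarchy) -> list[str]:
    """Families holding >1 locus in at least one genome."""
    return [fam.family_id for fam in hierarchy.families
            if fam.per_genome_count and max(fam.per_genome_count.values()) > 1]


def _length_clusters(loci: list[Locus], space: str,
                     identity: float) -> list[list[Locus]]:
    """Greedy 98%-similarity grouping (longest first, CD-HIT style).

    A locus joins a cluster only when its length is within `identity` of the
    cluster's longest member AND it matches that member at >= `identity`
    sequence identity over most of itself — so members of one cluster are
    near-identical copies, and one overlap test per cluster pair suffices.
    """
    order = sorted(loci, key=lambda l: (-len(l.analysis_seq(space)), l.locus_id))
    clusters: list[list[Locus]] = []
    for locus in order:
        seq = locus.analysis_seq(space)
        for cluster in clusters:
            rep_seq = cluster[0].analysis_seq(space)
            if len(seq) < identity * len(rep_seq):
                continue
            stats = align_pair(seq, rep_seq, space=space, mode="local")
            if (stats is not None
                    and stats.pct_identity >= 100.0 * identity
                    and stats.query_coverage >= 0.9):
                cluster.append(locus)
                break
        else:
            clusters.append([locus])
    return clusters


def _significant_overlap(seq_a: str, seq_b: str, space: str,
                         min_fraction: float) -> bool:
    stats = align_pair(seq_a, seq_b, space=space, mode="local")
    if stats is None:
        return False
    shorter_cov = (stats.query_coverage if len(seq_a) <= len(seq_b)
                   else stats.subject_coverage)
    return shorter_cov >= min_fraction


def _reference_interval(fragment: str, reference: str,
                        space: str) -> tuple[int, int] | None:
    stats = align_pair(fragment, reference, space=space, mode="local")
    if stats is None:
        return None
    return stats.subject_span


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cursor = 0, -1
    for start, end in sorted(intervals):
        start = max(start, cursor)
        if end > start:
            total += end - start
            cursor = end
        cursor = max(cursor, end)
    return total


def _combination_valid(intervals: list[tuple[int, int]],
                       tolerance: float) -> bool:
    for (a0, a1), (b0, b1) in combinations(intervals, 2):
        overlap = min(a1, b1) - max(a0, b0)
        shorter = min(a1 - a0, b1 - b0)
        if shorter <= 0 or overlap > tolerance * shorter:
            return False
    return True


def _best_combination(fragments: list[str],
                      intervals: dict[str, tuple[int, int]],
                      tolerance: float,
                      max_exhaustive: int = 4) -> list[str] | None:
    """Fragment combination (size >= 2) maximizing union coverage of the
    reference, subject to the mutual-overlap tolerance.

    Exhaustive over subsets when few fragments; greedy max-coverage-gain
    extension beyond that. Ties prefer fewer fragments, then lexicographic
    fragment ids.
    """
    usable = sorted(f for f in fragments if f in intervals)
    if len(usable) < 2:
        return None
    best: tuple[int, int, list[str]] | None = None  # (coverage, -size, ids)
    if len(usable) <= max_exhaustive:
        for size in range(2, len(usable) + 1):
            for combo in combinations(usable, size):
                ivals = [intervals[f] for f in combo]
                if not _combination_valid(ivals, tolerance):
                    continue
                cov = _union_length(ivals)
                cand = (cov, -size, list(combo))
                if best is None or (cand[0], cand[1], cand[2]) > best:
                    best = cand
        return best[2] if best else None
    # greedy: start from the longest-interval fragment, add best gain
    chosen: list[str] = []
    remaining = list(usable)
    while remaining:
        gains = []
        for f in remaining:
            trial = chosen + [f]
            ivals = [intervals[x] for x in trial]
            if not _combination_valid(ivals, tolerance):
                continue
            gains.append((_union_length(ivals), f))
        if not gains:
            break
        gains.sort(key=lambda g: (-g[0], g[1]))
        gain_cov, pick = gains[0]
        if chosen and gain_cov <= _union_length(
                [intervals[x] for x in chosen]):
            break
        chosen.append(pick)
        remaining.remove(pick)
    return sorted(chosen) if len(chosen) >= 2 else None


def classify_paralogs(family: GeneFamily, loci_by_id: dict[str, Locus],
                      config: PipelineConfig
                      ) -> tuple[list[ParalogAnnotation], list[FissionGroup]]:
    """Classify every extra within-genome copy of a family.

    Copies are first grouped into length clusters; one representative per
    length cluster is aligned all-vs-all so overlap is tested once per
    length class. Per genome, copies lacking significant overlap with some
    co-genome copy are candidate fission fragments and the most parsimonious
    combination covering the family's longest locus becomes a FissionGroup;
    the search repeats until no further group is found, and the remaining
    extra copies are duplications, numbered in genomic order.
    """
    space = config.sequence_space
    members = sorted(family.member_loci)
    loci = [loci_by_id[m] for m in members]
    if len(loci) < 2:
        return [], []
    by_genome: dict[str, list[Locus]] = {}
    for locus in loci:
        by_genome.setdefault(locus.genome_id, []).append(locus)

    length_clusters = _length_clusters(
        loci, space, config.length_cluster_identity)
    rep_of = {}
    rep_seq = {}
    for cluster in length_clusters:
        rep = cluster[0]
        rep_seq[rep.locus_id] = rep.analysis_seq(space)
        for locus in cluster:
            rep_of[locus.locus_id] = rep.locus_id

    overlap_cache: dict[tuple[str, str], bool] = {}

    def overlaps(a: Locus, b: Locus) -> bool:
        ra, rb = rep_of[a.locus_id], rep_of[b.locus_id]
        if ra == rb:
            return True  # same length class: near-identical lengths
        key = (min(ra, rb), max(ra, rb))
        if key not in overlap_cache:
            overlap_cache[key] = _significant_overlap(
                rep_seq[key[0]], rep_seq[key[1]], space,
                config.overlap_significant)
        return overlap_cache[key]

    reference = max(loci, key=lambda l: (len(l.analysis_seq(space)), l.locus_id))
    ref_seq = reference.analysis_seq(space)

    annotations: list[ParalogAnnotation] = []
    groups: list[FissionGroup] = []
    for genome_id in sorted(by_genome):
        copies = sorted(by_genome[genome_id],
                        key=lambda l: (l.contig_id, l.start, l.locus_id))
        if len(copies) < 2:
            continue
        unclassified = list(copies)
        group_no = 0
        while len(unclassified) > 1:
            fragments = [
                c for c in unclassified
                if any(not overlaps(c, other) for other in unclassified
                       if other is not c)]
            intervals: dict[str, tuple[int, int]] = {}
            for frag in fragments:
                ival = _reference_interval(
                    frag.analysis_seq(space), ref_seq, space)
                if ival is not None:
                    intervals[frag.locus_id] = ival
            combo = _best_combination(
                [f.locus_id for f in fragments], intervals,
                config.fragment_overlap_tolerance)
            if combo is None:
                break
            group_no += 1
            ordered = sorted(combo, key=lambda f: intervals[f])
            coverage = _union_length([intervals[f] for f in combo]) / len(ref_seq)
            group = FissionGroup(
                group_id=f"{family.family_id}_{genome_id}_fission{group_no}",
                genome_id=genome_id, fragment_loci=ordered,
                reference_locus=reference.locus_id,
                reference_coverage=coverage)
            groups.append(group)
            for frag_id in ordered:
                annotations.append(ParalogAnnotation(
                    locus_id=frag_id, classification=FISSION_FRAGMENT,
                    group_id=group.group_id))
            unclassified = [c for c in unclassified if c.locus_id not in combo]
        # remaining extra copies are duplications; the first copy in genomic
        # order is the canonical locus and carries no annotation
        if len(unclassified) > 1:
            for ordinal, locus in enumerate(unclassified, start=1):
                if ordinal == 1:
                    continue
                annotations.append(ParalogAnnotation(
                    locus_id=locus.locus_id, classification=DUPLICATION,
                    dup_ordinal=ordinal))
    return annotations, groups


def merge_fissions(hierarchy: Hierarchy,
                   groups: list[FissionGroup]) -> Hierarchy:
    """Recompute per-genome copy counts with each fission group as one locus."""
    groups_by_family: dict[str, list[FissionGroup]] = {}
    family_of = hierarchy.family_of()
    for group in groups:
        fam_id = family_of.get(group.fragment_loci[0])
        if fam_id is not None:
            groups_by_family.setdefault(fam_id, []).append(group)
    for fam in hierarchy.families:
        for group in groups_by_family.get(fam.family_id, []):
            n_in_family = sum(1 for f in group.fragment_loci
                              if f in fam.member_loci)
            if n_in_family > 1:
                fam.per_genome_count[group.genome_id] -= n_in_family - 1
    return hierarchy


def _units(family: GeneFamily, groups: list[FissionGroup]
           ) -> tuple[list[tuple[str, frozenset[str], str]], set[str]]:
    """Merged units of a family: fission groups plus singleton loci."""
    grouped: set[str] = set()
    units: list[tuple[str, frozenset[str], str]] = []
    for group in groups:
        frags = frozenset(f for f in group.fragment_loci
                          if f in family.member_loci)
        if len(frags) > 1:
            units.append((min(frags), frags, group.genome_id))
            grouped |= frags
    return units, grouped


def split_family(family: GeneFamily, hierarchy: Hierarchy,
                 groups: list[FissionGroup] = ()
                 ) -> list[GeneFamily]:
    """Split an over-clustered family on single-copy allele clusters.

    Scans ladder thresholds from the bottom; the first threshold whose
    allele clusters each hold at most one merged locus per genome (and there
    is more than one cluster) defines the children, named ``g0001_1`` etc. in
    descending genome count. A family with real duplications at every
    threshold is returned unchanged.
    """
    fam_groups = [g for g in groups
                  if any(f in family.member_loci for f in g.fragment_loci)]
    fission_units, grouped = _units(family, fam_groups)
    genome_of = hierarchy.genome_of
    units = list(fission_units)
    for locus in sorted(family.member_loci - grouped):
        units.append((locus, frozenset((locus,)), genome_of[locus]))
    per_genome: dict[str, int] = {}
    for _, _, genome in units:
        per_genome[genome] = per_genome.get(genome, 0) + 1
    if not per_genome or max(per_genome.values()) <= 1:
        return [family]

    alleles = hierarchy.alleles.get(family.family_id, [])
    by_threshold: dict[int, list[AlleleCluster]] = {}
    for allele in alleles:
        by_threshold.setdefault(allele.threshold, []).append(allele)

    for t in sorted(by_threshold):
        if t == family.base_threshold:
            continue
        clusters = sorted(by_threshold[t],
                          key=lambda a: (min(a.member_loci)))
        if len(clusters) < 2:
            continue
        assignment: dict[str, int] = {}  # unit_id -> cluster index
        counts: dict[tuple[int, str], int] = {}
        ok = True
        for unit_id, unit_loci, genome in units:
            overlap_sizes = [
                (len(unit_loci & c.member_loci), -k)
                for k, c in enumerate(clusters)]
            size, neg_k = max(overlap_sizes)
            if size == 0:
                ok = False
                break
            k = -neg_k
            assignment[unit_id] = k
            counts[(k, genome)] = counts.get((k, genome), 0) + 1
            if counts[(k, genome)] > 1:
                ok = False
                break
        if not ok:
            continue
        # qualifying threshold found: build children from unit assignment
        child_members: dict[int, set[str]] = {}
        for unit_id, unit_loci, _ in units:
            child_members.setdefault(assignment[unit_id], set()).update(unit_loci)
        children = []
        ordered = sorted(
            child_members.values(),
            key=lambda m: (-len({genome_of[x] for x in m}), -len(m), min(m)))
        for i, members in enumerate(ordered, start=1):
            counts_g: dict[str, int] = {}
            for locus in members:
                g = genome_of[locus]
                counts_g[g] = counts_g.get(g, 0) + 1
            child = GeneFamily(
                family_id=f"{family.family_id}_{i}",
                base_threshold=family.base_threshold,
                member_loci=frozenset(members),
                genomes=frozenset(counts_g),
                per_genome_count=counts_g,
                family_threshold=_containment_threshold(
                    frozenset(members), alleles, family))
            children.append(child)
        logger.info("family %s split into %d children at threshold %d",
                    family.family_id, len(children), t)
        return children
    return [family]


def _containment_threshold(members: frozenset[str],
                           alleles: list[AlleleCluster],
                           family: GeneFamily) -> int:
    """Highest ladder threshold at which `members` sit inside one cluster."""
    best = family.base_threshold
    for allele in alleles:
        if members <= allele.member_loci and allele.threshold > best:
            best = allele.threshold
    return best


def apply_splits(hierarchy: Hierarchy,
                 groups: list[FissionGroup]) -> Hierarchy:
    """Run split_family over every still-multi-copy family, rebuilding the
    hierarchy's family list and allele map (child alleles are the parent
    alleles wholly contained in the child)."""
    new_families: list[GeneFamily] = []
    new_alleles: dict[str, list[AlleleCluster]] = {}
    for fam in hierarchy.families:
        children = split_family(fam, hierarchy, groups)
        if len(children) == 1 and children[0] is fam:
            new_families.append(fam)
            new_alleles[fam.family_id] = hierarchy.alleles.get(
                fam.family_id, [])
            continue
        parent_alleles = hierarchy.alleles.get(fam.family_id, [])
        for child in children:
            new_families.append(child)
            inherited = [a for a in parent_alleles
                         if a.member_loci <= child.member_loci]
            if not any(a.member_loci == child.member_loci for a in inherited):
                inherited.insert(0, AlleleCluster(
                    allele_id=f"{child.family_id}_t{child.base_threshold}_1",
                    family_id=child.family_id,
                    threshold=child.base_threshold,
                    member_loci=child.member_loci, is_unique=True))
            new_alleles[child.family_id] = inherited
    hierarchy.families = new_families
    hierarchy.alleles = new_alleles
    return hierarchy


def paralog_report_rows(annotations: list[ParalogAnnotation],
                        groups: list[FissionGroup],
                        family_of: dict[str, str]) -> list[tuple]:
    coverage = {g.group_id: g.reference_coverage for g in groups}
    rows = []
    for ann in sorted(annotations, key=lambda a: a.locus_id):
        rows.append((
            ann.locus_id, family_of.get(ann.locus_id, ""),
            ann.classification,
            ann.dup_ordinal if ann.dup_ordinal is not None else "",
            ann.group_id or "",
            f"{coverage[ann.group_id]:.3f}" if ann.group_id else ""))
    return rows
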