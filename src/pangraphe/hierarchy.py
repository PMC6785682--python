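"""Nested gene-family / unique-allele hierarchy across the identity ladder.

Families are MCL clusters of the similarity graph filtered at the lowest
(most relaxed) identity threshold. Within each family, clustering is
repeated on the family's own subgraph at every higher ladder threshold;
sub-clusters whose locus set has not been seen at any lower threshold are
"unique alleles". The highest threshold at which a locus still sits in a
unique allele measures its divergence from the rest of the family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation_io import Locus
from .config import PipelineConfig
from .mcl import MclParams, mcl
from .similarity import ScoreGraph, filter_by_identity

logger = logging.getLogger(__name__)


@dataclass
class GeneFamily:
    """A cluster of loci at the base identity threshold."""

    family_id: str
    base_threshold: int
    member_loci: frozenset[str]
    genomes: frozenset[str]
    per_genome_count: dict[str, int]
    family_threshold: int  # highest ladder value at which all members co-cluster

    @property
    def genome_count(self) -> int:
        return len(self.genomes)


@dataclass
class AlleleCluster:
    """An MCL sub-cluster of a family at one ladder threshold."""

    allele_id: str
    family_id: str
    threshold: int
    member_loci: frozenset[str]
    is_unique: bool


@dataclass
class Hierarchy:
    """Families plus their allele clusters at every ladder threshold."""

    families: list[GeneFamily] = field(default_factory=list)
    alleles: dict[str, list[AlleleCluster]] = field(default_factory=dict)
    per_locus_threshold: dict[str, int] = field(default_factory=dict)
    genome_of: dict[str, str] = field(default_factory=dict)

    def family(self, family_id: str) -> GeneFamily:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(family_id)

    def family_of(self) -> dict[str, str]:
        return {locus: fam.family_id
                for fam in self.families for locus in fam.member_loci}

    def to_long_table(self) -> list[tuple[str, str, str, int, bool]]:
        """(locus_id, family_id, allele_id, threshold, is_unique) rows."""
        rows = []
        for fam in self.families:
            for allele in self.alleles.get(fam.family_id, []):
                for locus in sorted(allele.member_loci):
                    rows.append((locus, fam.family_id, allele.allele_id,
                                 allele.threshold, allele.is_unique))
        return rows


def _family_sort_key(members: frozenset[str], genome_of: dict[str, str]):
    genomes = {genome_of[m] for m in members}
    return (-len(genomes), -len(members), min(members))


def build_families(score_graph: ScoreGraph, loci: list[Locus],
                   config: PipelineConfig,
                   mcl_params: MclParams | None = None) -> list[GeneFamily]:
    """MCL at the base threshold; clusters become g0001... families.

    Numbering is by descending genome count, ties by descending member count
    then smallest locus id, so core families come first.
    """
    mcl_params = mcl_params or MclParams(inflation=config.inflation)
    genome_of = {l.locus_id: l.genome_id for l in loci}
    base_graph = filter_by_identity(score_graph, config.base_threshold)
    clustering = mcl(base_graph, mcl_params)
    ordered = sorted(clustering.clusters,
                     key=lambda c: _family_sort_key(c, genome_of))
    families = []
    for i, members in enumerate(ordered, start=1):
        counts: dict[str, int] = {}
        for locus in members:
            g = genome_of[locus]
            counts[g] = counts.get(g, 0) + 1
        families.append(GeneFamily(
            family_id=f"g{i:04d}",
            base_threshold=config.base_threshold,
            member_loci=frozenset(members),
            genomes=frozenset(counts),
            per_genome_count=counts,
            family_threshold=config.base_threshold))
    logger.info("base clustering: %d families from %d loci",
                len(families), len(loci))
    return families


def refine_alleles(families: list[GeneFamily], score_graph: ScoreGraph,
                   loci: list[Locus], config: PipelineConfig,
                   mcl_params: MclParams | None = None) -> Hierarchy:
    """Re-cluster each family at every higher ladder threshold.

    Clustering runs on the family's own subgraph, which guarantees the
    nesting the hierarchy promises: a cluster at threshold t is always a
    subset of exactly one cluster at any lower threshold. Loci isolated at a
    threshold become singleton allele clusters.
    """
    mcl_params = mcl_params or MclParams(inflation=config.inflation)
    genome_of = {l.locus_id: l.genome_id for l in loci}
    hierarchy = Hierarchy(families=list(families), genome_of=genome_of)

    for fam in families:
        fam_alleles: list[AlleleCluster] = []
        seen_sets: set[frozenset[str]] = set()
        # the family itself is the base-threshold cluster, unique by definition
        base_allele = AlleleCluster(
            allele_id=f"{fam.family_id}_t{fam.base_threshold}_1",
            family_id=fam.family_id, threshold=fam.base_threshold,
            member_loci=fam.member_loci, is_unique=True)
        fam_alleles.append(base_allele)
        seen_sets.add(fam.member_loci)
        for locus in fam.member_loci:
            hierarchy.per_locus_threshold[locus] = fam.base_threshold
        fam.family_threshold = fam.base_threshold

        subgraph = score_graph.subgraph(fam.member_loci)
        prev_partition: list[frozenset[str]] = [fam.member_loci]
        for t in config.thresholds[1:]:
            filtered = filter_by_identity(subgraph, t)
            # cluster within each previous-threshold cluster to force nesting
            partition: list[frozenset[str]] = []
            for parent in prev_partition:
                if len(parent) == 1:
                    partition.append(parent)
                    continue
                sub = filtered.subgraph(parent)
                clustering = mcl(sub, mcl_params)
                partition.extend(clustering.clusters)
            partition.sort(key=lambda c: (-len(c), min(c)))
            for k, members in enumerate(partition, start=1):
                is_unique = members not in seen_sets
                fam_alleles.append(AlleleCluster(
                    allele_id=f"{fam.family_id}_t{t}_{k}",
                    family_id=fam.family_id, threshold=t,
                    member_loci=members, is_unique=is_unique))
                if is_unique:
                    seen_sets.add(members)
                    for locus in members:
                        hierarchy.per_locus_threshold[locus] = max(
                            hierarchy.per_locus_threshold[locus], t)
            if len(partition) == 1:
                fam.family_threshold = t
            prev_partition = partition
        hierarchy.alleles[fam.family_id] = fam_alleles
    return hierarchy


def allele_count_curve(hierarchy: Hierarchy,
                       ladder: list[int] | None = None) -> dict[int, int]:
    """Unique-allele counts per ladder threshold (families count at base)."""
    if ladder is None:
        thresholds = sorted({a.threshold
                             for alleles in hierarchy.alleles.values()
                             for a in alleles})
    else:
        thresholds = list(ladder)
    curve = {t: 0 for t in thresholds}
    for alleles in hierarchy.alleles.values():
        for allele in alleles:
            if allele.is_unique and allele.threshold in curve:
                curve[allele.threshold] += 1
    return curve
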