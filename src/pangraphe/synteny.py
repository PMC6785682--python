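"""Syntenic pangenome graph and block ordering of the output table.

Gene families are linked when their loci are immediate neighbours on a
contig; edge support counts the genomes showing that adjacency. Families
sharing the same genome count are chained into maximal unbranched blocks
along edges supported by every one of those genomes, and blocks are emitted
in descending genome count so the core genome leads the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .annotation_io import GenomeAnnotation
from .hierarchy import Hierarchy

logger = logging.getLogger(__name__)


@dataclass
class SyntenyGraph:
    """Directed family-adjacency graph; support = genomes with the adjacency."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def support(self, a: str, b: str) -> int:
        data = self.graph.get_edge_data(a, b)
        return data["support"] if data else 0

    def undirected_support(self, a: str, b: str) -> int:
        return max(self.support(a, b), self.support(b, a))

    def dump_rows(self) -> list[tuple]:
        """GFA-like TSV rows: node lines then edge lines."""
        rows: list[tuple] = []
        for node in sorted(self.graph.nodes):
            rows.append(("N", node, self.graph.nodes[node].get("genome_count", 0)))
        for a, b, data in sorted(self.graph.edges(data=True)):
            rows.append(("E", a, b, data["support"]))
        return rows


@dataclass
class SyntenicBlock:
    block_id: str
    family_ids: list[str]
    genome_count: int


def build_synteny_graph(genomes: list[GenomeAnnotation],
                        hierarchy: Hierarchy) -> SyntenyGraph:
    """One edge per adjacent retained-locus pair along each contig.

    Traversal is left-to-right; an adjacent pair lying entirely on the minus
    strand contributes its edge in reverse orientation (reading direction).
    A genome contributes at most one unit of support per directed edge.
    Self-edges (tandem arrays) are recorded but never chained into blocks.
    """
    family_of = hierarchy.family_of()
    graph = nx.DiGraph()
    genome_counts = {fam.family_id: fam.genome_count
                     for fam in hierarchy.families}
    for fam_id, count in genome_counts.items():
        graph.add_node(fam_id, genome_count=count)
    per_edge_genomes: dict[tuple[str, str], set[str]] = {}
    for genome in genomes:
        for contig_id in sorted(genome.contigs):
            chain = [l for l in genome.contigs[contig_id]
                     if l.locus_id in family_of]
            for left, right in zip(chain, chain[1:]):
                fam_a = family_of[left.locus_id]
                fam_b = family_of[right.locus_id]
                if left.strand == "-" and right.strand == "-":
                    fam_a, fam_b = fam_b, fam_a
                per_edge_genomes.setdefault((fam_a, fam_b), set()).add(
                    genome.genome_id)
    for (a, b), genome_set in sorted(per_edge_genomes.items()):
        graph.add_edge(a, b, support=len(genome_set))
    syn = SyntenyGraph(graph=graph)
    logger.info("synteny graph: %d families, %d adjacencies",
                graph.number_of_nodes(), graph.number_of_edges())
    return syn


def order_pangenome(synteny: SyntenyGraph,
                    hierarchy: Hierarchy) -> list[SyntenicBlock]:
    """Chain equal-genome-count families into blocks and order the table.

    Within each genome-count group, edges whose (undirected) support equals
    the group's genome count qualify; qualifying edges are taken greedily
    from the highest support (ties lexicographic) and joined into simple
    paths — an edge that would give a family three neighbours, or close a
    cycle, is dropped. Blocks are ordered by descending genome count, then
    descending length, then first family id.
    """
    genome_count = {fam.family_id: fam.genome_count
                    for fam in hierarchy.families}
    groups: dict[int, list[str]] = {}
    for fam_id, count in genome_count.items():
        groups.setdefault(count, []).append(fam_id)

    blocks: list[SyntenicBlock] = []
    for count in sorted(groups, reverse=True):
        members = set(groups[count])
        edges = []
        seen = set()
        for a, b in synteny.graph.edges:
            if a == b or a not in members or b not in members:
                continue
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            support = synteny.undirected_support(a, b)
            if support == count:
                edges.append((support, key[0], key[1]))
        edges.sort(key=lambda e: (-e[0], e[1], e[2]))

        # greedy path building: accept an edge when both endpoints still
        # have chain-degree < 2 and it does not close a cycle
        neighbours: dict[str, list[str]] = {m: [] for m in members}
        chain_of: dict[str, int] = {}
        next_chain = 0
        for _, a, b in edges:
            if len(neighbours[a]) >= 2 or len(neighbours[b]) >= 2:
                continue
            ca, cb = chain_of.get(a), chain_of.get(b)
            if ca is not None and ca == cb:
                continue  # would close a cycle: lowest-support edge dropped
            neighbours[a].append(b)
            neighbours[b].append(a)
            merged = []
            for node, c in ((a, ca), (b, cb)):
                if c is None:
                    chain_of[node] = next_chain if not merged else merged[0]
                    merged.append(chain_of[node])
                else:
                    merged.append(c)
            target = min(merged)
            for node in list(chain_of):
                if chain_of[node] in merged:
                    chain_of[node] = target
            next_chain += 1

        # walk each chain end-to-end
        visited: set[str] = set()
        chain_blocks: list[list[str]] = []
        for fam_id in sorted(members):
            if fam_id in visited or len(neighbours[fam_id]) > 1:
                continue
            path = [fam_id]
            visited.add(fam_id)
            current = fam_id
            while True:
                nxt = [n for n in neighbours[current] if n not in visited]
                if not nxt:
                    break
                current = nxt[0]
                visited.add(current)
                path.append(current)
            if path[-1] < path[0]:
                path.reverse()
            chain_blocks.append(path)
        chain_blocks.sort(key=lambda p: (-len(p), p[0]))
        for path in chain_blocks:
            blocks.append(SyntenicBlock(
                block_id="", family_ids=path, genome_count=count))

    for i, block in enumerate(blocks, start=1):
        block.block_id = f"b{i:04d}"
    return blocks


def block_order(blocks: list[SyntenicBlock]) -> list[str]:
    """Family ids in final table order (a permutation of all families)."""
    return [fam_id for block in blocks for fam_id in block.family_ids]
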