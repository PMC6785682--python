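"""End-to-end pangenome construction: parse -> filter -> dereplicate ->
all-vs-all -> MCL over the threshold ladder -> paralog resolution ->
synteny ordering -> summaries and output files."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_io import GenomeAnnotation, Locus, filter_features, parse_genome
from .config import PipelineConfig
from .dereplication import RepCluster, iterative_dereplicate
from .hierarchy import Hierarchy, build_families, refine_alleles
from .mcl import MclParams
from .paralogs import (FissionGroup, ParalogAnnotation, apply_splits,
                       classify_paralogs, detect_paralog_families,
                       merge_fissions, paralog_report_rows)
from .similarity import ScoreGraph, all_vs_all, normalize_and_expand
from .summaries import (FamilySummary, PresenceAbsenceMatrix, align_families,
                        most_frequent_product, summarize, write_outputs)
from .synteny import (SyntenicBlock, SyntenyGraph, build_synteny_graph,
                      order_pangenome)

logger = logging.getLogger(__name__)


@dataclass
class PangenomeResult:
    """Everything a finished run produced, in memory."""

    config: PipelineConfig
    genomes: list[GenomeAnnotation]
    retained: list[Locus]
    excluded: list[tuple[Locus, str]]
    rep_clusters: list[RepCluster]
    score_graph: ScoreGraph
    hierarchy: Hierarchy
    paralog_annotations: list[ParalogAnnotation]
    fission_groups: list[FissionGroup]
    synteny: SyntenyGraph
    blocks: list[SyntenicBlock]
    summaries: list[FamilySummary]
    matrix: PresenceAbsenceMatrix
    output_paths: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def loci_by_id(self) -> dict[str, Locus]:
        return {l.locus_id: l for l in self.retained}


def _input_paths(input_dir: str | Path) -> list[Path]:
    paths = sorted(Path(input_dir).glob("*.gff")) + \
        sorted(Path(input_dir).glob("*.gff3"))
    return sorted(set(paths))


def run_pipeline(input_dir: str | Path, out_dir: str | Path | None = None,
                 config: PipelineConfig | None = None,
                 mcl_params: MclParams | None = None,
                 threads: int = 1, align: bool = False) -> PangenomeResult:
    """Run the whole pipeline over every GFF3 in `input_dir`.

    Results are independent of `threads`: parallel work is partitioned over
    sorted task lists and merged in that order.
    """
    config = config or PipelineConfig()
    mcl_params = mcl_params or MclParams(inflation=config.inflation)
    t0 = time.monotonic()
    timings: dict[str, float] = {}

    paths = _input_paths(input_dir)
    if len(paths) < 2:
        raise ValueError(
            f"need at least 2 GFF3 inputs, found {len(paths)} in {input_dir}")
    genomes = [parse_genome(p, config) for p in paths]
    timings["parse"] = time.monotonic() - t0

    retained, excluded = filter_features(genomes, config)
    loci_by_id = {l.locus_id: l for l in retained}
    timings["filter"] = time.monotonic() - t0

    rep_clusters = iterative_dereplicate(retained, config)
    reps = [loci_by_id[c.rep_id] for c in rep_clusters]
    timings["dereplicate"] = time.monotonic() - t0

    hits = all_vs_all(reps, config)
    score_graph = normalize_and_expand(hits, rep_clusters, config)
    timings["similarity"] = time.monotonic() - t0

    families = build_families(score_graph, retained, config, mcl_params)
    hierarchy = refine_alleles(families, score_graph, retained, config,
                               mcl_params)
    timings["hierarchy"] = time.monotonic() - t0

    flagged = detect_paralog_families(hierarchy)
    family_by_id = {f.family_id: f for f in hierarchy.families}
    tasks = sorted(flagged)

    def _classify(fam_id: str):
        return classify_paralogs(family_by_id[fam_id], loci_by_id, config)

    if threads > 1 and len(tasks) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(_classify, tasks))
    else:
        results = [_classify(t) for t in tasks]
    annotations: list[ParalogAnnotation] = []
    fission_groups: list[FissionGroup] = []
    for anns, groups in results:
        annotations.extend(anns)
        fission_groups.extend(groups)
    hierarchy = merge_fissions(hierarchy, fission_groups)
    hierarchy = apply_splits(hierarchy, fission_groups)
    timings["paralogs"] = time.monotonic() - t0

    synteny = build_synteny_graph(genomes, hierarchy)
    blocks = order_pangenome(synteny, hierarchy)
    timings["synteny"] = time.monotonic() - t0

    products = {
        fam.family_id: most_frequent_product(
            [loci_by_id[l] for l in sorted(fam.member_loci)])
        for fam in hierarchy.families}
    summaries, matrix = summarize(hierarchy, blocks, len(genomes), config,
                                  products)
    timings["summaries"] = time.monotonic() - t0

    result = PangenomeResult(
        config=config, genomes=genomes, retained=retained, excluded=excluded,
        rep_clusters=rep_clusters, score_graph=score_graph,
        hierarchy=hierarchy, paralog_annotations=annotations,
        fission_groups=fission_groups, synteny=synteny, blocks=blocks,
        summaries=summaries, matrix=matrix)
    result.manifest = _build_manifest(paths, config, result, timings)

    if out_dir is not None:
        out = Path(out_dir)
        family_of = hierarchy.family_of()
        rows = paralog_report_rows(annotations, fission_groups, family_of)
        result.output_paths = write_outputs(
            out, hierarchy, blocks, summaries, matrix, loci_by_id, rows,
            config)
        result.output_paths.update(_write_auxiliary_tables(out, result))
        if align:
            result.output_paths["core_alignment"] = align_families(
                hierarchy, loci_by_id, summaries, config, out)
        manifest_path = out / "manifest.json"
        tmp = manifest_path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
        tmp.replace(manifest_path)  # atomic publish
        result.output_paths["manifest"] = manifest_path
    return result


def _write_auxiliary_tables(out: Path, result: PangenomeResult) -> dict:
    """Dereplication membership, allele hierarchy and synteny graph dumps."""
    paths = {}
    paths["derep_clusters"] = out / "dereplication_clusters.tsv"
    with open(paths["derep_clusters"], "w") as fh:
        fh.write("rep_id\tmember_id\tidentity_level\n")
        for cluster in sorted(result.rep_clusters, key=lambda c: c.rep_id):
            for member in sorted(cluster.member_ids):
                fh.write(f"{cluster.rep_id}\t{member}\t"
                         f"{cluster.identity_level:g}\n")
    paths["alleles"] = out / "allele_hierarchy.tsv"
    with open(paths["alleles"], "w") as fh:
        fh.write("locus_id\tfamily_id\tallele_id\tthreshold\tis_unique\n")
        for row in result.hierarchy.to_long_table():
            fh.write("\t".join(str(v) for v in row) + "\n")
    paths["synteny"] = out / "synteny_graph.tsv"
    with open(paths["synteny"], "w") as fh:
        for row in result.synteny.dump_rows():
            fh.write("\t".join(str(v) for v in row) + "\n")
    return paths


def _build_manifest(paths: list[Path], config: PipelineConfig,
                    result: PangenomeResult, timings: dict) -> dict:
    from . import __version__

    checksums = {}
    for p in paths:
        digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        checksums[p.name] = digest
    return {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": checksums,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "counts": {
            "genomes": len(result.genomes),
            "loci_in": len(result.retained) + len(result.excluded),
            "loci_retained": len(result.retained),
            "loci_excluded": len(result.excluded),
            "representatives": len(result.rep_clusters),
            "families": len(result.hierarchy.families),
            "alleles": sum(len(a) for a in result.hierarchy.alleles.values()),
            "paralog_annotations": len(result.paralog_annotations),
            "fission_groups": len(result.fission_groups),
            "blocks": len(result.blocks),
        },
    }
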