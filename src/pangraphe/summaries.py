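"""Core/accessory classification, dose filtering, divergence summaries and
all tabular/alignment outputs.

Percentages in reports are recomputed from their integer numerator and
denominator and rounded half-up to two decimals, so every printed figure can
be checked by hand.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from scipy.stats import chi2_contingency

from .annotation_io import Locus, write_fasta
from .config import PipelineConfig
from .hierarchy import Hierarchy
from .synteny import SyntenicBlock, block_order

logger = logging.getLogger(__name__)


def percentage(numerator: int, denominator: int) -> float:
    """numerator/denominator as a percent, half-up at 2 decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class FamilySummary:
    family_id: str
    genome_count: int
    total_genomes: int
    dose: float  # mean merged copies per containing genome
    is_core: bool
    dose_excluded: bool
    family_threshold: int
    product: str


@dataclass
class PresenceAbsenceMatrix:
    """Families (block order) x genomes; cells are merged copy counts."""

    table: pd.DataFrame

    def binarized(self) -> pd.DataFrame:
        return (self.table > 0).astype(int)


def summarize(hierarchy: Hierarchy, blocks: list[SyntenicBlock],
              total_genomes: int, config: PipelineConfig,
              products: dict[str, str] | None = None
              ) -> tuple[list[FamilySummary], PresenceAbsenceMatrix]:
    """One FamilySummary per family, in block order, plus the matrix.

    Core status uses a strict inequality (present in more than
    ``core_fraction`` of genomes); the dose filter flags families whose mean
    merged copy number exceeds ``dose_cutoff``.
    """
    order = block_order(blocks)
    by_id = {fam.family_id: fam for fam in hierarchy.families}
    products = products or {}
    summaries = []
    genome_ids = sorted({g for fam in hierarchy.families
                         for g in fam.genomes})
    matrix = pd.DataFrame(0, index=order, columns=genome_ids, dtype=int)
    for fam_id in order:
        fam = by_id[fam_id]
        merged_total = sum(fam.per_genome_count.values())
        dose = merged_total / fam.genome_count if fam.genome_count else 0.0
        summaries.append(FamilySummary(
            family_id=fam_id,
            genome_count=fam.genome_count,
            total_genomes=total_genomes,
            dose=dose,
            is_core=fam.genome_count / total_genomes > config.core_fraction,
            dose_excluded=dose > config.dose_cutoff,
            family_threshold=fam.family_threshold,
            product=products.get(fam_id, "")))
        for genome, count in fam.per_genome_count.items():
            matrix.at[fam_id, genome] = count
    return summaries, PresenceAbsenceMatrix(table=matrix)


def most_frequent_product(loci: list[Locus]) -> str:
    counts: dict[str, int] = {}
    for locus in loci:
        if locus.product:
            counts[locus.product] = counts.get(locus.product, 0) + 1
    if not counts:
        return ""
    return max(sorted(counts), key=lambda p: counts[p])


def divergence_breakdown(summaries: list[FamilySummary],
                         config: PipelineConfig,
                         divergence_threshold: int = 95) -> dict:
    """Counts of divergent (family_threshold < 95) vs conserved families,
    split by core status, after dropping dose-excluded families.

    Reports the 2x2 chi-square statistic and p-value (no continuity
    correction) without making a decision.
    """
    kept = [s for s in summaries if not s.dose_excluded]
    n_excluded = len(summaries) - len(kept)
    cells = {"core_divergent": 0, "core_conserved": 0,
             "accessory_divergent": 0, "accessory_conserved": 0}
    for s in kept:
        status = "core" if s.is_core else "accessory"
        kind = ("divergent" if s.family_threshold < divergence_threshold
                else "conserved")
        cells[f"{status}_{kind}"] += 1
    result = {
        "total_families": len(summaries),
        "dose_excluded": n_excluded,
        "analysed": len(kept),
        "divergent": cells["core_divergent"] + cells["accessory_divergent"],
        **cells,
    }
    if result["analysed"]:
        result["pct_divergent"] = percentage(result["divergent"],
                                             result["analysed"])
    table = [[cells["core_divergent"], cells["core_conserved"]],
             [cells["accessory_divergent"], cells["accessory_conserved"]]]
    nonzero = sum(1 for row in table for v in row if v > 0)
    if nonzero >= 2 and all(sum(row) > 0 for row in table):
        try:
            stat, pvalue, _, _ = chi2_contingency(table, correction=False)
            result["chi2"] = float(stat)
            result["chi2_pvalue"] = float(pvalue)
        except ValueError:
            result["chi2_note"] = "degenerate table; statistic omitted"
    else:
        result["chi2_note"] = "fewer than 2 non-empty cells; statistic omitted"
    return result


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def write_outputs(out_dir: str | Path, hierarchy: Hierarchy,
                  blocks: list[SyntenicBlock],
                  summaries: list[FamilySummary],
                  matrix: PresenceAbsenceMatrix,
                  loci_by_id: dict[str, Locus],
                  paralog_rows: list[tuple],
                  config: PipelineConfig,
                  allele_counts: dict[str, dict[int, int]] | None = None
                  ) -> dict[str, Path]:
    """Write the pangenome table, Roary-style CSV, Rtab, per-family FASTA
    and the run log. Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary_by_id = {s.family_id: s for s in summaries}
    family_by_id = {f.family_id: f for f in hierarchy.families}
    genome_ids = list(matrix.table.columns)
    allele_counts = allele_counts or {}

    # (a) main pangenome table
    rows = []
    block_of = {fam_id: b.block_id for b in blocks for fam_id in b.family_ids}
    for fam_id in block_order(blocks):
        fam = family_by_id[fam_id]
        s = summary_by_id[fam_id]
        per_genome = {}
        for locus in sorted(fam.member_loci):
            per_genome.setdefault(hierarchy.genome_of[locus], []).append(locus)
        row = {
            "family_id": fam_id,
            "block_id": block_of[fam_id],
            "family_threshold": s.family_threshold,
            "n_alleles": sum(allele_counts.get(fam_id, {}).values()) or "",
            "genome_count": s.genome_count,
            "dose": f"{s.dose:.4f}",
            "is_core": int(s.is_core),
            "dose_excluded": int(s.dose_excluded),
            "product": s.product,
        }
        for genome in genome_ids:
            row[genome] = ";".join(per_genome.get(genome, []))
        rows.append(row)
    table = pd.DataFrame(rows)
    paths["gene_families"] = out / "pangenome.gene_families.tsv"
    table.to_csv(paths["gene_families"], sep="\t", index=False)

    # (b) Roary-style presence/absence CSV
    roary_rows = []
    for fam_id in block_order(blocks):
        fam = family_by_id[fam_id]
        s = summary_by_id[fam_id]
        per_genome = {}
        for locus in sorted(fam.member_loci):
            per_genome.setdefault(hierarchy.genome_of[locus], []).append(locus)
        row = {"Gene": fam_id, "Non-unique Gene name": "",
               "Annotation": s.product}
        for genome in genome_ids:
            row[genome] = "\t".join(per_genome.get(genome, []))
        roary_rows.append(row)
    paths["presence_absence"] = out / "gene_presence_absence.csv"
    pd.DataFrame(roary_rows).to_csv(paths["presence_absence"], index=False)

    # (c) binary Rtab
    paths["rtab"] = out / "gene_presence_absence.Rtab"
    rtab = matrix.binarized()
    rtab.index.name = "Gene"
    rtab.to_csv(paths["rtab"], sep="\t")

    # (d) per-family FASTA
    fasta_dir = out / "family_sequences"
    fasta_dir.mkdir(exist_ok=True)
    for fam in hierarchy.families:
        records = [(locus_id, loci_by_id[locus_id].analysis_seq(
            config.sequence_space))
            for locus_id in sorted(fam.member_loci)]
        write_fasta(records, fasta_dir / f"{fam.family_id}.fasta")
    paths["family_sequences"] = fasta_dir

    # paralog report
    paths["paralogs"] = out / "paralog_report.tsv"
    with open(paths["paralogs"], "w") as fh:
        fh.write("locus_id\tfamily_id\tclassification\tdup_ordinal\t"
                 "group_id\treference_coverage\n")
        for row in paralog_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")

    # (e) run log
    paths["run_log"] = out / "run_metadata.json"
    with open(paths["run_log"], "w") as fh:
        json.dump({"config": config.to_dict(),
                   "n_families": len(hierarchy.families),
                   "n_blocks": len(blocks),
                   "genomes": genome_ids}, fh, indent=2, sort_keys=True)
    return paths


def read_rtab(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def center_star_align(seqs: dict[str, str], space: str = "aa"
                      ) -> dict[str, str]:
    """Progressive multiple alignment against the longest sequence.

    Every sequence is aligned globally to the centre (longest) sequence and
    the centre-relative insertions are merged, yielding one fixed-width
    alignment. Exact and deterministic; adequate for the within-family
    divergences seen here, with MAFFT available as an external adapter.
    """
    if len(seqs) == 1:
        return dict(seqs)
    ids = sorted(seqs)
    center_id = max(ids, key=lambda i: (len(seqs[i]), i))
    center = seqs[center_id]
    # per-sequence: list of (center_pos or None, residue) columns
    pairwise: dict[str, list[tuple[int | None, str]]] = {}
    insertions = [0] * (len(center) + 1)  # max insert length before center pos
    for seq_id in ids:
        if seq_id == center_id:
            continue
        stats_cols = _global_columns(seqs[seq_id], center, space)
        pairwise[seq_id] = stats_cols
        run = 0
        for center_pos, _ in stats_cols:
            if center_pos is None:
                run += 1
            else:
                insertions[center_pos] = max(insertions[center_pos], run)
                run = 0
        insertions[len(center)] = max(insertions[len(center)], run)

    width = len(center) + sum(insertions)
    aligned: dict[str, str] = {}
    # centre row
    out = []
    for pos, residue in enumerate(center):
        out.append("-" * insertions[pos])
        out.append(residue)
    out.append("-" * insertions[len(center)])
    aligned[center_id] = "".join(out)
    for seq_id in ids:
        if seq_id == center_id:
            continue
        cols = pairwise[seq_id]
        out = []
        pending = []
        next_center = 0
        for center_pos, residue in cols:
            if center_pos is None:
                pending.append(residue)
                continue
            while next_center <= center_pos:
                gap = insertions[next_center]
                if next_center == center_pos:
                    out.append("".join(pending).rjust(gap, "-"))
                    pending = []
                else:
                    out.append("-" * gap)
                out.append(residue if next_center == center_pos else "-")
                next_center += 1
        while next_center <= len(center):
            gap = insertions[next_center]
            if next_center == len(center):
                out.append("".join(pending).rjust(gap, "-"))
                pending = []
            else:
                out.append("-" * gap)
            if next_center < len(center):
                out.append("-")
            next_center += 1
        row = "".join(out)
        assert len(row) == width, (seq_id, len(row), width)
        aligned[seq_id] = row
    return aligned


def _global_columns(seq: str, center: str, space: str
                    ) -> list[tuple[int | None, str]]:
    """Columns of the global alignment of seq vs center, as
    (center position or None for an insertion, seq residue), gaps in seq
    omitted (they surface as plain center columns)."""
    from ._align import make_aligner, sanitize_protein

    if space == "aa":
        seq_c, center_c = sanitize_protein(seq), sanitize_protein(center)
    else:
        seq_c, center_c = seq, center
    aligner = make_aligner(space, "global")
    alignment = next(iter(aligner.align(seq_c, center_c)))
    q_blocks, c_blocks = alignment.aligned
    cols: list[tuple[int | None, str]] = []
    q_prev = 0
    c_prev = 0
    for (qs, qe), (cs, ce) in zip(q_blocks, c_blocks):
        for q in range(q_prev, qs):  # insertion relative to center
            cols.append((None, seq[q]))
        q_prev = qs
        c_prev = cs
        for offset in range(qe - qs):
            cols.append((cs + offset, seq[qs + offset]))
        q_prev, c_prev = qe, ce
    for q in range(q_prev, len(seq)):
        cols.append((None, seq[q]))
    return cols


def mafft_available() -> bool:
    return shutil.which("mafft") is not None


def mafft_align(seqs: dict[str, str]) -> dict[str, str]:
    """External-aligner adapter (MAFFT), used as a cross-check oracle."""
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        write_fasta(sorted(seqs.items()), infile)
        proc = subprocess.run(
            ["mafft", "--quiet", "--auto", str(infile)],
            capture_output=True, text=True, check=True)
    from io import StringIO

    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(StringIO(proc.stdout), "fasta")}


def align_families(hierarchy: Hierarchy, loci_by_id: dict[str, Locus],
                   summaries: list[FamilySummary],
                   config: PipelineConfig, out_dir: str | Path,
                   backend=center_star_align) -> Path:
    """Per-family alignments plus the concatenated core-gene alignment.

    The core alignment concatenates, over single-copy core families
    (dose <= dose_cutoff), one representative per genome — the longest locus
    when a genome holds several; genomes lacking the family contribute a gap
    run. A partition table maps families to column ranges.
    """
    out = Path(out_dir)
    aln_dir = out / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    summary_by_id = {s.family_id: s for s in summaries}
    genome_ids = sorted({g for fam in hierarchy.families for g in fam.genomes})
    core_parts: dict[str, list[str]] = {g: [] for g in genome_ids}
    partition_rows = []
    cursor = 0
    for fam in hierarchy.families:
        seqs = {locus_id: loci_by_id[locus_id].analysis_seq(
            config.sequence_space)
            for locus_id in sorted(fam.member_loci)}
        aligned = backend(seqs) if len(seqs) > 1 else dict(seqs)
        write_fasta(sorted(aligned.items()),
                    aln_dir / f"{fam.family_id}.aln.fasta")
        s = summary_by_id.get(fam.family_id)
        if s is None or not s.is_core or s.dose_excluded:
            continue
        width = len(next(iter(aligned.values())))
        # one representative per genome: the longest locus
        rep_rows: dict[str, str] = {}
        for locus_id, row in aligned.items():
            genome = hierarchy.genome_of[locus_id]
            keep = rep_rows.get(genome)
            if keep is None or _ungapped_len(row) > _ungapped_len(keep):
                rep_rows[genome] = row
        for genome in genome_ids:
            core_parts[genome].append(rep_rows.get(genome, "-" * width))
        partition_rows.append((fam.family_id, cursor + 1, cursor + width))
        cursor += width
    core_path = out / "core_gene_alignment.fasta"
    write_fasta([(g, "".join(core_parts[g])) for g in genome_ids], core_path)
    with open(out / "core_alignment_partitions.tsv", "w") as fh:
        fh.write("family_id\tstart\tend\n")
        for fam_id, start, end in partition_rows:
            fh.write(f"{fam_id}\t{start}\t{end}\n")
    return core_path


def _ungapped_len(row: str) -> int:
    return len(row) - row.count("-")
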