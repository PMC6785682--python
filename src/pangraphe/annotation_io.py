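"""GFF3 + FASTA parsing into validated locus records, and GFF3/FASTA output.

Coordinates are GFF3-native throughout: 1-based, inclusive on both ends.
Feature lines are parsed with gffutils; contig sequences come from the
``##FASTA`` section of the same file or a side-car FASTA with the same stem.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: reason codes attached to excluded loci
TOO_SHORT = "too_short"
INTERNAL_STOP = "internal_stop"
AMBIGUOUS = "ambiguous"

_AMBIGUOUS_NT = set("NRYSWKMBDHV")


@dataclass(frozen=True)
class Locus:
    """One annotated feature (CDS, tRNA, ...) with its sequences.

    ``nt_seq`` is already reverse-complemented for minus-strand features, so
    it always reads 5'→3' in the coding orientation. ``aa_seq`` is the
    bacterial (table 11) translation with any terminal stop stripped; it is
    empty for features analysed in nucleotide space.
    """

    locus_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    feature_type: str
    product: str
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.locus_id}: invalid coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: invalid strand {self.strand!r}")
        if len(self.nt_seq) != self.end - self.start + 1:
            raise ValueError(
                f"{self.locus_id}: sequence length {len(self.nt_seq)} does not "
                f"match span {self.start}..{self.end}")

    @property
    def length_nt(self) -> int:
        return len(self.nt_seq)

    def analysis_seq(self, sequence_space: str) -> str:
        """Sequence compared by the pipeline: aa for CDS, nt otherwise."""
        if sequence_space == "aa" and self.aa_seq:
            return self.aa_seq
        return self.nt_seq


@dataclass
class GenomeAnnotation:
    """All retained loci of one genome, per contig, sorted by start."""

    genome_id: str
    contigs: dict[str, list[Locus]] = field(default_factory=dict)
    contig_seqs: dict[str, str] = field(default_factory=dict)

    @property
    def loci(self) -> list[Locus]:
        return [loc for contig in self.contigs.values() for loc in contig]

    def add(self, locus: Locus) -> None:
        self.contigs.setdefault(locus.contig_id, []).append(locus)

    def sort(self) -> None:
        for loci in self.contigs.values():
            loci.sort(key=lambda l: (l.start, l.end, l.locus_id))


def translate_cds(nt_seq: str) -> str:
    """Bacterial table-11 translation, terminal stop stripped.

    Trailing bases that do not complete a codon are ignored.
    """
    trimmed = nt_seq[: len(nt_seq) - len(nt_seq) % 3]
    if not trimmed:
        return ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial-codon warnings
        aa = str(Seq(trimmed).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def _split_gff_fasta(text: str) -> tuple[str, str | None]:
    marker = "##FASTA"
    idx = text.find(marker)
    if idx == -1:
        return text, None
    return text[:idx], text[idx + len(marker):].lstrip("\n")


def _read_contigs(fasta_text: str) -> dict[str, str]:
    handle = io.StringIO(fasta_text)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def parse_genome(gff3_path: str | Path, config, genome_id: str | None = None,
                 prefix_ids: bool = True) -> GenomeAnnotation:
    """Parse one GFF3 annotation into a GenomeAnnotation.

    Contig sequences come from the embedded ``##FASTA`` block or, failing
    that, a side-car ``<stem>.fasta``/``.fa``/``.fna`` file. Only features
    whose type is in ``config.feature_types`` are kept. Minus-strand
    sequences are reverse-complemented before translation. Locus ids are
    prefixed with the genome id to disambiguate reuse across genomes.
    """
    path = Path(gff3_path)
    if genome_id is None:
        genome_id = path.stem
    text = path.read_text()
    gff_part, fasta_part = _split_gff_fasta(text)
    if fasta_part:
        contig_seqs = _read_contigs(fasta_part)
    else:
        for ext in (".fasta", ".fa", ".fna"):
            sidecar = path.with_suffix(ext)
            if sidecar.exists():
                contig_seqs = _read_contigs(sidecar.read_text())
                break
        else:
            raise FileNotFoundError(
                f"{path}: no ##FASTA section and no side-car FASTA found")

    db = gffutils.create_db(
        gff_part, dbfn=":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True)

    genome = GenomeAnnotation(genome_id=genome_id, contig_seqs=contig_seqs)
    counter = 0
    for feat in db.all_features():
        if feat.featuretype not in config.feature_types:
            continue
        counter += 1
        contig = contig_seqs.get(feat.seqid)
        if contig is None:
            logger.warning("%s: contig %s missing from FASTA; feature %s skipped",
                           genome_id, feat.seqid, feat.id)
            continue
        if feat.end > len(contig) or feat.start < 1:
            logger.warning("%s: feature %s extends past contig end; skipped",
                           genome_id, feat.id)
            continue
        raw_id = feat.attributes.get("ID", [f"feature{counter:05d}"])[0]
        locus_id = f"{genome_id}|{raw_id}" if prefix_ids else raw_id
        nt = contig[feat.start - 1: feat.end]
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        aa = translate_cds(nt) if feat.featuretype == "CDS" else ""
        product = feat.attributes.get("product", [""])[0]
        genome.add(Locus(
            locus_id=locus_id, genome_id=genome_id, contig_id=feat.seqid,
            start=feat.start, end=feat.end, strand=strand,
            feature_type=feat.featuretype, product=product,
            nt_seq=nt, aa_seq=aa))
    genome.sort()
    return genome


def filter_features(genomes: list[GenomeAnnotation], config
                    ) -> tuple[list[Locus], list[tuple[Locus, str]]]:
    """Split all loci into retained and (locus, reason) excluded lists.

    Exclusion rules: shorter than ``config.min_length`` nt; CDS translation
    with an internal stop; more than ``config.max_ambiguous_fraction``
    ambiguous residues. The two lists partition the input.
    """
    retained: list[Locus] = []
    excluded: list[tuple[Locus, str]] = []
    for genome in genomes:
        for locus in genome.loci:
            reason = _exclusion_reason(locus, config)
            if reason is None:
                retained.append(locus)
            else:
                excluded.append((locus, reason))
    if not retained:
        raise RuntimeError("no sequences pass filtering")
    return retained, excluded


def _exclusion_reason(locus: Locus, config) -> str | None:
    if locus.length_nt < config.min_length:
        return TOO_SHORT
    if locus.feature_type == "CDS" and "*" in locus.aa_seq:
        return INTERNAL_STOP
    n_ambig = sum(1 for c in locus.nt_seq if c in _AMBIGUOUS_NT)
    if n_ambig > config.max_ambiguous_fraction * locus.length_nt:
        return AMBIGUOUS
    return None


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def write_gff3(genome: GenomeAnnotation, path: str | Path,
               strip_prefix: bool = True) -> None:
    """Write a GenomeAnnotation back to GFF3 with an embedded ##FASTA block."""
    lines = ["##gff-version 3"]
    for contig_id in sorted(genome.contig_seqs):
        lines.append(
            f"##sequence-region {contig_id} 1 {len(genome.contig_seqs[contig_id])}")
    for contig_id in sorted(genome.contigs):
        for locus in genome.contigs[contig_id]:
            raw_id = locus.locus_id
            if strip_prefix and raw_id.startswith(genome.genome_id + "|"):
                raw_id = raw_id[len(genome.genome_id) + 1:]
            attrs = f"ID={raw_id}"
            if locus.product:
                attrs += f";product={locus.product}"
            lines.append("\t".join([
                contig_id, "pangraphe", locus.feature_type,
                str(locus.start), str(locus.end), ".", locus.strand, "0", attrs]))
    lines.append("##FASTA")
    for contig_id in sorted(genome.contig_seqs):
        lines.append(f">{contig_id}")
        lines.append(_wrap(genome.contig_seqs[contig_id]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as 60-column wrapped FASTA."""
    with open(path, "w") as handle:
        for seq_id, seq in records:
            handle.write(f">{seq_id}\n{_wrap(seq)}\n")
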