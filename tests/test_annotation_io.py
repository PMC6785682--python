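"""GFF3 parsing, translation, filtering and round-trip fidelity."""

import pytest

from pangraphe.annotation_io import (AMBIGUOUS, INTERNAL_STOP, TOO_SHORT,
                                     GenomeAnnotation, filter_features,
                                     parse_genome, translate_cds, write_gff3)
from pangraphe.config import PipelineConfig

from conftest import make_locus


def _write_minimal_gff(path, strand="+"):
    path.write_text("\n".join([
        "##gff-version 3",
        "##sequence-region c1 1 9",
        f"c1\tsrc\tCDS\t1\t9\t.\t{strand}\t0\tID=gene1;product=demo",
        "##FASTA",
        ">c1",
        "ATGGCCTAA",
    ]) + "\n")


class TestParseGenome:
    def test_plus_strand_cds_translated_with_stop_stripped(self, tmp_path):
        gff = tmp_path / "g.gff"
        _write_minimal_gff(gff)
        genome = parse_genome(gff, PipelineConfig(), genome_id="g")
        (locus,) = genome.loci
        assert locus.nt_seq == "ATGGCCTAA"
        assert locus.aa_seq == "MA"
        assert (locus.start, locus.end) == (1, 9)
        assert locus.product == "demo"

    def test_minus_strand_reverse_complemented(self, tmp_path):
        gff = tmp_path / "g.gff"
        _write_minimal_gff(gff, strand="-")
        genome = parse_genome(gff, PipelineConfig(), genome_id="g")
        (locus,) = genome.loci
        assert locus.nt_seq == "TTAGGCCAT"

    def test_missing_fasta_is_fatal(self, tmp_path):
        gff = tmp_path / "nofasta.gff"
        gff.write_text("##gff-version 3\n"
                       "c1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=g1\n")
        with pytest.raises(FileNotFoundError, match="nofasta"):
            parse_genome(gff, PipelineConfig())

    def test_feature_past_contig_end_skipped(self, tmp_path):
        gff = tmp_path / "g.gff"
        gff.write_text("\n".join([
            "##gff-version 3",
            "c1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=ok",
            "c1\tsrc\tCDS\t5\t400\t.\t+\t0\tID=overruns",
            "##FASTA", ">c1", "ATGGCCTAA"]) + "\n")
        genome = parse_genome(gff, PipelineConfig(), genome_id="g")
        assert [l.locus_id for l in genome.loci] == ["g|ok"]

    def test_non_cds_features_filtered_by_type(self, tmp_path):
        gff = tmp_path / "g.gff"
        gff.write_text("\n".join([
            "##gff-version 3",
            "c1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=cds1",
            "c1\tsrc\ttRNA\t1\t9\t.\t+\t0\tID=trna1",
            "##FASTA", ">c1", "ATGGCCTAA"]) + "\n")
        cds_only = parse_genome(gff, PipelineConfig(), genome_id="g")
        assert len(cds_only.loci) == 1
        both = parse_genome(
            gff, PipelineConfig(feature_types={"CDS", "tRNA"}), genome_id="g")
        assert len(both.loci) == 2
        trna = [l for l in both.loci if l.feature_type == "tRNA"][0]
        assert trna.aa_seq == ""  # non-CDS analysed in nucleotide space


def test_translation_table_11_alternative_start_not_forced():
    # GTG codes valine internally under table 11; translate_cds does not
    # remap start codons (annotation pipelines emit M explicitly)
    assert translate_cds("ATGGCC") == "MA"
    assert translate_cds("ATGTGA") == "M"


def test_simulated_genomes_round_trip(small_sim, tmp_path):
    """write_gff3(parse_genome(f)) reparsed matches field-for-field."""
    sim_dir, paths, _ = small_sim
    config = PipelineConfig()
    original = parse_genome(paths[0], config, genome_id="gX")
    rewritten = tmp_path / "rt.gff"
    write_gff3(original, rewritten)
    reparsed = parse_genome(rewritten, config, genome_id="gX")
    assert len(original.loci) == len(reparsed.loci)
    for a, b in zip(original.loci, reparsed.loci):
        assert (a.locus_id, a.contig_id, a.start, a.end, a.strand,
                a.nt_seq, a.aa_seq, a.product) == \
               (b.locus_id, b.contig_id, b.start, b.end, b.strand,
                b.nt_seq, b.aa_seq, b.product)


class TestFilterFeatures:
    @staticmethod
    def _genome(*loci):
        genome = GenomeAnnotation(genome_id="G01")
        for locus in loci:
            genome.add(locus)
        return genome

    def test_reason_codes(self):
        config = PipelineConfig()
        short = make_locus("short", nt_seq="ATG" * 20)  # 60 nt
        stop = make_locus("stop", aa_seq="M*AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA")
        ambig = make_locus("ambig", nt_seq="N" * 60 + "A" * 60)
        clean = make_locus("clean", aa_seq="M" + "A" * 60)
        retained, excluded = filter_features(
            [self._genome(short, stop, ambig, clean)], config)
        reasons = {l.locus_id: r for l, r in excluded}
        assert reasons == {"short": TOO_SHORT, "stop": INTERNAL_STOP,
                           "ambig": AMBIGUOUS}
        assert [l.locus_id for l in retained] == ["clean"]

    def test_partition_and_no_internal_stops(self, small_sim):
        sim_dir, paths, _ = small_sim
        config = PipelineConfig()
        genomes = [parse_genome(p, config) for p in paths]
        n_input = sum(len(g.loci) for g in genomes)
        retained, excluded = filter_features(genomes, config)
        assert len(retained) + len(excluded) == n_input
        assert all("*" not in l.aa_seq for l in retained)

    def test_all_excluded_is_fatal(self):
        config = PipelineConfig()
        with pytest.raises(RuntimeError, match="no sequences pass"):
            filter_features(
                [self._genome(make_locus("s", nt_seq="ATGTAA"))], config)
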