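"""Duplication vs fission classification and family splitting."""

from itertools import combinations

import numpy as np
import pytest

from pangraphe.config import PipelineConfig
from pangraphe.hierarchy import AlleleCluster, GeneFamily, Hierarchy
from pangraphe.paralogs import (DUPLICATION, FISSION_FRAGMENT,
                                _best_combination, _union_length,
                                classify_paralogs, detect_paralog_families,
                                split_family)
from pangraphe.simulate import AA_FREQS, AMINO_ACIDS

from conftest import make_locus

CONFIG = PipelineConfig()


def _random_protein(rng, length):
    return "M" + "".join(rng.choice(list(AMINO_ACIDS), size=length - 1,
                                    p=AA_FREQS))


def _family(loci, family_id="g0001"):
    counts = {}
    for locus in loci:
        counts[locus.genome_id] = counts.get(locus.genome_id, 0) + 1
    return GeneFamily(
        family_id=family_id, base_threshold=50,
        member_loci=frozenset(l.locus_id for l in loci),
        genomes=frozenset(counts), per_genome_count=counts,
        family_threshold=50)


def _hierarchy(families, loci):
    h = Hierarchy(families=list(families))
    h.genome_of = {l.locus_id: l.genome_id for l in loci}
    return h


class TestDetect:
    def test_single_copy_not_flagged(self):
        loci = [make_locus("a", aa_seq="M" * 40, genome_id="A"),
                make_locus("b", aa_seq="M" * 40, genome_id="B")]
        h = _hierarchy([_family(loci)], loci)
        assert detect_paralog_families(h) == []

    def test_multi_copy_flagged(self):
        loci = [make_locus("a1", aa_seq="M" * 40, genome_id="A"),
                make_locus("a2", aa_seq="M" * 40, genome_id="A"),
                make_locus("b", aa_seq="M" * 40, genome_id="B")]
        h = _hierarchy([_family(loci)], loci)
        assert detect_paralog_families(h) == ["g0001"]


class TestClassify:
    def test_identical_second_copy_is_duplication(self):
        rng = np.random.default_rng(5)
        seq = _random_protein(rng, 150)
        loci = [make_locus("A|l1", aa_seq=seq, genome_id="A", start=100),
                make_locus("A|l2", aa_seq=seq, genome_id="A", start=900),
                make_locus("B|l1", aa_seq=seq, genome_id="B", start=100)]
        fam = _family(loci)
        anns, groups = classify_paralogs(
            fam, {l.locus_id: l for l in loci}, CONFIG)
        assert groups == []
        assert len(anns) == 1
        assert anns[0].classification == DUPLICATION
        assert anns[0].dup_ordinal == 2
        assert anns[0].locus_id == "A|l2"  # second in genomic order

    def test_split_gene_halves_form_fission_group(self):
        rng = np.random.default_rng(6)
        full = _random_protein(rng, 200)
        loci = [
            make_locus("A|n", aa_seq=full[:100], genome_id="A", start=100),
            make_locus("A|c", aa_seq=full[100:], genome_id="A", start=500),
            make_locus("B|full", aa_seq=full, genome_id="B", start=100),
        ]
        fam = _family(loci)
        anns, groups = classify_paralogs(
            fam, {l.locus_id: l for l in loci}, CONFIG)
        assert len(groups) == 1
        group = groups[0]
        assert group.fragment_loci == ["A|n", "A|c"]  # reference order
        assert group.reference_locus == "B|full"
        assert group.reference_coverage == pytest.approx(1.0, abs=0.02)
        assert {a.classification for a in anns} == {FISSION_FRAGMENT}

    def test_full_copy_plus_fragments_keeps_canonical_unannotated(self):
        rng = np.random.default_rng(7)
        full = _random_protein(rng, 240)
        loci = [
            make_locus("A|full", aa_seq=full, genome_id="A", start=50),
            make_locus("A|n", aa_seq=full[:120], genome_id="A", start=900),
            make_locus("A|c", aa_seq=full[120:], genome_id="A", start=1600),
            make_locus("B|full", aa_seq=full, genome_id="B", start=50),
        ]
        fam = _family(loci)
        anns, groups = classify_paralogs(
            fam, {l.locus_id: l for l in loci}, CONFIG)
        assert len(groups) == 1
        assert set(groups[0].fragment_loci) == {"A|n", "A|c"}
        # the intact copy is the canonical locus: no duplication record
        assert all(a.locus_id != "A|full" for a in anns)


class TestBestCombination:
    def test_overlap_violation_prefers_two_fragments(self):
        intervals = {"f1": (0, 95), "f2": (95, 190),
                     "f3": (40, 160)}  # f3 overlaps both heavily
        combo = _best_combination(["f1", "f2", "f3"], intervals,
                                  tolerance=0.20)
        assert combo == ["f1", "f2"]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(2, 5))
            intervals = {}
            for i in range(n):
                start = int(rng.integers(0, 150))
                end = start + int(rng.integers(20, 120))
                intervals[f"f{i}"] = (start, end)
            ids = sorted(intervals)
            # oracle: enumerate every subset, same constraints
            best = None
            for size in range(2, n + 1):
                for combo in combinations(ids, size):
                    ivals = [intervals[f] for f in combo]
                    ok = all(
                        min(a[1], b[1]) - max(a[0], b[0])
                        <= 0.2 * min(a[1] - a[0], b[1] - b[0])
                        for a, b in combinations(ivals, 2))
                    if not ok:
                        continue
                    cand = (_union_length(ivals), -size, list(combo))
                    if best is None or cand > best:
                        best = cand
            expected = best[2] if best else None
            assert _best_combination(ids, intervals, 0.2) == expected


class TestMergeAndSplit:
    def _two_gene_family(self):
        """One over-clustered family: two interleaved single-copy genes in
        three genomes, separable at the 80 rung."""
        loci = []
        for g in "ABC":
            loci.append(make_locus(f"{g}|x", aa_seq="M" * 60, genome_id=g,
                                   start=100))
            loci.append(make_locus(f"{g}|y", aa_seq="W" * 60, genome_id=g,
                                   start=500))
        fam = _family(loci, "g0007")
        h = _hierarchy([fam], loci)
        x_set = frozenset(f"{g}|x" for g in "ABC")
        y_set = frozenset(f"{g}|y" for g in "ABC")
        h.alleles["g0007"] = [
            AlleleCluster("g0007_t50_1", "g0007", 50, fam.member_loci, True),
            AlleleCluster("g0007_t80_1", "g0007", 80, x_set, True),
            AlleleCluster("g0007_t80_2", "g0007", 80, y_set, True),
        ]
        return fam, h, x_set, y_set

    def test_split_recovers_children_with_provenance_names(self):
        fam, h, x_set, y_set = self._two_gene_family()
        children = split_family(fam, h)
        assert [c.family_id for c in children] == ["g0007_1", "g0007_2"]
        assert {c.member_loci for c in children} == {x_set, y_set}
        # conservation: children partition the parent
        union = set()
        for c in children:
            assert not union & c.member_loci
            union |= c.member_loci
        assert union == set(fam.member_loci)

    def test_true_duplications_not_split(self):
        loci = []
        for g in "AB":
            loci.append(make_locus(f"{g}|c1", aa_seq="M" * 60, genome_id=g,
                                   start=100))
            loci.append(make_locus(f"{g}|c2", aa_seq="M" * 60, genome_id=g,
                                   start=500))
        fam = _family(loci, "g0003")
        h = _hierarchy([fam], loci)
        h.alleles["g0003"] = [
            AlleleCluster("g0003_t50_1", "g0003", 50, fam.member_loci, True),
            AlleleCluster("g0003_t80_1", "g0003", 80, fam.member_loci, False),
        ]
        assert split_family(fam, h) == [fam]

    def test_merge_fissions_counts_group_once(self, small_run):
        result, truth, _ = small_run
        # after merging, the fission genome's count in its family is 1
        fam_of = result.hierarchy.family_of()
        for group in result.fission_groups:
            fam_id = fam_of[group.fragment_loci[0]]
            fam = result.hierarchy.family(fam_id)
            assert fam.per_genome_count[group.genome_id] == 1


def test_pipeline_resolves_every_multicopy_genome(default_run):
    """Termination: after classification + merging + splitting, any genome
    still holding >1 merged copy of a family carries duplication records."""
    result, _, _ = default_run
    dup_keys = set()
    genome_of = result.hierarchy.genome_of
    fam_of = result.hierarchy.family_of()
    for ann in result.paralog_annotations:
        if ann.classification == DUPLICATION:
            dup_keys.add((fam_of[ann.locus_id], genome_of[ann.locus_id]))
    for fam in result.hierarchy.families:
        for genome, count in fam.per_genome_count.items():
            if count > 1:
                assert (fam.family_id, genome) in dup_keys


def test_recovered_dose_matches_truth(default_run):
    """Post-merge mean dose equals the truth-table copy number."""
    result, truth, _ = default_run
    truth_counts = {}
    for locus, (fam, event, group) in truth.events.items():
        key = fam
        truth_counts.setdefault(key, {})
    # copy number per (true family, genome): fission group counts once
    per = {}
    genome_of = result.hierarchy.genome_of
    for locus, (fam, event, group) in truth.events.items():
        g = genome_of[locus]
        key = (fam, g)
        if event == "fission_fragment":
            per.setdefault(key, set()).add(("fission", group))
        else:
            per.setdefault(key, set()).add(("locus", locus))
    fam_of = result.hierarchy.family_of()
    # map true family -> inferred family (memberships are identical here)
    true_to_inferred = {}
    for locus, (fam, _, _) in truth.events.items():
        true_to_inferred[fam] = fam_of[locus]
    for (true_fam, genome), units in per.items():
        inferred = result.hierarchy.family(true_to_inferred[true_fam])
        assert inferred.per_genome_count[genome] == len(units)
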