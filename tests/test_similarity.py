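"""Similarity graph: alignment oracle, normalization, expansion, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pangraphe._align import align_pair
from pangraphe.config import PipelineConfig
from pangraphe.dereplication import RepCluster
from pangraphe.similarity import (ScoreGraph, SimilarityHit, all_vs_all,
                                  filter_by_identity, normalize_and_expand)
from pangraphe.simulate import AA_FREQS, AMINO_ACIDS

from conftest import make_locus

CONFIG = PipelineConfig()


def _random_protein(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=AA_FREQS))


# ---------------------------------------------------------------------------
# brute-force affine-gap Smith-Waterman oracle (independent of Bio.Align)
# ---------------------------------------------------------------------------

def _sw_affine_score(a, b, open_pen=11, extend_pen=1):
    from Bio.Align import substitution_matrices
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_pen, E[i][j - 1] - extend_pen)
            F[i][j] = max(H[i - 1][j] - open_pen, F[i - 1][j] - extend_pen)
            diag = H[i - 1][j - 1] + blosum[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def test_alignment_scores_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        a = _random_protein(rng, int(rng.integers(30, 60)))
        b = _random_protein(rng, int(rng.integers(30, 60)))
        expected = _sw_affine_score(a, b)
        stats = align_pair(a, b, space="aa", mode="local")
        got = stats.raw_score if stats is not None else 0.0
        assert got == pytest.approx(expected)


class TestAllVsAll:
    def test_identical_pair(self):
        seq = "M" + "ACDEFGHIKLMNPQRSTVWY" * 5
        reps = [make_locus("a", aa_seq=seq), make_locus("b", aa_seq=seq)]
        hits = all_vs_all(reps, CONFIG)
        cross = [h for h in hits if h.query == "a" and h.subject == "b"]
        assert len(cross) == 1
        assert cross[0].pct_identity == pytest.approx(100.0)
        assert cross[0].query_coverage == pytest.approx(1.0)

    def test_unrelated_sequences_unreported(self):
        rng = np.random.default_rng(1)
        reps = [make_locus("a", aa_seq=_random_protein(rng, 100)),
                make_locus("b", aa_seq=_random_protein(rng, 100))]
        hits = all_vs_all(reps, CONFIG)
        assert all(h.query == h.subject for h in hits)  # self-hits only

    def test_self_hits_always_present(self):
        rng = np.random.default_rng(2)
        reps = [make_locus(f"s{i}", aa_seq=_random_protein(rng, 80))
                for i in range(4)]
        hits = all_vs_all(reps, CONFIG)
        selfs = {h.query for h in hits if h.query == h.subject}
        assert selfs == {"s0", "s1", "s2", "s3"}


def _hit(q, s, bit, ident=90.0, qcov=1.0, scov=1.0):
    return SimilarityHit(query=q, subject=s, bit_score=bit,
                         pct_identity=ident, query_coverage=qcov,
                         subject_coverage=scov)


def _singleton_clusters(*ids):
    return [RepCluster(rep_id=i) for i in ids]


class TestNormalizeAndExpand:
    def test_weight_is_bit_over_max_self(self):
        hits = [_hit("a", "a", 100), _hit("b", "b", 80), _hit("a", "b", 50)]
        graph = normalize_and_expand(hits, _singleton_clusters("a", "b"),
                                     CONFIG)
        assert graph.graph["a"]["b"]["weight"] == pytest.approx(0.5)

    def test_hsp_coverage_removes_edge(self):
        config = PipelineConfig(hsp_coverage=0.9)
        hits = [_hit("a", "a", 100), _hit("b", "b", 80),
                _hit("a", "b", 50, qcov=0.5), _hit("b", "a", 50, qcov=0.5)]
        graph = normalize_and_expand(hits, _singleton_clusters("a", "b"),
                                     config)
        assert not graph.graph.has_edge("a", "b")

    def test_member_expansion_inherits_edges(self):
        hits = [_hit("r", "r", 100), _hit("x", "x", 100), _hit("r", "x", 60)]
        clusters = [RepCluster(rep_id="r", member_ids={"r", "m1", "m2"},
                               identity_level=98.0),
                    RepCluster(rep_id="x")]
        graph = normalize_and_expand(hits, clusters, CONFIG)
        weights = [graph.graph["x"][m]["weight"] for m in ("r", "m1", "m2")]
        assert weights == pytest.approx([0.6, 0.6, 0.6])
        # members joined at 98% are linked at weight 1 with that identity
        assert graph.graph["m1"]["m2"]["weight"] == 1.0
        assert graph.graph["m1"]["m2"]["identity"] == 98.0

    def test_missing_self_hit_is_fatal(self):
        hits = [_hit("a", "a", 100), _hit("a", "b", 50)]
        with pytest.raises(RuntimeError, match="self-hit"):
            normalize_and_expand(hits, _singleton_clusters("a", "b"), CONFIG)


class TestFilterByIdentity:
    @staticmethod
    def _graph(identities):
        import networkx as nx
        g = nx.Graph()
        for i, ident in enumerate(identities):
            g.add_edge("hub", f"n{i}", weight=0.5, identity=ident,
                       coverage=1.0)
        return ScoreGraph(g)

    def test_boundary_is_inclusive(self):
        graph = self._graph([45.0, 50.0, 95.0])
        kept = filter_by_identity(graph, 50)
        idents = {d["identity"] for _, _, d in kept.graph.edges(data=True)}
        assert idents == {50.0, 95.0}

    def test_nodes_preserved_when_isolated(self):
        graph = self._graph([45.0])
        kept = filter_by_identity(graph, 100)
        assert kept.n_edges() == 0
        assert set(kept.graph.nodes) == {"hub", "n0"}

    @given(st.lists(st.floats(min_value=1, max_value=100), min_size=1,
                    max_size=12),
           st.integers(min_value=1, max_value=100),
           st.integers(min_value=1, max_value=100))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_edge_set_monotone_in_threshold(self, idents, t1, t2):
        lo, hi = sorted((t1, t2))
        graph = self._graph(idents)
        edges_hi = set(filter_by_identity(graph, hi).graph.edges)
        edges_lo = set(filter_by_identity(graph, lo).graph.edges)
        assert edges_hi <= edges_lo


def test_expanded_graph_symmetric_and_bounded(small_run):
    result, _, _ = small_run
    for a, b, data in result.score_graph.graph.edges(data=True):
        assert 0 < data["weight"] <= 1.0
        assert 0 <= data["identity"] <= 100.0
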