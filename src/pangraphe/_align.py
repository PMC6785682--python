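"""Exact pairwise alignment backend shared by the pipeline stages.

Wraps Bio.Align.PairwiseAligner (affine-gap Smith-Waterman / Needleman-Wunsch)
and adds bit-score scaling, identity/coverage bookkeeping and a k-mer
prescreen used to prune all-vs-all pair lists before exact alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import log

from Bio import Align
from Bio.Align import substitution_matrices

# Gapped Karlin-Altschul parameters: (lambda, K).
# BLOSUM62 with gap open 11 / extend 1; nucleotide +2/-3 with gap 5/2.
_KA_PARAMS = {"aa": (0.267, 0.041), "nt": (0.625, 0.41)}

_BLOSUM62_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


def sanitize_protein(seq: str) -> str:
    """Map residues outside the BLOSUM62 alphabet to X."""
    seq = seq.upper()
    if all(c in _BLOSUM62_ALPHABET for c in seq):
        return seq
    return "".join(c if c in _BLOSUM62_ALPHABET else "X" for c in seq)


@lru_cache(maxsize=8)
def make_aligner(space: str = "aa", mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if space == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    elif space == "nt":
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown sequence space {space!r}")
    return aligner


def bit_score(raw_score: float, space: str) -> float:
    lam, k = _KA_PARAMS[space]
    return (lam * raw_score - log(k)) / log(2.0)


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of the best local (or global) alignment of a pair."""

    raw_score: float
    bit_score: float
    pct_identity: float  # identities / ungapped aligned columns * 100
    query_coverage: float  # aligned query span / query length
    subject_coverage: float
    query_span: tuple[int, int]  # 0-based half-open on the query
    subject_span: tuple[int, int]


def align_pair(query: str, subject: str, space: str = "aa",
               mode: str = "local") -> AlignmentStats | None:
    """Align two sequences and summarise the single best alignment.

    Returns None when no alignment with positive score exists (local mode
    only). Identity is computed over the ungapped aligned columns, matching
    BLAST's pident semantics for the thresholds used downstream.
    """
    if not query or not subject:
        return None
    if space == "aa":
        query = sanitize_protein(query)
        subject = sanitize_protein(subject)
    aligner = make_aligner(space, mode)
    alignments = aligner.align(query, subject)
    score = alignments.score
    if mode == "local" and score <= 0:
        return None
    alignment = next(iter(alignments))
    q_blocks, s_blocks = alignment.aligned
    if len(q_blocks) == 0:
        return None
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        columns += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b)
    if columns == 0:
        return None
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    s_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return AlignmentStats(
        raw_score=float(score),
        bit_score=bit_score(float(score), space),
        pct_identity=100.0 * matches / columns,
        query_coverage=(q_span[1] - q_span[0]) / len(query),
        subject_coverage=(s_span[1] - s_span[0]) / len(subject),
        query_span=q_span,
        subject_span=s_span,
    )


def self_score(seq: str, space: str = "aa") -> float:
    """Raw score of a sequence aligned to itself (diagonal, no gaps)."""
    if space == "aa":
        seq = sanitize_protein(seq)
        matrix = substitution_matrices.load("BLOSUM62")
        return float(sum(matrix[c, c] for c in seq))
    return 2.0 * len(seq)


def kmer_set(seq: str, k: int = 4) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


class KmerIndex:
    """Inverted k-mer index for cheap candidate-pair screening.

    A pair of sequences sharing fewer than `min_shared` exact k-mers is
    extremely unlikely to align above ~50% identity over a meaningful span,
    so exact alignment is skipped for such pairs.
    """

    def __init__(self, k: int = 4, min_shared: int = 2) -> None:
        self.k = k
        self.min_shared = min_shared
        self._index: dict[str, list[str]] = {}
        self._rank: dict[str, int] = {}

    def add(self, seq_id: str, seq: str) -> None:
        self._rank[seq_id] = len(self._rank)
        for kmer in kmer_set(seq, self.k):
            self._index.setdefault(kmer, []).append(seq_id)

    def candidates(self, seq: str) -> list[str]:
        """Ids sharing at least min_shared k-mers with `seq`, insertion order."""
        counts: dict[str, int] = {}
        for kmer in kmer_set(seq, self.k):
            for other in self._index.get(kmer, ()):
                counts[other] = counts.get(other, 0) + 1
        hits = [sid for sid, n in counts.items() if n >= self.min_shared]
        hits.sort(key=self._rank.__getitem__)
        return hits

    def candidate_pairs(self) -> set[tuple[str, str]]:
        """All unordered pairs sharing >= min_shared k-mers."""
        counts: dict[tuple[str, str], int] = {}
        for members in self._index.values():
            if len(members) < 2:
                continue
            members = sorted(set(members))
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    counts[(a, b)] = counts.get((a, b), 0) + 1
        return {pair for pair, n in counts.items() if n >= self.min_shared}
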