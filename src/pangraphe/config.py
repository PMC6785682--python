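"""Run-wide configuration for the pangenome pipeline."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """Parameters shared by every stage of the pipeline.

    Attributes
    ----------
    thresholds:
        Ascending ladder of percent-identity values at which clustering is
        repeated. Families are defined at the lowest value; higher values
        resolve unique alleles.
    inflation:
        MCL inflation. 2 suits within-species data; larger values give finer
        clusters and suit inter-species comparisons.
    hsp_coverage:
        Minimum fraction of the query spanned by the best local alignment for
        a hit to be kept (0 disables the filter; 0.9 is a common strict value).
    feature_types:
        Annotation feature types analysed (CDS by default; tRNA/rRNA etc. are
        handled in nucleotide space).
    sequence_space:
        "aa" to compare translated CDS, "nt" to compare nucleotide sequences.
    core_fraction:
        A family is core when it occurs in strictly more than this fraction
        of genomes.
    dose_cutoff:
        Families whose mean merged copy number per containing genome exceeds
        this are flagged and excluded from divergence summaries.
    min_length:
        Minimum nucleotide length for a locus to enter the analysis.
    max_ambiguous_fraction:
        Loci with more than this fraction of ambiguous residues are dropped.
    derep_cascade:
        Identity levels (descending) for iterative greedy dereplication.
    length_cluster_identity:
        Length-similarity level used to group paralogous loci before overlap
        testing.
    overlap_significant:
        Minimum aligned fraction of the shorter locus for two loci to count
        as overlapping (duplicates overlap; fission fragments do not).
    fragment_overlap_tolerance:
        Maximum allowed mutual overlap, as a fraction of the shorter fragment,
        between fragments of one reconstructed fission locus.
    """

    thresholds: tuple[int, ...] = (50, 60, 70, 80, 90, 95)
    inflation: float = 2.0
    hsp_coverage: float = 0.0
    feature_types: frozenset[str] = frozenset({"CDS"})
    sequence_space: str = "aa"
    core_fraction: float = 0.95
    dose_cutoff: float = 1.25
    min_length: int = 120
    max_ambiguous_fraction: float = 0.05
    derep_cascade: tuple[int, ...] = (100, 98, 95)
    length_cluster_identity: float = 0.98
    overlap_significant: float = 0.50
    fragment_overlap_tolerance: float = 0.20

    def __post_init__(self) -> None:
        self.thresholds = tuple(int(t) for t in self.thresholds)
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly ascending")
        if not all(0 < t <= 100 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 100]")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if not 0.0 <= self.hsp_coverage <= 1.0:
            raise ValueError("hsp_coverage must lie in [0, 1]")
        if self.sequence_space not in ("aa", "nt"):
            raise ValueError("sequence_space must be 'aa' or 'nt'")
        self.feature_types = frozenset(self.feature_types)

    @property
    def base_threshold(self) -> int:
        return self.thresholds[0]

    def to_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "inflation": self.inflation,
            "hsp_coverage": self.hsp_coverage,
            "feature_types": sorted(self.feature_types),
            "sequence_space": self.sequence_space,
            "core_fraction": self.core_fraction,
            "dose_cutoff": self.dose_cutoff,
            "min_length": self.min_length,
            "max_ambiguous_fraction": self.max_ambiguous_fraction,
            "derep_cascade": list(self.derep_cascade),
            "length_cluster_identity": self.length_cluster_identity,
            "overlap_significant": self.overlap_significant,
            "fragment_overlap_tolerance": self.fragment_overlap_tolerance,
        }
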