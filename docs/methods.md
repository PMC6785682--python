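# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `pangraphe`. It is the package's own account of what it
computes; every empirical statement here is one the test suite or
`scripts/acceptance.py` computes.

## Scope and assumptions

The pipeline assumes a set of annotated bacterial genomes (GFF3 with
contig sequences) whose protein-coding features are comparable by
amino-acid similarity. It makes no phylogenetic assumptions: families are
defined purely by graph clustering of normalized alignment scores, and
divergence is reported relative to a user-chosen identity ladder, not a
tree. Non-CDS features (tRNA/rRNA) can be analysed in nucleotide space by
widening `feature_types`; the default analyses CDS in amino-acid space.

## Sequence filtering

The filter removes loci shorter than `min_length` (default 120 nt —
roughly the shortest annotated real genes), CDS whose translation contains
an internal stop (pseudogene/frameshift artefacts that would distort
alignment scores), and loci with more than `max_ambiguous_fraction` (5%)
ambiguous residues. These three rules and their thresholds are
config-exposed; they are pragmatic defaults, not a claim about any other
tool's internals. Retained ∪ excluded always equals the input (asserted in
tests), and each excluded locus carries a machine-readable reason code.

## Dereplication

Greedy incremental clustering in decreasing length order: a sequence joins
the first cluster whose representative it matches at ≥ the pass identity
over ≥80% of the shorter sequence (containment), else founds a cluster.
The cascade runs at 100, then 98, then 95% — conventional pre-clustering
steps, config-exposed — stopping above `max(base_threshold, 95)` so
dereplication can never collapse sequences the family clustering must
still distinguish. Identity is computed on the exact local alignment; a
best-infix edit-distance bound (edlib) rejects clear non-matches first,
with a 6-point slack so no true match at the clustering identities can be
screened out. Members of a composed cluster record the *minimum* identity
at which any member joined; inherited intra-cluster edges carry that
identity, so they survive every ladder rung up to 95.

## Similarity graph

Representative pairs sharing at least two exact 4-mers are aligned by
exact affine-gap local alignment (BLOSUM62, gap open 11 / extend 1;
nucleotide +2/−3, gap 5/2). Raw scores are converted to bits with the
standard Karlin–Altschul scaling (λ = 0.267, K = 0.041 for gapped
BLOSUM62-11/1; λ = 0.625, K = 0.41 for the nucleotide scheme). Percent
identity is computed over the ungapped aligned columns, and coverage as
the aligned span over sequence length.

Edge weight is `bit(a,b) / max(bit(a,a), bit(b,b))`, symmetrized by the
larger direction and capped at 1. Dividing by the larger self-score bounds
weights in (0, 1], is scale-free in sequence length, and makes the graph
insensitive to the Karlin–Altschul constants. Hits whose query coverage
falls below `hsp_coverage` (default 0; 0.9 for strict runs) are discarded
before symmetrization. Identity filtering at each ladder rung keeps edges
with identity ≥ the rung — the boundary is inclusive, so an edge at
exactly 50% survives the default base threshold.

## Markov clustering

MCL runs on a sparse column-stochastic matrix (memory proportional to
edges): expansion (matrix squaring), inflation (elementwise power, default
2, then column renormalization) and pruning of entries below 1e-5, until
the largest entry change falls below 1e-8 or 100 iterations. Self-loops
are set to each node's maximum incident weight (damps oscillation;
switchable to unit loops). Clusters are read from the converged matrix:
nodes retaining diagonal mass are attractors, attractors exchanging mass
form cluster cores, and every other node joins the core receiving the
largest share of its column mass — ties resolved toward the
lexicographically smallest core, so the partition is deterministic. The
implementation does not reproduce the `mcl` binary's adaptive k-best
pruning schedule; on planted clique-plus-weak-bridge graphs the partition
equals the planted structure (verified on 50 random graphs per run), and
clusters always refine connected components.

## Threshold hierarchy

Families are MCL clusters at the base rung, numbered `g0001…` by
descending genome count (ties: member count, then smallest locus id).
Higher rungs re-cluster each family's own identity-filtered subgraph,
within the previous rung's clusters. Running per family — rather than
globally — *guarantees* the nesting the hierarchy promises; global
re-clustering could violate it because MCL is not monotone under edge
deletion. Loci isolated at a rung become singleton alleles. An allele is
"unique" when its locus set has not appeared at any lower rung; the
family's `family_threshold` is the last rung at which the family is one
cluster, and each locus's divergence measure is the highest rung of a
unique allele containing it.

## Paralog classification

Within a flagged family (some genome holds >1 locus):

- Copies are grouped by greedy 98%-similarity clustering (longest first),
  so near-identical copies are overlap-tested once via a representative.
- Two copies "significantly overlap" when their best local alignment
  covers ≥50% of the shorter (`overlap_significant`). Duplicates overlap;
  fragments of a split gene do not. The 50% value separates the two
  regimes with a wide margin on clean annotations and is config-exposed.
- Per genome, copies lacking significant overlap with some co-genome copy
  are fission candidates. Each candidate is mapped onto the family's
  longest locus (the reference); the combination of ≥2 fragments
  maximizing union coverage of the reference, with pairwise
  reference-overlap ≤20% of the shorter fragment
  (`fragment_overlap_tolerance`, allowing slightly overlapping annotated
  ends), becomes a fission group. The search is exhaustive up to 4
  fragments and greedy by coverage gain beyond — real fission events
  rarely exceed 3 fragments. Ties prefer fewer fragments, then
  lexicographic ids.
- The search repeats on the remaining copies until no group is found; the
  remaining extra copies are duplications numbered in genomic order
  (contig, then start), the first copy being the unannotated canonical
  locus.

After classification each fission group counts as one locus. Families
still multi-copy are split at the first rung whose allele clusters hold at
most one merged locus per genome; children are named `g0001_1, g0001_2, …`
by descending genome count, and splitting conserves loci exactly. A family
whose duplicates persist at every rung is returned unchanged.

## Synteny and ordering

Adjacent retained loci on a contig link their families in a directed
graph; a pair lying wholly on the minus strand contributes its edge in
reading orientation, and a genome supports a given edge at most once.
Contig ends break adjacency (no circular wrap — circularity is unknowable
from GFF3), and self-edges (tandem arrays) are recorded but never chained.
Families with equal genome count are chained greedily along edges
supported by all of those genomes (highest support first, lexicographic
ties, cycles broken by dropping the edge that would close them); maximal
unbranched chains become blocks, emitted by descending genome count, then
length, then first family id. This operationalizes "parsimonious paths
between equal-count families" conservatively: only unanimous adjacencies
form blocks.

## Summaries

A family is core when present in strictly more than `core_fraction` (0.95)
of genomes. `dose` is the mean merged copy number per containing genome;
families with dose > 1.25 are flagged and excluded from divergence
summaries, since high-copy or residually over-clustered families are not
comparable. Reported percentages are recomputed from integer
numerator/denominator with half-up rounding at two decimals. The
core-vs-accessory divergence table carries a chi-square statistic (no
continuity correction), reported but never used to make a decision.

## Alignments

Per-family alignments use a deterministic center-star progressive scheme:
every sequence is aligned globally to the longest member and
center-relative insertions are merged. On the within-family divergences
the pipeline produces (alleles of one gene), its column identity is within
5 points of MAFFT's (cross-checked in the test suite; MAFFT is available
as an external adapter). The core alignment concatenates one
representative per genome — the longest locus, for dose-conformant core
families only — with gap runs for absent genomes, plus a partition table
mapping families to column ranges.

## Synthetic data

The simulator emulates descent from a shared ancestral repertoire:
ancestral proteins (length uniform 100–400 aa, residues from BLOSUM62
background frequencies, leading M), per-family alleles produced by
substituting random positions and accept-rejecting until the realized
minimum pairwise identity lies within ±2.5 points of the target (±3 is the
declared tolerance), synonymous back-translation under table 11,
presence/absence sampling, duplications inserted at random order
positions, fissions splitting a CDS at codon boundaries into separately
annotated fragments with a 30-nt disruption, optional inversion of order
windows, and 100-nt random spacers between genes. Output is byte-identical
under a fixed seed.

What it does **not** emulate: realistic codon usage, intergenic content,
recombination, insertion sequences, annotation errors, or contig
fragmentation. Passing recovery tests therefore demonstrates correctness
of the clustering and classification machinery under controlled
divergence, not robustness to real-world annotation noise.

## Problem sizes and test design

The standard fixture is 20 genomes × 50 families (~910 loci; identity
targets 60/80/95/99%, every fifth family accessory at 50% presence, five
duplications, five fissions). At this size the whole pipeline runs in
about a minute on one CPU, which lets the suite run it once and reuse the
result across recovery, nesting, conservation and determinism checks.
Unit tests use smaller purpose-built inputs. MCL fidelity uses 50 random
planted-clique graphs of ≤40 nodes, where the intended partition is known
by construction.

## Determinism and parallelism

Every stage is deterministic: node orderings are sorted, all tie-breaks
are lexicographic, and the only randomness (the simulator's) is seeded.
Worker threads partition sorted task lists and results are merged in task
order, so outputs are identical for any thread count (verified
byte-for-byte for 1 vs 4). The run manifest records timings, which are the
one intentionally non-reproducible output; result tables are compared
byte-for-byte across reruns.

## Known limitations

- Allele identity inside dereplication clusters is recorded at the
  cluster's minimum join level (≥95), so ladders extending above 95%
  (e.g. 91–99 by 1) slightly under-resolve alleles that dereplication
  merged; disable the 98/95 cascade levels for dense high-identity
  ladders.
- The fission search scores fragments against a single reference (the
  family's longest locus); genes whose full-length form is absent from
  the sample can yield partial reference coverage.
- Center-star alignment is adequate for congeneric alleles but inferior
  to MAFFT for deeply divergent families; use the adapter when alignment
  quality matters downstream.
- BLAST/DIAMOND-style acceleration is out of scope; the exact aligner
  with a k-mer prescreen targets desk-scale datasets (tens of genomes),
  not thousands.
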