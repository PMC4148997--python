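# Methods

## Scope and model

This package implements the genome-comparison core of a taxonogenomic
species description: given draft bacterial assemblies, it quantifies
genome relatedness as the **Average Genomic Identity of Orthologous gene
Sequences (AGIOS)** — the unweighted arithmetic mean, over the one-to-one
orthologous gene pairs of two genomes, of the percent nucleotide identity
of their globally aligned coding sequences — and places strains in a 16S
rRNA phylogeny with neighbor-joining and bootstrap support. A synthetic
genome-evolution generator supplies inputs with known ground truth so that
every stage is testable without external downloads.

## Pairwise alignment

Alignment is Needleman–Wunsch (global) with affine gaps: a run of k gap
columns costs `gap_open + k·gap_extend`. End gaps are penalized (true
global alignment). Defaults follow the de-facto conventions for global
alignment: DNA match/mismatch +5/−4, protein BLOSUM62, gap open 10,
gap extend 0.5. The original description of the statistic names the
algorithm but not its parameters, so these defaults are declared package
decisions, exposed in `ScoringScheme`.

Identity is counted over **all** alignment columns: gap columns sit in the
denominator and never match, and `N`/`X` columns never match (so an
all-`N` pair has identity 0, and `N`s in a draft assembly can only lower,
never raise, reported identity). The alternative aligned-columns-only
denominator is available via `identity_percent(..., denominator="aligned")`.

Numerics: the DP keeps three state matrices (match, gap-in-a, gap-in-b);
the gap-in-a state is computed with a prefix-max scan so whole rows
vectorize, and a batched score-only sweep aligns one query against a
stack of targets at once (used by the all-vs-all ortholog search). Among
co-optimal moves the traceback prefers diagonal over up over left, making
the emitted alignment deterministic; equality of candidate scores is
tested with an absolute tolerance of 1e−6 so user-supplied float
penalties cannot strand the traceback.

## Orthology

Orthologs are one-to-one reciprocal best hits (RBH) on exact global
protein alignment scores — no heuristic pre-filter, so the search is
deterministic at desk scale. A best hit is retained only if its alignment
has ≥ 25% identity and covers ≥ 50% of the shorter protein
(residue-to-residue columns); the thresholds are configurable and the
best-scoring candidate is checked against them without fallback to the
next-best. Ties on score break to the lexicographically smallest target
gene id. Because global scores are symmetric the A×B score matrix is
computed once and reused transposed for the reverse direction. Paralog
clusters, many-to-many groups and synteny are out of scope.

AGIOS then re-aligns each mapped pair at the **nucleotide** level
(strand-corrected CDSs, stop codon included) — proteins find the
orthologs, genes measure the identity. The per-pair mean is unweighted; a
`length_weighted=True` switch records the alternative. Self-comparison is
defined and equals exactly 100. A pair with zero orthologs is an error
("no orthologs"), never a 0 — the statistic is undefined there, and the
multi-genome matrix renders such cells with a marker instead.

The comparison matrix mirrors the conventional report layout: diagonal =
protein-coding gene counts, upper triangle = shared ortholog counts,
lower triangle = mean identities to 2 decimals.

## Genome statistics and ORF calling

Genome statistics count `N` in total length but never as G+C; coding
length is the union of feature intervals (overlaps counted once — the
convention is not fixed by published annotation tables, so the union was
adopted and documented). Coordinates are 0-based half-open internally and
1-based inclusive in GFF3 I/O.

The ORF caller is a deterministic rule, not a scored gene finder: in each
of the six frames, an ORF runs from the first start codon (ATG/GTG/TTG)
after the previous stop to the next in-frame stop, stop included, with a
300 nt default minimum. It exists so the pipeline runs end-to-end on
genomes where the true genes are planted; on real genomes a trained gene
finder will outperform it.

## Phylogeny

Distances from a supplied multiple alignment default to the p-distance
with pairwise deletion of gap/`N` columns (the common default for
distance trees in MEGA-style workflows); Jukes–Cantor and Kimura
two-parameter corrections are available. Neighbor joining is the
Saitou–Nei agglomeration with the standard Q criterion; ties break to the
smallest (i, j) index pair in the working matrix, and a negative branch
estimate is clamped to zero with the deficit moved to its sister so the
cherry still sums to its distance. NJ is exact on additive matrices,
which the tests verify against a least-squares fit over all quartet
topologies. Two taxa bisect their distance; three taxa get the closed-form
star. Trees are dendropy objects, serialized as newick with bootstrap
supports as internal node labels.

Bootstrap resamples alignment columns with replacement (seeded generator,
no global state; the seed is a required argument), rebuilds the NJ tree
per replicate, and reports for each internal edge of the full-data tree
the percentage of replicates containing the same bipartition. An
alignment whose distance matrix is all zeros has nothing to resolve and
raises "no resolved bipartitions".

The 16S species rule follows the 98.7% identity threshold: two unaligned
sequences are globally aligned at DNA defaults, and identity strictly
below the threshold yields the "candidate new species" verdict (the
threshold itself is inclusive on the same-species side).

## Synthetic data generator

`simulate_genome` plants `n_genes` genes (default 50 × 900 nt, the scale
used throughout the validation suite) of ATG + non-stop codons + TAA,
separated by 100 nt random spacers, on one contig. `evolve_genome`
derives a descendant: every site (start/stop codons included) substitutes
independently with probability `q_sub` to a uniformly drawn different
base, and whole genes are lost with probability `gene_loss` (deleted from
the contig). Substitution is applied once per site — no multi-hit — so
the expected ortholog identity is exactly `100·(1−q)`. When substitution
leaves an in-frame stop before a gene's final codon, only the substituted
bases of that codon are redrawn while the substitution mask is held
fixed; this keeps the number of substituted sites, hence the expectation,
exact rather than conditioning it upward (redraw events are counted in
the ground truth). Realized per-gene identity is recorded and equals the
observed hamming identity.

The marker simulator is different by design: along each branch of length
t, sites substitute with probability `(3/4)(1 − e^(−4qt/3))` — the true
Jukes–Cantor transition probability, which composes correctly along paths
and saturates at 3/4 — so p-distances from simulated alignments follow
the closed-form expectation and NJ recovers the generating topology at
realistic lengths.

What the generator does **not** emulate: indels within genes, codon-usage
bias, rearrangement, horizontal transfer, multi-hit substitution in
genome pairs, and assembly artifacts (chimeras, collapsed repeats).
Passing recovery tests therefore demonstrates correctness of the
statistics and the pipeline plumbing under the stated model, not
robustness to real-data pathologies.

## Validation problem sizes

The validation suite runs entirely on simulated data at the scales above:
alignment optimality is checked against exhaustive enumeration of every
global alignment for ~10⁴ sampled pairs of length ≤ 7 over a 3-letter
alphabet (enumeration is vectorized over precomputed lattice-path
tables); substitution-rate recovery uses 50-gene × 900 nt genomes at
q ∈ {0.05, 0.15, 0.30} with three seeds each (|mean AGIOS − 100(1−q)|
stays within 1 percentage point; the ~+0.1–0.3 pp residual at high q is
gap-harvesting by the optimal alignment, not generator bias); NJ
exactness uses 50 random additive quartets at 1e−9 tolerance; bootstrap
sanity uses a 5-taxon, 2,000-column simulated alignment at 100
replicates. Statistics of the deposited EB02^T draft assembly (EMBL
CBYO000000000) are asserted in a test that reads the assembly from
`data/reference/` — the file is fetched separately (see the README there)
because a 4 Mb assembly does not belong in a source tree.

## Known limitations

- The ORF caller has no ribosome-binding or GC-frame model; it
  over-predicts on minus strands of real genes and under-predicts genes
  with non-canonical starts.
- RBH with exact all-vs-all alignment is O(n²) alignments per genome
  pair; it is meant for desk-scale analyses (thousands of genes work,
  but a heuristic search tool is faster for routine use).
- p-distance NJ underestimates divergence at saturation; use the jc69 or
  k2p corrections beyond ~20% divergence.
- The AGIOS parameterization (gap costs, identity denominator, unweighted
  mean) is declared, not inferred from the original software; values are
  reproducible under this declaration and the switches record the
  alternatives.
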