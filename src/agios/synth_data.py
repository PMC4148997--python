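"""Synthetic genome and marker-gene evolution with known ground truth.

The generator plants ``n_genes`` protein-coding genes (ATG … TAA, no
internal in-frame stop) separated by random intergenic spacers on a single
contig, then derives descendants by per-site substitution (probability
``q_sub`` per site, to a uniformly chosen different base) and per-gene
loss (probability ``gene_loss``).  Substitution is applied once per site,
so the expected nucleotide identity between orthologous genes is
100·(1−q) — a sharp target for recovery tests.  Every site of a gene is
mutable, start and stop codons included; substituted bases that leave an
in-frame stop before the final codon are redrawn holding the substitution
mask fixed (events counted), so the number of substituted sites — and with
it the 100·(1−q) expectation — is exact.  The realized per-gene identity
is recorded as ground truth.

Marker (16S-like) alignments are evolved along a given tree under the
Jukes–Cantor model: along a branch of length t each site substitutes with
probability (3/4)(1 − e^(−4qt/3)), which composes correctly along paths
(multi-hit saturation included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genome_io import Contig, GeneFeature, Genome
from .orf_caller import STOP_CODONS, translate
from .phylo16s import MultipleAlignment

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_genome",
    "evolve_genome",
    "evolve_marker_along_tree",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    n_genes: int = 50
    gene_len_nt: int = 900
    intergenic_len_nt: int = 100
    q_sub: float = 0.0
    gene_loss: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be ≥ 0")
        if self.gene_len_nt % 3 or self.gene_len_nt < 9:
            raise ValueError("gene_len_nt must be divisible by 3 and ≥ 9")
        if self.intergenic_len_nt < 1:
            raise ValueError("intergenic_len_nt must be ≥ 1")
        if not (0 <= self.q_sub < 1) or not (0 <= self.gene_loss < 1):
            raise ValueError("q_sub and gene_loss must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator knows: ortholog pairing and realized divergence."""

    pairs: dict[str, str] = field(default_factory=dict)
    realized_identity: dict[str, float] = field(default_factory=dict)
    n_repair_events: int = 0
    tree: dendropy.Tree | None = None


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n codons uniform over the 61 non-stop codons (rejection sampling)."""
    out = []
    while len(out) < n:
        codon = "".join(_BASES[b] for b in rng.integers(0, 4, size=3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[b] for b in rng.integers(0, 4, size=n))


def simulate_genome(params: SimParams, genome_id: str = "ancestor") -> tuple[Genome, GroundTruth]:
    """Ancestral gene-bearing genome: alternating spacers and genes.

    Contig length is ``n_genes·gene_len + (n_genes+1)·intergenic_len``.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(params.seed)
    parts = [_random_dna(rng, params.intergenic_len_nt)]
    features = []
    pos = params.intergenic_len_nt
    contig_id = f"{genome_id}_c1"
    for g in range(params.n_genes):
        body = _random_codons(rng, params.gene_len_nt // 3 - 2)
        gene = "ATG" + body + "TAA"
        gene_id = f"g{g + 1:04d}"
        features.append(
            GeneFeature(gene_id, contig_id, pos, pos + params.gene_len_nt, "+",
                        product=translate(gene))
        )
        parts.append(gene)
        parts.append(_random_dna(rng, params.intergenic_len_nt))
        pos += params.gene_len_nt + params.intergenic_len_nt
    genome = Genome(id=genome_id, contigs=[Contig(contig_id, "".join(parts))],
                    features=features)
    truth = GroundTruth(pairs={f.gene_id: f.gene_id for f in features},
                        realized_identity={f.gene_id: 100.0 for f in features})
    return genome, truth


def _mutate(rng: np.random.Generator, seq: str, q: float) -> str:
    """Each site substituted with probability q to a uniform different base."""
    if q == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = np.zeros(arr.shape, dtype=np.int8)
    for i, base in enumerate(_BASES):
        codes[arr == ord(base)] = i
    hit = rng.random(len(seq)) < q
    shifts = rng.integers(1, 4, size=len(seq))
    codes[hit] = (codes[hit] + shifts[hit]) % 4
    return "".join(_BASES[c] for c in codes)


def _evolve_gene(rng: np.random.Generator, gene: str, q: float) -> tuple[str, int]:
    """Mutate a gene site-wise, redrawing codons that become internal stops.

    The substitution mask (which sites are hit) is drawn once and kept;
    when a codon before the final position lands on a stop, only the
    substituted bases of that codon are redrawn (again to a base different
    from the ancestral one) until the codon is not a stop.  The number of
    substituted sites — hence the expected identity 100·(1−q) — is
    therefore exact, not merely approximate.  A codon with no substituted
    site cannot be a stop (its ancestor was not), and with ≥1 substituted
    site a non-stop redraw always exists, so the loop terminates.
    """
    codes = np.fromiter((_BASES.index(c) for c in gene), dtype=np.int8, count=len(gene))
    hit = rng.random(len(gene)) < q
    mutated = codes.copy()
    mutated[hit] = (mutated[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    last = len(gene) - 3  # final codon: stops allowed there
    repairs = 0
    for i in range(0, last, 3):
        codon = "".join(_BASES[b] for b in mutated[i : i + 3])
        sites = [i + k for k in range(3) if hit[i + k]]
        while codon in STOP_CODONS:
            repairs += 1
            for s in sites:
                mutated[s] = (codes[s] + rng.integers(1, 4)) % 4
            codon = "".join(_BASES[b] for b in mutated[i : i + 3])
    return "".join(_BASES[b] for b in mutated), repairs


def evolve_genome(
    genome: Genome,
    q_sub: float,
    gene_loss: float,
    seed: int,
    descendant_id: str | None = None,
) -> tuple[Genome, GroundTruth]:
    """Derive a descendant genome by substitution and gene loss.

    Retained genes keep their gene ids (the ortholog pairing is the
    identity map on retained ids); lost genes are deleted from the contig.
    Intergenic sequence is substituted without constraint.  Requires an
    annotated genome with non-overlapping features.
    """
    if not (0 <= q_sub < 1) or not (0 <= gene_loss < 1):
        raise ValueError("q_sub and gene_loss must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    desc_id = descendant_id or f"{genome.id}_desc"
    truth = GroundTruth()
    new_contigs = []
    new_features = []
    for contig in genome.contigs:
        feats = sorted(
            (f for f in genome.features if f.contig_id == contig.id),
            key=lambda f: f.start,
        )
        new_contig_id = contig.id.replace(genome.id, desc_id, 1) if contig.id.startswith(genome.id) else f"{desc_id}_{contig.id}"
        parts = []
        cursor = 0
        pos = 0
        for f in feats:
            spacer = _mutate(rng, contig.sequence[cursor : f.start], q_sub)
            parts.append(spacer)
            pos += len(spacer)
            cursor = f.end
            gene = contig.sequence[f.start : f.end]
            oriented = gene if f.strand == "+" else _revcomp(gene)
            lost = rng.random() < gene_loss
            evolved_oriented, repairs = _evolve_gene(rng, oriented, q_sub)
            if lost:
                continue
            truth.n_repair_events += repairs
            matches = sum(x == y for x, y in zip(oriented, evolved_oriented))
            truth.realized_identity[f.gene_id] = 100.0 * matches / len(oriented)
            truth.pairs[f.gene_id] = f.gene_id
            evolved = evolved_oriented if f.strand == "+" else _revcomp(evolved_oriented)
            new_features.append(
                GeneFeature(f.gene_id, new_contig_id, pos, pos + len(evolved), f.strand,
                            product=translate(evolved_oriented))
            )
            parts.append(evolved)
            pos += len(evolved)
        parts.append(_mutate(rng, contig.sequence[cursor:], q_sub))
        new_contigs.append(Contig(new_contig_id, "".join(parts)))
    descendant = Genome(id=desc_id, contigs=new_contigs, features=new_features)
    return descendant, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def evolve_marker_along_tree(
    tree: dendropy.Tree, seq_len: int, q_per_unit_length: float, seed: int
) -> tuple[MultipleAlignment, dendropy.Tree]:
    """Evolve a gap-free marker alignment along *tree* under Jukes–Cantor.

    The root sequence is uniform over ACGT; along each branch of length t
    each site substitutes with probability (3/4)(1 − e^(−4qt/3)) to a
    uniformly chosen different base.  Returns the leaf alignment (taxa in
    leaf-iteration order) together with the generating tree.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be ≥ 1")
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    states: dict[int, np.ndarray] = {id(root): rng.integers(0, 4, size=seq_len)}
    taxa, rows = [], []
    for node in tree.preorder_node_iter():
        if node is root:
            seq = states[id(root)]
        else:
            t = node.edge.length if node.edge.length is not None else 0.0
            if t < 0:
                raise ValueError("negative branch length")
            p = 0.75 * (1.0 - math.exp(-4.0 * q_per_unit_length * t / 3.0))
            parent_seq = states[id(node.parent_node)]
            seq = parent_seq.copy()
            hit = rng.random(seq_len) < p
            shifts = rng.integers(1, 4, size=seq_len)
            seq[hit] = (seq[hit] + shifts[hit]) % 4
            states[id(node)] = seq
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or f"leaf{len(taxa)}")
            taxa.append(label)
            rows.append("".join(_BASES[b] for b in seq))
    return MultipleAlignment(tuple(taxa), tuple(rows)), tree
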