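"""Reciprocal-best-hit (RBH) ortholog detection between two annotated genomes.

Orthologs are detected at the protein level: every protein of genome A is
globally aligned against every protein of genome B (exact affine NW, no
heuristic pre-filter), each protein's best-scoring partner is recorded, and
a pair is an ortholog iff the choice is mutual.  The best hit is kept only
if it passes identity and coverage thresholds.  One-to-one by construction;
paralog clusters are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .genome_io import Genome, cds_sequence
from .orf_caller import translate
from .pairwise_align import PROTEIN_SCHEME, ScoringScheme, nw_align, nw_score_batch

__all__ = ["OrthologPair", "OrthologMap", "best_hits", "rbh_orthologs", "proteome"]

DEFAULT_MIN_IDENTITY = 25.0  # percent, over all alignment columns
DEFAULT_MIN_COVERAGE = 0.5  # fraction of the shorter sequence aligned residue-to-residue


class OrthologPair(NamedTuple):
    gene_a: str
    gene_b: str
    protein_score: float
    protein_identity: float


@dataclass
class OrthologMap:
    genome_a_id: str
    genome_b_id: str
    pairs: list[OrthologPair]
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE

    def __post_init__(self) -> None:
        seen_a = {p.gene_a for p in self.pairs}
        seen_b = {p.gene_b for p in self.pairs}
        if len(seen_a) != len(self.pairs) or len(seen_b) != len(self.pairs):
            raise ValueError("ortholog map is not one-to-one")
        self.pairs = sorted(self.pairs, key=lambda p: p.gene_a)

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return {p.gene_a: p.gene_b for p in self.pairs}


def proteome(genome: Genome) -> dict[str, str]:
    """Gene id → protein sequence, translating CDSs where no product is stored."""
    if not genome.features:
        raise ValueError(f"no genes in genome {genome.id}")
    prots: dict[str, str] = {}
    for f in genome.features:
        prots[f.gene_id] = f.product if f.product else translate(cds_sequence(genome, f))
    return prots


def _score_matrix(
    prots_a: dict[str, str], prots_b: dict[str, str], scheme: ScoringScheme
) -> tuple[list[str], list[str], np.ndarray]:
    ids_a, ids_b = list(prots_a), list(prots_b)
    seqs_b = [prots_b[g] for g in ids_b]
    scores = np.empty((len(ids_a), len(ids_b)))
    for i, ga in enumerate(ids_a):
        scores[i] = nw_score_batch(prots_a[ga], seqs_b, scheme)
    return ids_a, ids_b, scores


def _passes_thresholds(
    seq_a: str, seq_b: str, scheme: ScoringScheme, min_identity: float, min_coverage: float
) -> tuple[bool, float, float]:
    res = nw_align(seq_a, seq_b, scheme)
    aligned_cols = res.n_columns - res.n_gap_columns
    coverage = aligned_cols / min(len(seq_a), len(seq_b))
    ok = res.identity_percent >= min_identity and coverage >= min_coverage
    return ok, res.score, res.identity_percent


def best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    scheme: ScoringScheme = PROTEIN_SCHEME,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, tuple[str, float, float]]:
    """Best-hit table a→b: gene_a → (gene_b, score, identity_percent).

    For each protein in A the best-scoring B protein is selected (ties
    broken by lexicographically smallest B gene id) and retained only if
    its alignment passes the identity and coverage thresholds.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    ids_a, ids_b, scores = _score_matrix(proteome_a, proteome_b, scheme)
    return _hits_from_matrix(
        ids_a, ids_b, scores, proteome_a, proteome_b, scheme, min_identity, min_coverage
    )


def _hits_from_matrix(
    ids_a, ids_b, scores, proteome_a, proteome_b, scheme, min_identity, min_coverage
) -> dict[str, tuple[str, float, float]]:
    hits: dict[str, tuple[str, float, float]] = {}
    for i, ga in enumerate(ids_a):
        row = scores[i]
        top = row.max()
        gb = min(ids_b[j] for j in np.flatnonzero(row == top))
        ok, score, identity = _passes_thresholds(
            proteome_a[ga], proteome_b[gb], scheme, min_identity, min_coverage
        )
        if ok:
            hits[ga] = (gb, score, identity)
    return hits


def rbh_orthologs(
    genome_a: Genome,
    genome_b: Genome,
    scheme: ScoringScheme = PROTEIN_SCHEME,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> OrthologMap:
    """One-to-one orthologs between two genomes by reciprocal best hit.

    The A×B score matrix is computed once; because global alignment scores
    are symmetric, the B→A best hits are read off its transpose.
    """
    prots_a, prots_b = proteome(genome_a), proteome(genome_b)
    ids_a, ids_b, scores = _score_matrix(prots_a, prots_b, scheme)
    ab = _hits_from_matrix(
        ids_a, ids_b, scores, prots_a, prots_b, scheme, min_identity, min_coverage
    )
    ba = _hits_from_matrix(
        ids_b, ids_a, scores.T, prots_b, prots_a, scheme, min_identity, min_coverage
    )
    pairs = [
        OrthologPair(ga, gb, score, identity)
        for ga, (gb, score, identity) in ab.items()
        if ba.get(gb, (None,))[0] == ga
    ]
    return OrthologMap(
        genome_a_id=genome_a.id,
        genome_b_id=genome_b.id,
        pairs=pairs,
        min_identity=min_identity,
        min_coverage=min_coverage,
    )
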