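"""16S rRNA comparison: pairwise identity, distance matrices, neighbor-joining
with bootstrap support, and the 98.7% species-delineation threshold.

Distances default to the p-distance (proportion of differing sites among
comparable columns, with pairwise deletion of gap/N columns); Jukes–Cantor
and Kimura two-parameter corrections are available.  Neighbor joining is
the Saitou–Nei agglomeration with the standard Q criterion; it is exact on
additive matrices.  Bootstrap support of an internal edge is the percentage
of column-resampled replicates whose NJ tree contains the same bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import dendropy
import numpy as np
from Bio import SeqIO

from .pairwise_align import DNA_SCHEME, nw_align

__all__ = [
    "SPECIES_THRESHOLD_PERCENT",
    "MultipleAlignment",
    "DistanceMatrix",
    "Identity16S",
    "pairwise_identity_16s",
    "p_distance_matrix",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "read_alignment_fasta",
]

#: 16S rRNA identity below which a strain is a candidate new species
#: without DNA-DNA hybridization (Stackebrandt & Ebers threshold).
SPECIES_THRESHOLD_PERCENT = 98.7

VERDICT_NEW_SPECIES = "candidate new species"
VERDICT_SAME_SPECIES = "same-species range"

_GAPLIKE = set("-N")


@dataclass(frozen=True)
class MultipleAlignment:
    """Aligned sequences: equal-length rows over {A,C,G,T,N,-}."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2 or len(self.taxa) != len(self.rows):
            raise ValueError("need ≥2 taxa with one row each")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, columns: np.ndarray) -> "MultipleAlignment":
        rows = tuple("".join(row[c] for c in columns) for row in self.rows)
        return MultipleAlignment(self.taxa, rows)


def read_alignment_fasta(path) -> MultipleAlignment:
    taxa, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        taxa.append(record.id)
        rows.append(str(record.seq).upper())
    return MultipleAlignment(tuple(taxa), tuple(rows))


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if np.any(d < 0) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("invalid distances")


class Identity16S(NamedTuple):
    identity_percent: float
    verdict: str


def pairwise_identity_16s(seq_a: str, seq_b: str) -> Identity16S:
    """Global-alignment identity of two unaligned 16S sequences, with the
    species-delineation verdict (identity ≥ 98.7% → same-species range)."""
    if not seq_a or not seq_b:
        raise ValueError("empty input")
    result = nw_align(seq_a, seq_b, DNA_SCHEME)
    identity = result.identity_percent
    verdict = (
        VERDICT_SAME_SPECIES
        if identity >= SPECIES_THRESHOLD_PERCENT
        else VERDICT_NEW_SPECIES
    )
    return Identity16S(identity, verdict)


def _pairwise_p(row_a: str, row_b: str) -> tuple[float, float, int]:
    """(mismatch fraction, transition fraction, n comparable columns)."""
    purines = {"A", "G"}
    n_comp = n_diff = n_ts = 0
    for x, y in zip(row_a, row_b):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        n_comp += 1
        if x != y:
            n_diff += 1
            if (x in purines) == (y in purines):
                n_ts += 1
    if n_comp == 0:
        raise ValueError("no overlap")
    return n_diff / n_comp, n_ts / n_comp, n_comp


def distance_matrix(msa: MultipleAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/N columns.

    Models: ``p`` (raw proportion), ``jc69`` (−3/4·ln(1−4p/3)),
    ``k2p`` (Kimura 1980, separate transition/transversion fractions).
    """
    n = len(msa.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, ts, _ = _pairwise_p(msa.rows[i], msa.rows[j])
            if model == "p":
                dist = p
            elif model == "jc69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0:
                    raise ValueError("jc69 distance undefined (p ≥ 0.75)")
                dist = -0.75 * math.log(arg)
            elif model == "k2p":
                tv = p - ts
                a1, a2 = 1.0 - 2.0 * ts - tv, 1.0 - 2.0 * tv
                if a1 <= 0 or a2 <= 0:
                    raise ValueError("k2p distance undefined")
                dist = -0.5 * math.log(a1) - 0.25 * math.log(a2)
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(msa.taxa, d)


def p_distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    return distance_matrix(msa, model="p")


def neighbor_joining(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; unrooted dendropy tree.

    Joins minimize the Q criterion, ties broken by the smallest (i, j)
    index pair in the current working matrix (row-major); negative branch
    length estimates are clamped to zero with the deficit moved to the
    sister edge so the pair still sums to its distance.
    """
    taxa = dm.taxa
    n = len(taxa)
    if n < 2:
        raise ValueError("need ≥2 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(list(taxa))
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=t)) for t in taxa]
    D = dm.d.astype(float).copy()

    def _join(i: int, j: int, li: float, lj: float) -> None:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes[i] = parent

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major argmin = smallest (i, j) tie-break
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        _join(i, j, li, lj)
        del nodes[j]

    center = dendropy.Node()
    if len(nodes) == 2:
        half = 0.5 * D[0, 1]
        lengths = [half, half]
    else:
        lengths = [
            max(0.0, 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])),
            max(0.0, 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])),
            max(0.0, 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])),
        ]
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def _internal_bipartitions(tree: dendropy.Tree) -> dict[int, dendropy.Edge]:
    tree.encode_bipartitions()
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.head_node.is_leaf():
            continue
        out[edge.bipartition.split_bitmask] = edge
    return out


def bootstrap_support(
    msa: MultipleAlignment, n_reps: int, seed: int, model: str = "p"
) -> dendropy.Tree:
    """NJ tree of *msa* with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate (seeded, hence
    deterministic); the support of each internal edge of the full-data
    tree is the percentage of replicate trees containing its bipartition,
    stored as the integer node label and as ``node.support``.
    """
    if n_reps < 1:
        raise ValueError("invalid replicate count")
    full_dm = distance_matrix(msa, model=model)
    tns = dendropy.TaxonNamespace(list(msa.taxa))
    full_tree = neighbor_joining(full_dm, taxon_namespace=tns)
    edges = _internal_bipartitions(full_tree)
    if not edges or all(
        (e.length or 0.0) == 0.0 for e in edges.values()
    ) and np.all(full_dm.d == 0):
        raise ValueError("no resolved bipartitions")
    counts = dict.fromkeys(edges, 0)
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, msa.n_columns, size=msa.n_columns)
        rep_tree = neighbor_joining(
            distance_matrix(msa.resample_columns(cols), model=model),
            taxon_namespace=tns,
        )
        rep_masks = set(_internal_bipartitions(rep_tree))
        for mask in counts:
            if mask in rep_masks:
                counts[mask] += 1
    for mask, edge in edges.items():
        support = round(100.0 * counts[mask] / n_reps)
        edge.head_node.label = str(support)
        edge.head_node.support = support
    return full_tree
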