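"""The AGIOS statistic and the multi-genome comparison report.

AGIOS (Average Genomic Identity of Orthologous gene Sequences) between two
genomes is the unweighted arithmetic mean, over their one-to-one ortholog
pairs, of the percent nucleotide identity of the globally aligned gene
sequences.  Orthologs are found at the protein level (reciprocal best hit)
and identity is measured at the nucleotide level on the strand-corrected
CDSs.  The multi-genome matrix follows the conventional layout: diagonal =
protein-coding gene counts, upper triangle = shared ortholog counts, lower
triangle = mean identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Genome, cds_sequence, genome_stats
from .orthology import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    OrthologMap,
    rbh_orthologs,
)
from .pairwise_align import DNA_SCHEME, PROTEIN_SCHEME, ScoringScheme, nw_align

__all__ = ["AgiosResult", "AgiosMatrix", "agios_pair", "agios_matrix", "build_report"]

NO_ORTHOLOG_MARKER = "no orthologs"


@dataclass(frozen=True)
class AgiosResult:
    genome_a_id: str
    genome_b_id: str
    n_orthologs: int
    mean_identity: float
    identities: tuple[float, ...]


def agios_pair(
    genome_a: Genome,
    genome_b: Genome,
    orthomap: OrthologMap | None = None,
    dna_scheme: ScoringScheme = DNA_SCHEME,
    protein_scheme: ScoringScheme = PROTEIN_SCHEME,
    length_weighted: bool = False,
) -> AgiosResult:
    """Mean nucleotide identity over the ortholog pairs of two genomes.

    If *orthomap* is not supplied it is computed by reciprocal best hit.
    Each mapped gene pair is resolved to its strand-corrected nucleotide
    CDS and globally aligned; the mean of the per-pair identity percents
    is the AGIOS value.  ``length_weighted=True`` weights each pair by its
    alignment column count instead.
    """
    if orthomap is None:
        orthomap = rbh_orthologs(genome_a, genome_b, scheme=protein_scheme)
    if len(orthomap) == 0:
        raise ValueError("no orthologs")
    feats_a = {f.gene_id: f for f in genome_a.features}
    feats_b = {f.gene_id: f for f in genome_b.features}
    identities = []
    weights = []
    for pair in orthomap.pairs:
        cds_a = cds_sequence(genome_a, feats_a[pair.gene_a])
        cds_b = cds_sequence(genome_b, feats_b[pair.gene_b])
        res = nw_align(cds_a, cds_b, dna_scheme)
        identities.append(res.identity_percent)
        weights.append(res.n_columns)
    if length_weighted:
        mean = float(np.average(identities, weights=weights))
    else:
        mean = float(np.mean(identities))
    return AgiosResult(
        genome_a_id=genome_a.id,
        genome_b_id=genome_b.id,
        n_orthologs=len(identities),
        mean_identity=mean,
        identities=tuple(identities),
    )


@dataclass
class AgiosMatrix:
    """Pairwise comparison table.

    ``gene_counts[i]`` sits on the diagonal; ``shared[i][j]`` (i<j) is the
    ortholog count of the pair; ``identity[i][j]`` (i>j) the mean percent
    identity, reported to 2 decimals.  Cells of pairs with no orthologs
    carry ``None`` and render as a marker.
    """

    genome_ids: list[str]
    gene_counts: list[int]
    shared: dict[tuple[int, int], int | None]
    identity: dict[tuple[int, int], float | None]

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.genome_ids)
        cells: list[list[object]] = [["" for _ in range(n)] for _ in range(n)]
        for i in range(n):
            cells[i][i] = self.gene_counts[i]
            for j in range(i + 1, n):
                shared = self.shared[(i, j)]
                ident = self.identity[(j, i)]
                cells[i][j] = shared if shared is not None else NO_ORTHOLOG_MARKER
                cells[j][i] = (
                    f"{ident:.2f}" if ident is not None else NO_ORTHOLOG_MARKER
                )
        return pd.DataFrame(cells, index=self.genome_ids, columns=self.genome_ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def agios_matrix(
    genomes: list[Genome],
    dna_scheme: ScoringScheme = DNA_SCHEME,
    protein_scheme: ScoringScheme = PROTEIN_SCHEME,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> AgiosMatrix:
    """All-pairs AGIOS comparison of ≥2 annotated genomes."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate id")
    shared: dict[tuple[int, int], int | None] = {}
    identity: dict[tuple[int, int], float | None] = {}
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            if not genomes[i].features or not genomes[j].features:
                shared[(i, j)] = None
                identity[(j, i)] = None
                continue
            orthomap = rbh_orthologs(
                genomes[i],
                genomes[j],
                scheme=protein_scheme,
                min_identity=min_identity,
                min_coverage=min_coverage,
            )
            if len(orthomap) == 0:
                shared[(i, j)] = None
                identity[(j, i)] = None
                continue
            result = agios_pair(genomes[i], genomes[j], orthomap, dna_scheme=dna_scheme)
            shared[(i, j)] = result.n_orthologs
            identity[(j, i)] = round(result.mean_identity, 2)
    return AgiosMatrix(
        genome_ids=ids,
        gene_counts=[g.n_genes for g in genomes],
        shared=shared,
        identity=identity,
    )


def build_report(genomes: list[Genome], matrix: AgiosMatrix | None = None) -> str:
    """Text comparison report: per-genome rows plus the AGIOS matrix.

    Rows carry genome size in Mb (2 decimals), G+C percent (1 decimal)
    and protein-coding gene count.
    """
    lines = ["genome\tsize_Mb\tgc_percent\tn_genes"]
    for g in genomes:
        stats = genome_stats(g)
        lines.append(
            f"{g.id}\t{stats.total_bp / 1e6:.2f}\t{stats.gc_percent:.1f}\t{g.n_genes}"
        )
    if matrix is None and len(genomes) >= 2 and all(g.features for g in genomes):
        matrix = agios_matrix(genomes)
    if matrix is not None:
        lines.append("")
        lines.append(
            "# diagonal: gene counts; upper: shared orthologs; lower: mean identity (%)"
        )
        lines.append(matrix.to_dataframe().to_csv(sep="\t").rstrip("\n"))
    return "\n".join(lines) + "\n"
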