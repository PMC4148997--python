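"""Genome containers, FASTA/GFF3 I/O and assembly-level statistics.

A :class:`Genome` is an ordered set of contigs (uppercase DNA over
``{A,C,G,T,N}``) with optional gene features.  Coordinates are 0-based
half-open internally; GFF3 input/output uses the standard 1-based
inclusive convention.  Ambiguous IUPAC nucleotide codes are mapped to
``N`` on read: ``N`` counts toward genome length but never toward G+C,
so a genome of 4,006,766 bp with 1,442,326 G+C bases reports 36% G+C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "GeneFeature",
    "Genome",
    "GenomeStats",
    "read_fasta",
    "write_fasta",
    "read_gff_genes",
    "write_gff_genes",
    "genome_stats",
    "cds_sequence",
]

logger = logging.getLogger(__name__)

_VALID_ALPHABET = set("ACGTN")
# Ambiguity codes (and U) silently degraded to N; anything else is an error.
_IUPAC_TO_N = set("RYSWKMBDHVU")

FASTA_LINE_WIDTH = 70


class Contig(NamedTuple):
    id: str
    sequence: str


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene on a contig, 0-based half-open, stop included."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """Named, ordered collection of contigs with optional gene features."""

    id: str
    contigs: list[Contig]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for contig in self.contigs:
            if contig.id in seen:
                raise ValueError(f"duplicate contig id: {contig.id}")
            seen.add(contig.id)
            if not contig.sequence:
                raise ValueError(f"contig {contig.id}: empty sequence")
            bad = set(contig.sequence) - _VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"invalid alphabet in contig {contig.id}: {sorted(bad)}"
                )

    def contig_sequence(self, contig_id: str) -> str:
        for contig in self.contigs:
            if contig.id == contig_id:
                return contig.sequence
        raise KeyError(contig_id)

    @property
    def n_genes(self) -> int:
        return len(self.features)


def _normalize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _VALID_ALPHABET
    mapped = bad & _IUPAC_TO_N
    if mapped:
        logger.warning(
            "contig %s: mapping ambiguous IUPAC codes %s to N",
            record_id,
            "".join(sorted(mapped)),
        )
        seq = seq.translate(str.maketrans({c: "N" for c in mapped}))
        bad -= mapped
    if bad:
        raise ValueError(f"invalid alphabet in record {record_id}: {sorted(bad)}")
    return seq


def read_fasta(path, genome_id: str | None = None) -> Genome:
    """Read a multi-FASTA nucleotide file into a :class:`Genome`.

    Sequences are uppercased; ambiguous IUPAC codes become ``N`` (with a
    logged warning); any other character raises ``invalid alphabet``.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate contig id: {record.id}")
        seen.add(record.id)
        contigs.append(Contig(record.id, _normalize_sequence(str(record.seq), record.id)))
    if not contigs:
        raise ValueError(f"no records in {path}")
    name = genome_id if genome_id is not None else _stem(path)
    return Genome(id=name, contigs=contigs)


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base


def write_fasta(genome_or_records, path, width: int = FASTA_LINE_WIDTH) -> None:
    """Write a Genome (or iterable of ``(id, sequence)``) as wrapped FASTA."""
    if isinstance(genome_or_records, Genome):
        items: Iterable[tuple[str, str]] = (
            (c.id, c.sequence) for c in genome_or_records.contigs
        )
    else:
        items = genome_or_records
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_gff_genes(path, genome: Genome, feature_types: tuple[str, ...] = ("CDS", "gene")) -> Genome:
    """Attach gene features from a GFF3 subset to *genome*.

    Only columns 1 (seqid), 3 (type), 4/5 (1-based inclusive coordinates)
    and 7 (strand) are honored.  Returns a new Genome sharing contigs.
    """
    lengths = {c.id: len(c.sequence) for c in genome.contigs}
    features: list[GeneFeature] = []
    counter = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{lineno}: expected ≥8 GFF3 columns")
            seqid, _source, ftype, start_s, end_s, _score, strand = cols[:7]
            if ftype not in feature_types:
                continue
            if seqid not in lengths:
                raise ValueError(f"{path}:{lineno}: unmapped feature (unknown contig {seqid})")
            start1, end1 = int(start_s), int(end_s)
            start, end = start1 - 1, end1  # to 0-based half-open
            if not (0 <= start < end <= lengths[seqid]):
                raise ValueError(
                    f"{path}:{lineno}: feature out of bounds ({start1}..{end1} on {seqid})"
                )
            gene_id = _gff_attribute_id(cols[8] if len(cols) > 8 else "")
            if gene_id is None:
                counter += 1
                gene_id = f"{seqid}_gene{counter:04d}"
            features.append(GeneFeature(gene_id, seqid, start, end, strand))
    return Genome(id=genome.id, contigs=genome.contigs, features=features)


def _gff_attribute_id(attributes: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
    return None


def write_gff_genes(genome: Genome, path) -> None:
    """Write features as GFF3 (1-based inclusive, CDS rows)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for f in genome.features:
            handle.write(
                "\t".join(
                    [
                        f.contig_id,
                        "agios",
                        "CDS",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        f"ID={f.gene_id}",
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class GenomeStats:
    total_bp: int
    gc_bp: int
    gc_percent: float
    n_contigs: int
    min_contig_bp: int
    max_contig_bp: int
    mean_contig_bp: float
    coding_bp: int
    coding_percent: float


def genome_stats(genome: Genome) -> GenomeStats:
    """Assembly-level statistics: length, G+C, contig sizes, coding fraction.

    ``N`` counts in ``total_bp`` but never as G+C.  ``coding_bp`` is the
    length of the union of feature intervals, so overlapping or duplicated
    features are counted once.
    """
    lengths = [len(c.sequence) for c in genome.contigs]
    total = sum(lengths)
    gc = sum(c.sequence.count("G") + c.sequence.count("C") for c in genome.contigs)
    coding = _interval_union_length(genome.features)
    return GenomeStats(
        total_bp=total,
        gc_bp=gc,
        gc_percent=100.0 * gc / total,
        n_contigs=len(lengths),
        min_contig_bp=min(lengths),
        max_contig_bp=max(lengths),
        mean_contig_bp=total / len(lengths),
        coding_bp=coding,
        coding_percent=100.0 * coding / total,
    )


def _interval_union_length(features: Iterable[GeneFeature]) -> int:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_contig.setdefault(f.contig_id, []).append((f.start, f.end))
    total = 0
    for intervals in by_contig.values():
        intervals.sort()
        cur_start, cur_end = intervals[0]
        for start, end in intervals[1:]:
            if start > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        total += cur_end - cur_start
    return total


def cds_sequence(genome: Genome, feature: GeneFeature) -> str:
    """Strand-corrected nucleotide sequence of a gene (stop codon included)."""
    seq = genome.contig_sequence(feature.contig_id)[feature.start : feature.end]
    if feature.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
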