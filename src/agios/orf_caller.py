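"""Six-frame maximal-ORF prediction and translation (bacterial code, table 11).

A deterministic gene caller: on each contig and each of the six reading
frames, an ORF runs from the first start codon after the previous stop to
the next in-frame stop (stop codon included in the coordinates).  This is
a rule-based stand-in for a scored gene finder, adequate for genomes where
the true genes are planted by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import GeneFeature, Genome

__all__ = ["OrfParams", "find_orfs", "translate"]

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_FORWARD = dict(_TABLE11.forward_table)
STOP_CODONS = frozenset(_TABLE11.stop_codons)  # TAA, TAG, TGA
DEFAULT_STARTS = frozenset({"ATG", "GTG", "TTG"})


@dataclass(frozen=True)
class OrfParams:
    min_len_nt: int = 300
    start_codons: frozenset[str] = DEFAULT_STARTS
    require_stop: bool = True

    def __post_init__(self) -> None:
        if self.min_len_nt < 6 or self.min_len_nt % 3:
            raise ValueError("min_len_nt must be ≥ 6 and divisible by 3")


def translate(dna: str) -> str:
    """Translate a CDS with the bacterial genetic code.

    GTG/TTG at position 0 become M; a trailing stop codon is dropped; an
    internal stop raises ``premature stop``; any codon containing N yields X.
    """
    if len(dna) % 3:
        raise ValueError("frame error: length not divisible by 3")
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons.pop()
    out = []
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"premature stop at codon {idx}")
        if "N" in codon:
            out.append("X")
        elif idx == 0 and codon in DEFAULT_STARTS:
            out.append("M")
        else:
            out.append(_FORWARD[codon])
    return "".join(out)


def _scan_frame(seq: str, frame: int, params: OrfParams) -> list[tuple[int, int]]:
    """Maximal ORFs (start, end) in one forward frame of *seq*."""
    orfs = []
    pending: int | None = None
    last_full = frame + 3 * ((len(seq) - frame) // 3)
    for pos in range(frame, last_full, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if pending is not None and pos + 3 - pending >= params.min_len_nt:
                orfs.append((pending, pos + 3))
            pending = None
        elif pending is None and codon in params.start_codons:
            pending = pos
    if pending is not None and not params.require_stop:
        if last_full - pending >= params.min_len_nt:
            orfs.append((pending, last_full))
    return orfs


def find_orfs(genome: Genome, params: OrfParams = OrfParams()) -> list[GeneFeature]:
    """Predict ORFs in all six frames of every contig.

    Minus-strand ORFs are reported in forward-contig coordinates with
    strand ``-``; output is sorted by (contig, start, strand) and gene ids
    are assigned in that order.  Deterministic.
    """
    raw: list[tuple[int, int, int, str]] = []  # (contig_idx, start, end, strand)
    for ci, contig in enumerate(genome.contigs):
        length = len(contig.sequence)
        rc = str(Seq(contig.sequence).reverse_complement())
        for frame in range(3):
            for start, end in _scan_frame(contig.sequence, frame, params):
                raw.append((ci, start, end, "+"))
            for start, end in _scan_frame(rc, frame, params):
                raw.append((ci, length - end, length - start, "-"))
    raw.sort(key=lambda t: (t[0], t[1], t[3]))
    features = []
    for n, (ci, start, end, strand) in enumerate(raw, 1):
        contig = genome.contigs[ci]
        oriented = contig.sequence[start:end]
        if strand == "-":
            oriented = str(Seq(oriented).reverse_complement())
        features.append(
            GeneFeature(
                gene_id=f"{contig.id}_orf{n:04d}",
                contig_id=contig.id,
                start=start,
                end=end,
                strand=strand,
                product=translate(oriented),
            )
        )
    return features
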