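"""Needleman–Wunsch global alignment with affine gap penalties.

This is the computational core of the ortholog-identity statistic: every
ortholog pair is globally aligned at the nucleotide level and scored as
percent identity over all alignment columns (terminal gaps included in
the denominator; ``N``/``X`` columns are never matches).

Cost model: a gap of k columns costs ``gap_open + k * gap_extend``.  The
dynamic program keeps three states (match, gap-in-b, gap-in-a); among
co-optimal moves the traceback prefers diagonal over up over left, so the
emitted alignment is deterministic.  Defaults follow the de-facto global
alignment conventions: DNA +5/−4 with 10/0.5 gaps, protein BLOSUM62 with
10/0.5 gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "nw_align",
    "nw_score",
    "nw_score_batch",
    "identity_percent",
]

_NEG = -1e30  # effectively -inf, avoids inf arithmetic
_TOL = 1e-6

_DNA_ALPHABET = "ACGTN"
_DNA_INDEX = {c: i for i, c in enumerate(_DNA_ALPHABET)}


@lru_cache(maxsize=None)
def _blosum(name: str) -> tuple[str, np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load(name)
    alphabet = "".join(c for c in mat.alphabet if c != "*")
    index = {c: i for i, c in enumerate(alphabet)}
    arr = np.empty((len(alphabet), len(alphabet)))
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            arr[i, j] = mat[a, b]
    return alphabet, arr, index


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment parameters for DNA or protein mode.

    ``gap_open`` is charged once per gap run and ``gap_extend`` once per
    gap column, so a single-column gap costs ``gap_open + gap_extend``.
    """

    mode: str = "dna"
    match: float = 5.0
    mismatch: float = -4.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("dna", "protein"):
            raise ValueError("mode must be 'dna' or 'protein'")
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open ≥ gap_extend ≥ 0")

    def _tables(self) -> tuple[dict[str, int], np.ndarray, str]:
        if self.mode == "dna":
            n = len(_DNA_ALPHABET)
            sub = np.full((n, n), self.mismatch)
            for i in range(4):  # N never matches anything, including N
                sub[i, i] = self.match
            return _DNA_INDEX, sub, "N"
        alphabet, sub, index = _blosum(self.matrix_name)
        return index, sub, "X"

    def encode(self, seq: str) -> np.ndarray:
        index, _, _ = self._tables()
        try:
            return np.fromiter((index[c] for c in seq), dtype=np.intp, count=len(seq))
        except KeyError as exc:
            raise ValueError(f"alphabet error: {exc.args[0]!r} not valid in {self.mode} mode")


PROTEIN_SCHEME = ScoringScheme(mode="protein")
DNA_SCHEME = ScoringScheme(mode="dna")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    n_columns: int
    n_matches: int
    n_gap_columns: int
    identity_percent: float


def _fill(ea: np.ndarray, eb: np.ndarray, sub: np.ndarray, go: float, ge: float):
    """Forward pass; returns the three (n+1)x(m+1) state matrices."""
    n, m = len(ea), len(eb)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in b: consume a ("up")
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in a: consume b ("left")
    M[0, 0] = 0.0
    cols = np.arange(1, m + 1)
    Iy[0, 1:] = -go - cols * ge
    rows = np.arange(1, n + 1)
    Ix[1:, 0] = -go - rows * ge
    k_ge = np.arange(m + 1) * ge
    for i in range(1, n + 1):
        srow = sub[ea[i - 1], eb]
        prev_best = np.maximum(M[i - 1], np.maximum(Ix[i - 1], Iy[i - 1]))
        M[i, 1:] = prev_best[:-1] + srow
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) - go - ge, Ix[i - 1, 1:] - ge
        )
        # Iy[i,j] = max_{k<j} (max(M,Ix)[i,k] - go - (j-k) ge): prefix-max scan
        best_here = np.maximum(M[i], Ix[i])
        acc = np.maximum.accumulate(best_here + k_ge)
        Iy[i, 1:] = acc[:-1] - go - cols * ge
    return M, Ix, Iy


def _traceback(a: str, b: str, M, Ix, Iy, sub, ea, eb, go: float, ge: float):
    i, j = len(a), len(b)
    finals = (M[i, j], Ix[i, j], Iy[i, j])
    top = max(finals)
    state = next(s for s, v in enumerate(finals) if v >= top - _TOL)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # diagonal
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            cands = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            i, j = i - 1, j - 1
        elif state == 1:  # up: a[i-1] vs gap
            out_a.append(a[i - 1])
            out_b.append("-")
            cands = (M[i - 1, j] - go - ge, Ix[i - 1, j] - ge, Iy[i - 1, j] - go - ge)
            i -= 1
        else:  # left: gap vs b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            cands = (M[i, j - 1] - go - ge, Ix[i, j - 1] - go - ge, Iy[i, j - 1] - ge)
            j -= 1
        if i == 0 and j == 0:
            break
        best = max(cands)
        state = next(s for s, v in enumerate(cands) if v >= best - _TOL)
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _count_stats(aligned_a: str, aligned_b: str, wildcard: str) -> tuple[int, int, int]:
    n_cols = len(aligned_a)
    n_matches = 0
    n_gap_cols = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            n_gap_cols += 1
        elif x == y and x != wildcard:
            n_matches += 1
    return n_cols, n_matches, n_gap_cols


def nw_align(a: str, b: str, scheme: ScoringScheme = DNA_SCHEME) -> AlignmentResult:
    """Optimal global alignment of *a* and *b* under *scheme*.

    Raises ``empty input`` for an empty sequence and ``alphabet error``
    for characters outside the scheme's alphabet.
    """
    if not a or not b:
        raise ValueError("empty input")
    _, sub, wildcard = scheme._tables()
    ea, eb = scheme.encode(a), scheme.encode(b)
    M, Ix, Iy = _fill(ea, eb, sub, scheme.gap_open, scheme.gap_extend)
    score = float(max(M[-1, -1], Ix[-1, -1], Iy[-1, -1]))
    aligned_a, aligned_b = _traceback(
        a, b, M, Ix, Iy, sub, ea, eb, scheme.gap_open, scheme.gap_extend
    )
    n_cols, n_matches, n_gap_cols = _count_stats(aligned_a, aligned_b, wildcard)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        n_columns=n_cols,
        n_matches=n_matches,
        n_gap_columns=n_gap_cols,
        identity_percent=100.0 * n_matches / n_cols,
    )


def nw_score(a: str, b: str, scheme: ScoringScheme = DNA_SCHEME) -> float:
    """Optimal global alignment score only (no traceback)."""
    return nw_score_batch(a, [b], scheme)[0]


def nw_score_batch(a: str, bs: list[str], scheme: ScoringScheme = DNA_SCHEME) -> np.ndarray:
    """Scores of *a* against each sequence in *bs*, in one vectorized sweep.

    All DP rows for the batch advance together; sequences shorter than the
    longest are read out at their own final column, which the left-to-right
    recurrences never contaminate from padded columns.
    """
    if not a or not bs or any(not b for b in bs):
        raise ValueError("empty input")
    _, sub, _ = scheme._tables()
    go, ge = scheme.gap_open, scheme.gap_extend
    ea = scheme.encode(a)
    ebs = [scheme.encode(b) for b in bs]
    lens = np.array([len(b) for b in bs])
    m = int(lens.max())
    k = len(bs)
    eb = np.zeros((k, m), dtype=np.intp)  # padding index 0; never read out
    for r, e in enumerate(ebs):
        eb[r, : len(e)] = e
    n = len(a)
    M = np.full((k, m + 1), _NEG)
    Ix = np.full((k, m + 1), _NEG)
    Iy = np.full((k, m + 1), _NEG)
    M[:, 0] = 0.0
    cols = np.arange(1, m + 1)
    Iy[:, 1:] = -go - cols * ge
    k_ge = np.arange(m + 1) * ge
    out = np.empty(k)
    for i in range(1, n + 1):
        srow = sub[ea[i - 1]][eb]  # (k, m)
        prev_best = np.maximum(M, np.maximum(Ix, Iy))
        newM = np.full_like(M, _NEG)
        newM[:, 1:] = prev_best[:, :-1] + srow
        newIx = np.empty_like(Ix)
        newIx[:, 0] = -go - i * ge
        newIx[:, 1:] = np.maximum(np.maximum(M[:, 1:], Iy[:, 1:]) - go - ge, Ix[:, 1:] - ge)
        best_here = np.maximum(newM, newIx)
        acc = np.maximum.accumulate(best_here + k_ge, axis=1)
        newIy = np.full_like(Iy, _NEG)
        newIy[:, 1:] = acc[:, :-1] - go - cols * ge
        M, Ix, Iy = newM, newIx, newIy
    final = np.maximum(M, np.maximum(Ix, Iy))
    out[:] = final[np.arange(k), lens]
    return out


def identity_percent(result: AlignmentResult, denominator: str = "all") -> float:
    """Percent identity of an alignment.

    ``denominator="all"`` (default) counts every alignment column,
    terminal gaps included; ``"aligned"`` counts only columns where both
    sequences have a residue.
    """
    if result.n_columns == 0:
        raise ValueError("empty alignment")
    if denominator == "all":
        return 100.0 * result.n_matches / result.n_columns
    if denominator == "aligned":
        n_aligned = result.n_columns - result.n_gap_columns
        if n_aligned == 0:
            raise ValueError("empty alignment")
        return 100.0 * result.n_matches / n_aligned
    raise ValueError("denominator must be 'all' or 'aligned'")
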