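"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and
agglomeration code paths: alignment scores come from exhaustive
enumeration of every global alignment (as lattice paths), and quartet
trees from a least-squares fit of all three possible topologies.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------- alignment

@lru_cache(maxsize=None)
def _path_tables(la: int, lb: int):
    """All monotone lattice paths from (0,0) to (la,lb).

    Returns (I, J, W, runs, cols): per path, the (i, j) coordinates of its
    diagonal steps (padded, with W the validity mask), its number of gap
    runs and its number of gap columns.  Gap cost is sequence-independent,
    so a path's score is its substitution sum minus runs·open + cols·extend.
    """
    diag_steps: list[list[tuple[int, int]]] = []
    gap_info: list[tuple[int, int]] = []

    def rec(i: int, j: int, ops: list[tuple[str, int, int]]) -> None:
        if i == la and j == lb:
            diag = [(a, b) for (op, a, b) in ops if op == "D"]
            runs = cols = 0
            prev = ""
            for op, _, _ in ops:
                if op != "D":
                    cols += 1
                    if op != prev:
                        runs += 1
                prev = op
            diag_steps.append(diag)
            gap_info.append((runs, cols))
            return
        if i < la:
            rec(i + 1, j, ops + [("U", i, j)])
        if j < lb:
            rec(i, j + 1, ops + [("L", i, j)])
        if i < la and j < lb:
            rec(i + 1, j + 1, ops + [("D", i, j)])

    rec(0, 0, [])
    n_paths = len(diag_steps)
    width = max((len(d) for d in diag_steps), default=0)
    I = np.zeros((n_paths, max(width, 1)), dtype=np.int8)
    J = np.zeros_like(I)
    W = np.zeros(I.shape, dtype=bool)
    for p, diag in enumerate(diag_steps):
        for t, (a, b) in enumerate(diag):
            I[p, t], J[p, t], W[p, t] = a, b, True
    runs = np.array([r for r, _ in gap_info])
    cols = np.array([c for _, c in gap_info])
    return I, J, W, runs, cols


def brute_force_nw_score(
    a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> float:
    """Optimal global score by scoring every alignment path explicitly."""
    I, J, W, runs, cols = _path_tables(len(a), len(b))
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(ea[I] == eb[J], match, mismatch) * W
    scores = sub.sum(axis=1) - runs * gap_open - cols * gap_extend
    return float(scores.max())


# ------------------------------------------------------------------ quartets

QUARTET_TOPOLOGIES = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def least_squares_quartet(D: np.ndarray):
    """Best-fit quartet: least-squares branch lengths for each of the three
    topologies, returning (winning split, lengths[5], residual sum of squares).

    ``lengths[:4]`` are the leaf edges in taxon order, ``lengths[4]`` the
    internal edge.  On an additive matrix the winning topology fits exactly.
    """
    pairs = list(itertools.combinations(range(4), 2))
    best = None
    for split in QUARTET_TOPOLOGIES:
        A = np.zeros((6, 5))
        y = np.zeros(6)
        for r, (i, j) in enumerate(pairs):
            y[r] = D[i, j]
            A[r, i] = A[r, j] = 1
            same_side = {i, j} in (set(split[0]), set(split[1]))
            if not same_side:
                A[r, 4] = 1
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ x - y) ** 2).sum())
        if best is None or rss < best[2]:
            best = (split, x, rss)
    return best


def random_additive_quartet(rng: np.random.Generator):
    """A random quartet tree and its (exactly additive) distance matrix.

    Returns (split, lengths[5], D) with leaf edges in taxon order.
    """
    split = QUARTET_TOPOLOGIES[rng.integers(0, 3)]
    lengths = rng.uniform(0.1, 2.0, size=5)
    D = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        d = lengths[i] + lengths[j]
        if {i, j} not in (set(split[0]), set(split[1])):
            d += lengths[4]
        D[i, j] = D[j, i] = d
    return split, lengths, D
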