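"""Independent brute-force oracles used to check the implementation.

The alignment oracle is a full-matrix Waterman–Smith–Beyer dynamic program
with an explicit scan over every gap length (cost ``gap_open + k *
gap_extend`` for a gap of length k). It shares no code or recurrence
shortcuts with the package's alignment engine.
"""

from __future__ import annotations

import numpy as np


def _score_table(matrix, a: str, b: str) -> np.ndarray:
    return np.array([[matrix.score(x, y) for y in b] for x in a], dtype=float)


def global_score_oracle(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal end-to-end alignment score by exhaustive gap-length scan."""
    n, m = len(a), len(b)
    S = _score_table(matrix, a, b)
    M = np.full((n + 1, m + 1), -np.inf)
    M[0, 0] = 0.0
    gap = gap_open + gap_extend * np.arange(1, max(n, m) + 1)
    for i in range(n + 1):
        for j in range(m + 1):
            best = M[i, j]
            if i > 0 and j > 0:
                best = max(best, M[i - 1, j - 1] + S[i - 1, j - 1])
            if i > 0:
                best = max(best, float(np.max(M[:i, j] - gap[:i][::-1])))
            if j > 0:
                best = max(best, float(np.max(M[i, :j] - gap[:j][::-1])))
            M[i, j] = best
    return float(M[n, m])


def local_score_oracle(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score by exhaustive gap-length scan."""
    n, m = len(a), len(b)
    S = _score_table(matrix, a, b)
    L = np.zeros((n + 1, m + 1))
    gap = gap_open + gap_extend * np.arange(1, max(n, m) + 1)
    best_all = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = L[i - 1, j - 1] + S[i - 1, j - 1]
            best = max(best, float(np.max(L[:i, j] - gap[:i][::-1])))
            best = max(best, float(np.max(L[i, :j] - gap[:j][::-1])))
            L[i, j] = max(0.0, best)
            best_all = max(best_all, L[i, j])
    return float(best_all)


def enumerate_short_local_alignments(a: str, b: str, matrix, max_len: int = 3) -> float:
    """Best score over all gap-free sub-alignments of length <= max_len."""
    best = 0.0
    for la in range(1, max_len + 1):
        for i in range(len(a) - la + 1):
            for j in range(len(b) - la + 1):
                s = sum(matrix.score(a[i + k], b[j + k]) for k in range(la))
                best = max(best, s)
    return best


def p_distance_oracle(row_a: str, row_b: str) -> float:
    """Mismatch fraction over mutually ungapped columns (column-by-column)."""
    comparable = mismatch = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            comparable += 1
            if x != y:
                mismatch += 1
    if comparable == 0:
        raise ValueError("no comparable columns")
    return mismatch / comparable


def surviving_columns_oracle(rows: list[str], max_gap_fraction: float, min_block_length: int):
    """Per-column recount of the conserved-block trimming rule."""
    n_cols = len(rows[0])
    survive = []
    for j in range(n_cols):
        gaps = sum(1 for r in rows if r[j] == "-")
        survive.append(gaps / len(rows) <= max_gap_fraction)
    keep = []
    run = []
    for j in range(n_cols + 1):
        if j < n_cols and survive[j]:
            run.append(j)
        else:
            if len(run) >= min_block_length:
                keep.extend(run)
            run = []
    return keep


def random_protein(rng: np.random.Generator, length: int) -> str:
    from sterolscan.core_io import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
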