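"""Brute-force oracles, independent of the library's alignment/clustering code."""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = -1e12


def blosum(a: str, b: str) -> float:
    return float(_BLOSUM62[a][b])


def sw_score(a: str, b: str, sub=blosum, gap_open: float = -11.0, gap_extend: float = -1.0) -> float:
    """Smith–Waterman local alignment score with affine gaps (Gotoh).

    Gap of length L costs gap_open + (L-1)*gap_extend, matching the
    convention where the opening residue carries the open score.
    """
    n, m = len(a), len(b)
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), NEG)
    f = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i, j] = max(e[i, j - 1] + gap_extend, h[i, j - 1] + gap_open)
            f[i, j] = max(f[i - 1, j] + gap_extend, h[i - 1, j] + gap_open)
            h[i, j] = max(0.0, h[i - 1, j - 1] + sub(a[i - 1], b[j - 1]), e[i, j], f[i, j])
            best = max(best, h[i, j])
    return best


def nw_score(a: str, b: str, sub=blosum, gap_open: float = -11.0, gap_extend: float = -1.0) -> float:
    """Needleman–Wunsch global score with affine gaps, terminal gaps penalized."""
    n, m = len(a), len(b)
    h = np.full((n + 1, m + 1), NEG)
    e = np.full((n + 1, m + 1), NEG)
    f = np.full((n + 1, m + 1), NEG)
    h[0, 0] = 0.0
    for j in range(1, m + 1):
        e[0, j] = gap_open + (j - 1) * gap_extend
        h[0, j] = e[0, j]
    for i in range(1, n + 1):
        f[i, 0] = gap_open + (i - 1) * gap_extend
        h[i, 0] = f[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i, j] = max(e[i, j - 1] + gap_extend, h[i, j - 1] + gap_open)
            f[i, j] = max(f[i - 1, j] + gap_extend, h[i - 1, j] + gap_open)
            h[i, j] = max(h[i - 1, j - 1] + sub(a[i - 1], b[j - 1]), e[i, j], f[i, j])
    return float(h[n, m])


def complete_linkage_merges(data: np.ndarray, labels: list[str]) -> list[tuple[frozenset, float]]:
    """O(n^3) complete-linkage agglomeration; returns (merged leaf set, height) steps."""
    clusters: list[set[str]] = [{lab} for lab in labels]
    points = {lab: data[i] for i, lab in enumerate(labels)}

    def dist(c1: set[str], c2: set[str]) -> float:
        return max(
            float(np.sqrt(((points[x] - points[y]) ** 2).sum())) for x in c1 for y in c2
        )

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                key = (d, sorted(clusters[i])[0], sorted(clusters[j])[0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        merges.append((frozenset(merged), d))
    return merges
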