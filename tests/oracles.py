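"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive: exhaustive scans and plain-Python
dynamic programming, sharing no code path with the package internals.
"""
from __future__ import annotations

import numpy as np


def exhaustive_alignment(read: np.ndarray, genome: np.ndarray):
    """All-positions, both-strand Hamming scan of one read over one genome.

    Returns (best_mm, best_start, best_strand, second_mm) where loci are
    (strand, start) pairs and second_mm is over distinct loci.
    """
    L = len(read)
    rc = (3 - read[::-1]).astype(np.uint8)
    entries = []
    for strand, oriented in ((0, read), (1, rc)):
        for s in range(0, len(genome) - L + 1):
            mm = int(np.count_nonzero(genome[s : s + L] != oriented))
            entries.append((mm, strand, s))
    entries.sort()
    best = entries[0]
    second_mm = entries[1][0] if len(entries) > 1 else np.iinfo(np.int64).max
    return best[0], best[2], best[1], second_mm


def nw_score(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> int:
    """Plain-Python Needleman-Wunsch global alignment score."""
    n, m = len(a), len(b)
    prev = [gap * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [gap * i] + [0] * m
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def sliding_window_hits(
    probe: np.ndarray,
    target: np.ndarray,
    min_identity: float,
    min_cov: float,
):
    """Every ungapped offset (both strands) passing coverage and identity.

    Returns a set of (strand, tstart_forward_coords) matching the engine's
    reporting convention.
    """
    plen = len(probe)
    hits = set()
    for strand, tgt in (("+", target), ("-", (3 - target[::-1]).astype(np.uint8))):
        for s in range(-plen + 1, len(tgt)):
            a, b = max(0, s), min(len(tgt), s + plen)
            if b - a < min_cov * plen:
                continue
            matches = int(np.count_nonzero(tgt[a:b] == probe[a - s : b - s]))
            if matches / plen >= min_identity:
                tstart = s if strand == "+" else len(tgt) - (s + plen)
                hits.add((strand, tstart))
    return hits


def interval_jaccard_by_bases(a: tuple[int, int], b: tuple[int, int]):
    """Overlap and Jaccard via explicit per-base sets."""
    sa = set(range(*a))
    sb = set(range(*b))
    inter = len(sa & sb)
    union = len(sa | sb)
    return inter, inter / union if union else 0.0
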