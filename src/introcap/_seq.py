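"""Low-level nucleotide sequence utilities.

Sequences are held internally as ``numpy.uint8`` arrays of base codes
(A=0, C=1, G=2, T=3); this makes mismatch counting, reverse complement
and k-mer hashing vectorizable.
"""
from __future__ import annotations

import numpy as np

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
    _BASE_TO_CODE[_b + 32] = _i  # lowercase


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string as an array of base codes (A=0,C=1,G=2,T=3)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    raw = np.frombuffer(seq, dtype=np.uint8)
    codes = _BASE_TO_CODE[raw]
    if codes.max(initial=0) > 3:
        bad = chr(raw[int(np.argmax(codes > 3))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode base codes back to an ACGT string."""
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (complement of code c is 3-c)."""
    return (3 - codes[::-1]).astype(np.uint8)


def kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of ``codes`` into an integer (4**k keyspace).

    Returns an int64 array of length ``len(codes) - k + 1``.
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    return windows @ powers


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    """i.i.d. uniform bases."""
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def mutate_substitutions(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each base independently with probability ``rate``.

    A substituted base becomes one of the three *other* bases, uniformly.
    """
    out = codes.copy()
    mask = rng.random(len(codes)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out
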