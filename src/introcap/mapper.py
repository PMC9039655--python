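"""Seed-and-extend read alignment with an explicit uniqueness criterion.

Reads are aligned to the reference by exact k-mer seeding followed by
ungapped full-length Hamming scoring of every candidate locus, on both
strands. A read is accepted at a locus if its mismatch count is within the
``max_mismatch_frac`` budget, and is *unique* iff the best locus beats the
second-best by at least ``unique_margin`` mismatches. Only uniquely mapped,
properly paired reads feed the coverage profiles; reads more diverged than
the mismatch budget (e.g. from tertiary-genepool introgressions) fall out
here, which is the mechanism that converts divergence into coverage drops.

Mapping is deterministic: ties in score between distinct loci always yield
a non-unique call, never an arbitrary assignment. Alignment is ungapped by
design — indel-bearing reads go unmapped and are handed to the attribution
stage (gapped comparison lives in :mod:`introcap.efficacy`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import kmer_values
from .capture import ReadSet
from .synthcohort import ReferenceGenome

UNMAPPED, MULTI, UNIQUE = 0, 1, 2


@dataclass
class SeedIndex:
    """Exact-match k-mer index over a concatenated reference."""

    k: int
    concat: np.ndarray  # all chromosomes concatenated (base codes)
    offsets: np.ndarray  # chromosome start offsets, length n_chrom + 1
    names: list[str]
    sorted_vals: np.ndarray  # packed k-mer values, sorted
    sorted_pos: np.ndarray  # global positions, co-sorted

    def lookup(self, value: int) -> np.ndarray:
        """Global positions of one exact k-mer (empty if absent)."""
        lo = np.searchsorted(self.sorted_vals, value, side="left")
        hi = np.searchsorted(self.sorted_vals, value, side="right")
        return self.sorted_pos[lo:hi]

    def chrom_of(self, gpos: int) -> tuple[str, int]:
        cid = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.names[cid], int(gpos - self.offsets[cid])


def build_index(reference: ReferenceGenome, k: int = 13) -> SeedIndex:
    """Index every k-mer of the reference (k-mers never span chromosomes)."""
    if not 11 <= k <= 31:
        raise ValueError("k must be between 11 and 31")
    names = reference.names
    seqs = [reference.chromosomes[n] for n in names]
    offsets = np.zeros(len(names) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in seqs], out=offsets[1:])
    concat = np.concatenate(seqs)
    vals_parts, pos_parts = [], []
    for name, seq, off in zip(names, seqs, offsets[:-1]):
        v = kmer_values(seq, k)
        vals_parts.append(v)
        pos_parts.append(np.arange(len(v), dtype=np.int64) + off)
    vals = np.concatenate(vals_parts)
    pos = np.concatenate(pos_parts)
    order = np.argsort(vals, kind="stable")
    return SeedIndex(k, concat, offsets, names, vals[order], pos[order])


@dataclass
class MappingResult:
    """Outcome of mapping one accession's paired reads.

    ``status`` is (n_pairs, 2): per-mate UNMAPPED / MULTI / UNIQUE codes
    (MULTI covers any accepted mate that does not end up in a uniquely
    mapped, properly paired alignment, so the three id sets partition the
    reads). ``alignments`` holds one row per mate of every proper unique
    pair.
    """

    accession: str
    alignments: pd.DataFrame  # pair_id, mate, chrom, start, strand, mismatches
    status: np.ndarray
    proper_unique: np.ndarray  # (n_pairs,) bool
    pair_ids: np.ndarray
    read_len: int
    counts: dict[str, int]

    def mate_ids(self, code: int) -> list[str]:
        out = []
        for i, pid in enumerate(self.pair_ids):
            for m in (0, 1):
                if self.status[i, m] == code:
                    out.append(f"{pid}/{m + 1}")
        return out

    @property
    def unmapped_ids(self) -> list[str]:
        return self.mate_ids(UNMAPPED)

    @property
    def multimapped_ids(self) -> list[str]:
        return self.mate_ids(MULTI)


def _seed_offsets(read_len: int, k: int) -> list[int]:
    if read_len < k:
        return []
    offs = list(range(0, read_len - k + 1, k))
    if offs[-1] != read_len - k:
        offs.append(read_len - k)
    return offs


def _candidates(
    reads: np.ndarray, index: SeedIndex
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All candidate (read_idx, global_start) loci plus mismatch counts."""
    n, L = reads.shape
    k = index.k
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    idx_parts, start_parts = [], []
    for off in _seed_offsets(L, k):
        v = reads[:, off : off + k].astype(np.int64) @ powers
        lo = np.searchsorted(index.sorted_vals, v, side="left")
        hi = np.searchsorted(index.sorted_vals, v, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        csum = np.cumsum(counts)
        flat = np.repeat(lo, counts) + (np.arange(total) - np.repeat(csum - counts, counts))
        pos = index.sorted_pos[flat]
        ridx = np.repeat(np.arange(n, dtype=np.int64), counts)
        gstart = pos - off
        # candidate window must stay within the seed's chromosome
        cid = np.searchsorted(index.offsets, pos, side="right") - 1
        ok = (gstart >= index.offsets[cid]) & (gstart + L <= index.offsets[cid + 1])
        idx_parts.append(ridx[ok])
        start_parts.append(gstart[ok])
    if not idx_parts:
        e = np.empty(0, dtype=np.int64)
        return e, e, e
    ridx = np.concatenate(idx_parts)
    gstart = np.concatenate(start_parts)
    # dedupe (read, locus)
    key = ridx * np.int64(len(index.concat)) + gstart
    _, uniq = np.unique(key, return_index=True)
    ridx, gstart = ridx[uniq], gstart[uniq]
    windows = index.concat[gstart[:, None] + np.arange(L)]
    mm = np.count_nonzero(windows != reads[ridx], axis=1).astype(np.int64)
    return ridx, gstart, mm


def _best_per_read(
    n_reads: int, ridx: np.ndarray, gstart: np.ndarray, strand: np.ndarray, mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best locus (mm, gstart, strand) and second-best mm per read."""
    best_mm = np.full(n_reads, np.iinfo(np.int64).max, dtype=np.int64)
    best_start = np.full(n_reads, -1, dtype=np.int64)
    best_strand = np.zeros(n_reads, dtype=np.int8)
    second_mm = np.full(n_reads, np.iinfo(np.int64).max, dtype=np.int64)
    if len(ridx) == 0:
        return best_mm, best_start, best_strand, second_mm
    order = np.lexsort((gstart, strand, mm, ridx))
    r, g, s, m = ridx[order], gstart[order], strand[order], mm[order]
    first = np.ones(len(r), dtype=bool)
    first[1:] = r[1:] != r[:-1]
    fi = np.flatnonzero(first)
    best_mm[r[fi]] = m[fi]
    best_start[r[fi]] = g[fi]
    best_strand[r[fi]] = s[fi]
    si = fi + 1
    si = si[si < len(r)]
    si = si[r[si] == r[si - 1]]
    second_mm[r[si]] = m[si]
    return best_mm, best_start, best_strand, second_mm


def align_mates(
    mates: np.ndarray,
    index: SeedIndex,
    max_mismatch_frac: float = 0.06,
    unique_margin: int = 1,
) -> dict[str, np.ndarray]:
    """Align a (n, read_len) matrix of single-end reads, both strands.

    Returns per-read arrays: ``best_mm``, ``best_start`` (global), ``best_strand``
    (0 forward / 1 reverse), ``second_mm``, ``accepted``, ``unique``.
    """
    n, L = mates.shape
    rc = (3 - np.ascontiguousarray(mates[:, ::-1])).astype(np.uint8)
    parts = []
    for strand_code, oriented in ((0, mates), (1, rc)):
        ridx, gstart, mm = _candidates(oriented, index)
        parts.append((ridx, gstart, np.full(len(ridx), strand_code, np.int8), mm))
    ridx = np.concatenate([p[0] for p in parts])
    gstart = np.concatenate([p[1] for p in parts])
    strand = np.concatenate([p[2] for p in parts])
    mm = np.concatenate([p[3] for p in parts])
    best_mm, best_start, best_strand, second_mm = _best_per_read(n, ridx, gstart, strand, mm)
    max_mm = int(np.floor(max_mismatch_frac * L + 1e-9))
    accepted = best_mm <= max_mm
    unique = accepted & ((second_mm - best_mm) >= unique_margin)
    return {
        "best_mm": best_mm,
        "best_start": best_start,
        "best_strand": best_strand,
        "second_mm": second_mm,
        "accepted": accepted,
        "unique": unique,
    }


def map_reads(
    reads: ReadSet,
    index: SeedIndex,
    max_mismatch_frac: float = 0.06,
    unique_margin: int = 1,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
) -> MappingResult:
    """Map a paired ReadSet against the indexed reference.

    A pair is "uniquely mapped, properly paired" iff both mates map
    uniquely, to the same chromosome, in forward/reverse orientation, with
    an implied fragment no longer than ``frag_mean + 4 * frag_sd``.
    """
    n = reads.n_pairs
    L = reads.read_len
    status = np.zeros((n, 2), dtype=np.int8)
    proper = np.zeros(n, dtype=bool)
    if n == 0:
        return MappingResult(
            reads.accession,
            _empty_alignments(),
            status,
            proper,
            np.empty(0, dtype=object),
            L,
            {"total_reads": 0, "mapped_pairs": 0, "uniquely_mapped_pairs": 0},
        )
    if L < index.k:
        warnings.warn(
            f"read length {L} shorter than k={index.k}; all reads unmapped",
            stacklevel=2,
        )
        return MappingResult(
            reads.accession,
            _empty_alignments(),
            status,
            proper,
            reads.pair_ids(),
            L,
            {"total_reads": 2 * n, "mapped_pairs": 0, "uniquely_mapped_pairs": 0},
        )

    max_frag = frag_mean + 4.0 * frag_sd

    per_mate = [
        align_mates(mates, index, max_mismatch_frac, unique_margin)
        for mates in (reads.mate1, reads.mate2)
    ]
    accepted = [pm["accepted"] for pm in per_mate]
    unique = [pm["unique"] for pm in per_mate]

    # orientation/fragment check: the forward-strand mate must come first
    bs1, bs2 = per_mate[0]["best_start"], per_mate[1]["best_start"]
    st1, st2 = per_mate[0]["best_strand"], per_mate[1]["best_strand"]
    both_unique = unique[0] & unique[1]
    opposite = st1 != st2
    fwd_start = np.where(st1 == 0, bs1, bs2)
    rev_start = np.where(st1 == 0, bs2, bs1)
    frag = rev_start + L - fwd_start
    same_chrom = (
        np.searchsorted(index.offsets, bs1, side="right")
        == np.searchsorted(index.offsets, bs2, side="right")
    )
    proper = both_unique & opposite & same_chrom & (frag >= L) & (frag <= max_frag)

    for m in (0, 1):
        status[accepted[m], m] = MULTI
        status[:, m][proper & unique[m]] = UNIQUE

    pair_ids = reads.pair_ids()
    rows = []
    for i in np.flatnonzero(proper):
        for m, pm in enumerate(per_mate):
            chrom, local = index.chrom_of(int(pm["best_start"][i]))
            rows.append(
                (
                    pair_ids[i],
                    m + 1,
                    chrom,
                    local,
                    "-" if pm["best_strand"][i] else "+",
                    int(pm["best_mm"][i]),
                )
            )
    alignments = pd.DataFrame(
        rows, columns=["pair_id", "mate", "chrom", "start", "strand", "mismatches"]
    )
    counts = {
        "total_reads": 2 * n,
        "mapped_pairs": int((accepted[0] & accepted[1]).sum()),
        "uniquely_mapped_pairs": int(proper.sum()),
    }
    return MappingResult(reads.accession, alignments, status, proper, pair_ids, L, counts)


def _empty_alignments() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["pair_id", "mate", "chrom", "start", "strand", "mismatches"]
    )
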