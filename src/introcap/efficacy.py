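"""In-silico probe efficacy scoring and global locus alignment.

``probe_hits`` scores a probe set against an arbitrary target sequence with
a word-seeded, ungapped-extended local matcher (both strands), summarizing
how many probes find hits, how many are single-hit, and the mean best-hit
identity — the analysis that shows capture efficacy decaying with
divergence. ``locus_align`` is a full Needleman–Wunsch global aligner with
deterministic traceback, used to diagnose small indels between candidate
source loci; ``assign_nearest_reference`` compares a query against a panel
of candidate references and renders a verdict.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import decode, kmer_values, revcomp


# ---------------------------------------------------------------------------
# Seeded local hit engine
# ---------------------------------------------------------------------------


class TargetIndex:
    """Word index over a single target sequence (forward strand)."""

    def __init__(self, target: np.ndarray, word_size: int = 11):
        if not 1 <= word_size <= 31:
            raise ValueError("word_size must be in [1, 31]")
        self.target = target
        self.word_size = word_size
        vals = kmer_values(target, word_size)
        order = np.argsort(vals, kind="stable")
        self._vals = vals[order]
        self._pos = np.arange(len(vals), dtype=np.int64)[order]

    def seed_starts(self, query: np.ndarray) -> np.ndarray:
        """Candidate target start offsets for an ungapped full-query match."""
        k = self.word_size
        if len(query) < k:
            return np.empty(0, dtype=np.int64)
        qvals = kmer_values(query, k)
        offsets = list(range(0, len(query) - k + 1, k))
        if offsets[-1] != len(query) - k:
            offsets.append(len(query) - k)
        starts = []
        for off in offsets:
            lo = np.searchsorted(self._vals, qvals[off], side="left")
            hi = np.searchsorted(self._vals, qvals[off], side="right")
            starts.append(self._pos[lo:hi] - off)
        return np.unique(np.concatenate(starts)) if starts else np.empty(0, np.int64)


@dataclass
class HitSummary:
    """Aggregate probe-vs-target hit statistics."""

    n_probes: int
    n_hits: int  # total hits, multi-hits counted
    n_probes_with_hit: int
    n_single_hit_probes: int
    mean_best_identity: float | None  # percent, None if no probe hit

    def as_dict(self) -> dict:
        mean = (
            None
            if self.mean_best_identity is None
            else round(self.mean_best_identity, 1)
        )
        return {
            "n_probes": self.n_probes,
            "n_hits": self.n_hits,
            "n_probes_with_hit": self.n_probes_with_hit,
            "n_single_hit_probes": self.n_single_hit_probes,
            "mean_best_identity": mean,
        }


def _ungapped_hits(
    query: np.ndarray,
    target: np.ndarray,
    starts: np.ndarray,
    min_identity: float,
    min_cov: float,
) -> list[tuple[int, float]]:
    """Score candidate start offsets; identity is matches / query length."""
    qlen = len(query)
    hits = []
    for s in starts:
        s = int(s)
        a, b = max(0, s), min(len(target), s + qlen)
        if b - a < min_cov * qlen:
            continue
        matches = int(np.count_nonzero(target[a:b] == query[a - s : b - s]))
        identity = matches / qlen
        if identity >= min_identity:
            hits.append((s, identity))
    return hits


def best_hit_identity(
    query: np.ndarray,
    index: TargetIndex,
    index_rc: TargetIndex | None = None,
    min_cov: float = 0.8,
) -> float | None:
    """Best local-match identity of a query on a target (both strands)."""
    best = None
    for idx, q in ((index, query), (index_rc, query)):
        if idx is None:
            continue
        for _, ident in _ungapped_hits(q, idx.target, idx.seed_starts(q), 0.0, min_cov):
            if best is None or ident > best:
                best = ident
    return best


def probe_hits(
    probe_seqs: dict[str, np.ndarray],
    target: np.ndarray,
    min_identity: float = 0.80,
    min_cov: float = 0.80,
    word_size: int = 11,
) -> tuple[HitSummary, pd.DataFrame]:
    """Score every probe against a target sequence, both strands.

    A hit is a seeded, ungapped-extended local match covering at least
    ``min_cov`` of the probe at identity >= ``min_identity`` (identity is
    matches over the full probe length). Returns the summary plus a
    per-probe hit table (probe_id, strand, target_start, identity).
    """
    if len(target) == 0:
        raise ValueError("target is empty")
    min_probe = min(len(s) for s in probe_seqs.values())
    if word_size > min_probe:
        raise ValueError("word_size exceeds probe length")
    fwd = TargetIndex(target, word_size)
    rc_target = revcomp(target)
    rev = TargetIndex(rc_target, word_size)

    rows = []
    best_per_probe: dict[str, float] = {}
    for pid, seq in probe_seqs.items():
        for strand, idx in (("+", fwd), ("-", rev)):
            for s, ident in _ungapped_hits(
                seq, idx.target, idx.seed_starts(seq), min_identity, min_cov
            ):
                # report reverse-strand hits in forward-target coordinates
                tstart = s if strand == "+" else len(target) - (s + len(seq))
                rows.append((pid, strand, tstart, 100.0 * ident))
                if pid not in best_per_probe or ident * 100.0 > best_per_probe[pid]:
                    best_per_probe[pid] = 100.0 * ident
    table = pd.DataFrame(rows, columns=["probe_id", "strand", "target_start", "identity"])
    hit_counts = table.groupby("probe_id").size() if len(table) else pd.Series(dtype=int)
    summary = HitSummary(
        n_probes=len(probe_seqs),
        n_hits=len(table),
        n_probes_with_hit=len(best_per_probe),
        n_single_hit_probes=int((hit_counts == 1).sum()),
        mean_best_identity=(
            float(np.mean(list(best_per_probe.values()))) if best_per_probe else None
        ),
    )
    return summary, table


# ---------------------------------------------------------------------------
# Global alignment (Needleman-Wunsch) and indel extraction
# ---------------------------------------------------------------------------


@dataclass
class IndelEvent:
    """One gap run, in reference-frame coordinates."""

    ref_pos: int
    length: int
    kind: str  # "insertion" (absent from ref) or "deletion" (absent from query)
    sequence: str  # inserted sequence, "" for deletions


@dataclass
class LocusAlignment:
    """A scored global alignment of reference vs query with gap characters."""

    aligned_ref: str
    aligned_query: str
    score: int
    indels: list[IndelEvent] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_ref)

    @property
    def matches(self) -> int:
        return sum(
            1
            for a, b in zip(self.aligned_ref, self.aligned_query)
            if a == b and a != "-"
        )

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.n_columns if self.n_columns else 100.0


def locus_align(
    seq_a: np.ndarray | str,
    seq_b: np.ndarray | str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> LocusAlignment:
    """Optimal global alignment of reference ``seq_a`` vs query ``seq_b``.

    Deterministic traceback prefers diagonal > up (gap in query) > left
    (gap in reference). Indel events are reported in reference coordinates:
    an insertion of length n before reference position p, or a deletion of
    reference bases [p, p+n).
    """
    from ._seq import encode

    a = encode(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode(seq_b) if isinstance(seq_b, str) else seq_b
    n, m = len(a), len(b)

    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    if n and m:
        sub = np.where(a[:, None] == b[None, :], match, mismatch).astype(np.int32)
        for i in range(1, n + 1):
            diag = H[i - 1, :-1] + sub[i - 1]
            up = H[i - 1, 1:] + gap
            best = np.maximum(diag, up)
            # resolve the within-row (left-gap) dependency with a running max
            j_idx = np.arange(1, m + 1, dtype=np.int64)
            run = np.maximum.accumulate(
                np.concatenate(([H[i, 0]], best - gap * j_idx))
            )
            H[i, 1:] = np.maximum(best, run[:-1] + gap * j_idx)

    # traceback, preferring diagonal > up > left
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            ra.append(decode(a[i - 1 : i]))
            rb.append(decode(b[j - 1 : j]))
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            ra.append(decode(a[i - 1 : i]))
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(decode(b[j - 1 : j]))
            j -= 1
    aligned_ref = "".join(reversed(ra))
    aligned_query = "".join(reversed(rb))

    indels: list[IndelEvent] = []
    ref_pos = 0
    col = 0
    while col < len(aligned_ref):
        if aligned_ref[col] == "-":
            run = col
            while run < len(aligned_ref) and aligned_ref[run] == "-":
                run += 1
            indels.append(
                IndelEvent(ref_pos, run - col, "insertion", aligned_query[col:run])
            )
            col = run
        elif aligned_query[col] == "-":
            run = col
            while run < len(aligned_query) and aligned_query[run] == "-":
                run += 1
            indels.append(IndelEvent(ref_pos, run - col, "deletion", ""))
            ref_pos += run - col
            col = run
        else:
            ref_pos += 1
            col += 1
    return LocusAlignment(aligned_ref, aligned_query, int(H[n, m]), indels)


AMBIGUOUS = "AMBIGUOUS"


def assign_nearest_reference(
    query: np.ndarray | str,
    candidates: dict[str, np.ndarray | str],
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[pd.DataFrame, str]:
    """Align a query to each candidate reference; verdict = argmax identity.

    Ties (within 1e-9 percent) yield the AMBIGUOUS verdict.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate references")
    rows = []
    for label, seq in candidates.items():
        aln = locus_align(seq, query, match, mismatch, gap)
        rows.append((label, aln.percent_identity, aln.score, len(aln.indels)))
    table = pd.DataFrame(rows, columns=["candidate", "percent_identity", "score", "n_indels"])
    ranked = table.sort_values("percent_identity", ascending=False).reset_index(drop=True)
    if len(ranked) > 1 and abs(ranked.loc[0, "percent_identity"] - ranked.loc[1, "percent_identity"]) < 1e-9:
        return table, AMBIGUOUS
    return table, str(ranked.loc[0, "candidate"])
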