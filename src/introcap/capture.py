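"""Divergence-dependent capture simulation and paired-end read generation.

Hybridization capture tolerates some probe-target mismatch (vendor figures in
the 10-20% range); beyond that tolerance the probe fails and the target drops
out of the library. This module models that mechanism: each probe's realized
divergence against the accession genome sets its capture probability, and
captured probes emit Poisson numbers of paired-end fragments.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import decode, revcomp
from .synthcohort import DELETION, MosaicGenome, ProbeSet


@dataclass
class CaptureModel:
    """Capture success probability as a function of probe-target divergence.

    ``step`` mode: capture succeeds iff divergence <= tolerance.
    ``logistic`` mode: p = 1 / (1 + exp(steepness * (d - tolerance))), a
    smooth version with p = 0.5 exactly at the tolerance.
    """

    tolerance: float = 0.10
    mode: str = "step"
    steepness: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance < 1.0:
            raise ValueError("tolerance must be in (0, 1)")
        if self.mode not in ("step", "logistic"):
            raise ValueError(f"unknown capture mode {self.mode!r}")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")


def capture_probability(d, model: CaptureModel):
    """Probability that a probe at divergence ``d`` captures its target.

    Vectorized over ``d``; non-increasing in d in both modes.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("divergence must be in [0, 1]")
    if model.mode == "step":
        p = (d <= model.tolerance).astype(float)
    else:
        p = 1.0 / (1.0 + np.exp(model.steepness * (d - model.tolerance)))
    return float(p) if p.ndim == 0 else p


def probe_target_divergence(
    probe_chrom: str, probe_start: int, probe_seq: np.ndarray, mosaic: MosaicGenome
) -> float:
    """Per-base mismatch fraction between a probe and its homologous window.

    Bases falling in a DELETION segment count as mismatches, so a fully
    deleted window returns 1.0.
    """
    plen = len(probe_seq)
    start, end = probe_start, probe_start + plen
    mismatches = 0
    seen = 0
    for blk in mosaic.blocks[probe_chrom]:
        a = max(start, blk.ref_start)
        b = min(end, blk.ref_end)
        if a >= b:
            continue
        seen += b - a
        if blk.source == DELETION:
            mismatches += b - a
            continue
        mos_a = blk.mos_start + (a - blk.ref_start)
        window = mosaic.chromosomes[probe_chrom][mos_a : mos_a + (b - a)]
        probe_part = probe_seq[a - start : b - start]
        n = min(len(window), len(probe_part))
        mismatches += int(np.count_nonzero(window[:n] != probe_part[:n]))
        mismatches += (b - a) - n  # bases lost to donor-indel length changes
    mismatches += plen - seen  # window extends past recorded blocks
    return mismatches / plen


@dataclass
class ReadSet:
    """Simulated paired reads with per-pair truth of origin.

    ``mate1``/``mate2`` are (n_pairs, read_len) arrays of base codes; mate2
    is the reverse-complemented 3' read, as sequenced. ``truth`` records the
    fragment interval (mosaic frame) and the source label of the fragment
    midpoint (reference or donor name).
    """

    accession: str
    mate1: np.ndarray
    mate2: np.ndarray
    truth: pd.DataFrame  # pair_id, chrom, frag_start, frag_end, origin
    read_len: int
    quality_char: str = "?"  # constant Q30

    @property
    def n_pairs(self) -> int:
        return len(self.truth)

    def pair_ids(self) -> np.ndarray:
        return self.truth["pair_id"].to_numpy()

    def write_fastq(self, prefix) -> tuple[str, str]:
        """Write the two mate files as <prefix>_1.fastq / <prefix>_2.fastq."""
        paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq")
        qual = self.quality_char * self.read_len
        for path, mates, suffix in zip(paths, (self.mate1, self.mate2), ("/1", "/2")):
            with open(path, "w") as fh:
                for pid, row in zip(self.truth["pair_id"], mates):
                    fh.write(f"@{pid}{suffix}\n{decode(row)}\n+\n{qual}\n")
        return paths


def load_fastq_pair(path1, path2, accession: str = "sample") -> ReadSet:
    """Load two mate FASTQ files (real-data mode) into a ReadSet.

    Pair ids are taken from mate-1 record names with any /1 suffix stripped;
    truth columns are empty.
    """
    from Bio.SeqIO import parse

    from ._seq import encode

    def _load(path, suffix):
        ids, rows = [], []
        for rec in parse(str(path), "fastq"):
            rid = rec.id
            if rid.endswith(suffix):
                rid = rid[: -len(suffix)]
            ids.append(rid)
            rows.append(encode(str(rec.seq)))
        return ids, rows

    ids1, rows1 = _load(path1, "/1")
    ids2, rows2 = _load(path2, "/2")
    if ids1 != ids2:
        raise ValueError("mate files disagree on read ids or order")
    lens = {len(r) for r in rows1} | {len(r) for r in rows2}
    if len(lens) != 1:
        raise ValueError("reads must have a single constant length")
    read_len = lens.pop()
    truth = pd.DataFrame(
        {
            "pair_id": ids1,
            "chrom": [""] * len(ids1),
            "frag_start": np.zeros(len(ids1), dtype=np.int64),
            "frag_end": np.zeros(len(ids1), dtype=np.int64),
            "origin": [""] * len(ids1),
        }
    )
    return ReadSet(accession, np.array(rows1), np.array(rows2), truth, read_len)


def _pairs_per_probe_rate(
    probes: ProbeSet, mean_depth: float, frag_mean: float, read_len: int
) -> float:
    """Poisson rate per probe so that expected depth over probe-covered
    bases equals ``mean_depth``.

    One pair deposits 2*read_len sequenced bases spread over roughly a
    frag_mean-wide footprint centred on its probe, so nearby probes add
    depth to each other's bases. The expected unit-rate depth at base x is
    (2*read_len / (frag_mean * probe_len)) * sum of probe-window occupancy
    over the frag_mean window around x; the rate is mean_depth divided by
    the mask average of that quantity.
    """
    plen = probes.probe_len
    half = int(round(frag_mean / 2.0))
    unit_sum = 0.0
    mask_total = 0
    for chrom, grp in probes.probes.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        L = int(ends.max()) + half + 1
        occ = np.zeros(L + 1, dtype=np.int64)
        np.add.at(occ, starts, 1)
        np.add.at(occ, ends, -1)
        occ = np.cumsum(occ[:-1])  # probe-window multiplicity per base
        csum = np.concatenate(([0], np.cumsum(occ)))
        mask = np.flatnonzero(occ > 0)
        lo = np.maximum(mask - half + 1, 0)
        hi = np.minimum(mask + half, L)
        unit_sum += float((csum[hi] - csum[lo]).sum()) * 2 * read_len / (frag_mean * plen)
        mask_total += len(mask)
    if mask_total == 0 or unit_sum == 0:
        return mean_depth
    return mean_depth / (unit_sum / mask_total)


def simulate_reads(
    mosaic: MosaicGenome,
    probes: ProbeSet,
    model: CaptureModel,
    mean_depth: float,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
    read_len: int = 150,
    err_rate: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Simulate capture-and-sequencing for one accession.

    Per probe, the pair count is Poisson with a rate calibrated so the
    expected depth over probe-covered bases equals ``mean_depth``, thinned
    by the capture probability at the probe's realized divergence.
    Fragments are Normal(frag_mean, frag_sd) truncated at read_len and
    centred on the probe with uniform jitter across the probe window.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)

    probe_rows = probes.probes
    d_values = np.empty(len(probe_rows))
    for i, row in enumerate(probe_rows.itertuples(index=False)):
        d_values[i] = probe_target_divergence(
            row.chrom, row.start, probes.sequences[row.probe_id], mosaic
        )
    p_capture = np.atleast_1d(capture_probability(d_values, model))
    rate = _pairs_per_probe_rate(probes, mean_depth, frag_mean, read_len)
    n_pairs_per_probe = rng.poisson(rate * p_capture)

    starts_all: list[int] = []
    lens_all: list[int] = []
    chroms_all: list[str] = []
    for i, row in enumerate(probe_rows.itertuples(index=False)):
        n = int(n_pairs_per_probe[i])
        if n == 0:
            continue
        Lm = mosaic.length(row.chrom)
        m_start, m_end = mosaic.lift_interval(row.chrom, row.start, row.end)
        if m_end <= m_start:
            continue
        centers = m_start + rng.random(n) * (m_end - m_start)
        frag_lens = np.maximum(
            read_len, np.round(rng.normal(frag_mean, frag_sd, size=n))
        ).astype(np.int64)
        frag_lens = np.minimum(frag_lens, Lm)
        fs = np.round(centers - frag_lens / 2).astype(np.int64)
        fs = np.clip(fs, 0, Lm - frag_lens)
        starts_all.extend(fs.tolist())
        lens_all.extend(frag_lens.tolist())
        chroms_all.extend([row.chrom] * n)

    n_total = len(starts_all)
    mate1 = np.empty((n_total, read_len), dtype=np.uint8)
    mate2 = np.empty((n_total, read_len), dtype=np.uint8)
    origins: list[str] = []
    for j in range(n_total):
        chrom, fs, fl = chroms_all[j], starts_all[j], lens_all[j]
        seq = mosaic.chromosomes[chrom]
        mate1[j] = seq[fs : fs + read_len]
        mate2[j] = revcomp(seq[fs + fl - read_len : fs + fl])
        origins.append(mosaic.source_at(chrom, fs + fl // 2))
    if err_rate > 0 and n_total:
        for mates in (mate1, mate2):
            mask = rng.random(mates.shape) < err_rate
            n_err = int(mask.sum())
            if n_err:
                mates[mask] = (
                    mates[mask] + rng.integers(1, 4, size=n_err, dtype=np.uint8)
                ) % 4

    truth = pd.DataFrame(
        {
            "pair_id": [f"{mosaic.accession}_p{j:07d}" for j in range(n_total)],
            "chrom": chroms_all,
            "frag_start": np.array(starts_all, dtype=np.int64),
            "frag_end": np.array(starts_all, dtype=np.int64)
            + np.array(lens_all, dtype=np.int64),
            "origin": origins,
        }
    )
    return ReadSet(mosaic.accession, mate1, mate2, truth, read_len)
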