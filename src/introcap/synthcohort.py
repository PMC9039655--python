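"""Synthetic cohort generator.

Builds the statistical stand-in for an exome-capture introgression study on a
hexaploid crop: a multi-chromosome reference genome, donor genomes at fixed
substitution-divergence tiers (primary/secondary/tertiary genepool), accession
genomes that are mosaics of reference and introgressed or deleted segments,
capture probes placed with a telomere-to-centromere density gradient, and a
biallelic marker genotype matrix consistent with the mosaic truth.

Coordinates are 0-based half-open everywhere; the truth BED uses the same
convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import decode, encode, mutate_substitutions, random_codes

#: Sentinel donor name marking a deleted (hemizygous-absent) segment.
DELETION = "DELETION"

#: Genotype call codes used throughout.
HOM_REF, HOM_ALT, HET, MISSING = 0, 1, 2, 3
CALL_LABELS = {HOM_REF: "AA", HOM_ALT: "BB", HET: "AB", MISSING: "NC"}
LABEL_CALLS = {v: k for k, v in CALL_LABELS.items()}

#: Default divergence calibration per genepool tier (substitutions/base).
#: These are calibration choices, not measured values; see docs/methods.md.
TIER_DIVERGENCE = {"primary": 0.015, "secondary": 0.06, "tertiary": 0.12}


@dataclass
class ReferenceGenome:
    """Reference assembly: ordered chromosomes plus centromere positions."""

    chromosomes: dict[str, np.ndarray]  # name -> base codes
    centromeres: dict[str, int]  # name -> base offset

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("reference needs at least one chromosome")
        for name, seq in self.chromosomes.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name} is empty")
            cen = self.centromeres[name]
            if not 0 < cen < len(seq):
                raise ValueError(f"centromere of {name} not strictly inside")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass
class DonorSpec:
    """An introgression donor species at a given divergence tier."""

    name: str
    genepool: str  # primary | secondary | tertiary
    divergence: float  # expected substitution fraction per base
    indel_rate: float = 0.0  # expected indel events per base
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if self.genepool not in ("primary", "secondary", "tertiary"):
            raise ValueError(f"unknown genepool {self.genepool!r}")


@dataclass
class DonorGenome:
    """Donor genome diverged from the reference, with a coordinate lift.

    ``events`` maps chromosome -> (positions, deltas): an indel at reference
    position p with delta>0 inserts delta bases before p; delta<0 deletes the
    reference run [p, p-delta). The lift lets a reference interval be located
    in the donor frame (perfect synteny is assumed).
    """

    spec: DonorSpec
    chromosomes: dict[str, np.ndarray]
    events: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.spec.name

    def ref_to_donor(self, chrom: str, pos: int) -> int:
        pos_arr, deltas = self.events.get(chrom, (np.empty(0, int), np.empty(0, int)))
        shift = int(deltas[pos_arr <= pos].sum()) if len(pos_arr) else 0
        return max(0, min(pos + shift, len(self.chromosomes[chrom])))

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Donor sequence homologous to reference interval [start, end)."""
        a = self.ref_to_donor(chrom, start)
        b = self.ref_to_donor(chrom, end)
        return self.chromosomes[chrom][a:b]


@dataclass(frozen=True)
class IntrogressionSegment:
    """One introgressed (or deleted) segment in the reference frame."""

    chrom: str
    start: int
    end: int
    donor: str  # donor name, or DELETION

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("segment needs 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class _Block:
    """Alignment block between reference and mosaic frames."""

    ref_start: int
    ref_end: int
    mos_start: int
    mos_end: int
    source: str  # "reference", donor name, or DELETION


@dataclass
class MosaicGenome:
    """An accession genome: reference with donor segments spliced in."""

    accession: str
    chromosomes: dict[str, np.ndarray]
    truth: list[IntrogressionSegment]
    blocks: dict[str, list[_Block]]

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def lift_interval(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Map a reference-frame interval into the mosaic frame (clipped)."""
        return self._lift(chrom, start), self._lift(chrom, end)

    def _lift(self, chrom: str, pos: int) -> int:
        for blk in self.blocks[chrom]:
            if blk.ref_start <= pos < blk.ref_end:
                off = pos - blk.ref_start
                return min(blk.mos_start + off, blk.mos_end)
        return self.blocks[chrom][-1].mos_end if pos > 0 else 0

    def source_at(self, chrom: str, mosaic_pos: int) -> str:
        """Origin label (reference or donor name) of a mosaic-frame position."""
        for blk in self.blocks[chrom]:
            if blk.mos_start <= mosaic_pos < blk.mos_end:
                return blk.source
        return "reference"

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": self.accession,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "donor": s.donor,
                }
                for s in self.truth
            ],
            columns=["accession", "chrom", "start", "end", "donor"],
        )


@dataclass
class ProbeSet:
    """Capture probes: constant-length intervals on the reference."""

    probes: pd.DataFrame  # columns: probe_id, chrom, start, end
    sequences: dict[str, np.ndarray]  # probe_id -> base codes
    probe_len: int

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class GenotypeMatrix:
    """Markers x accessions categorical genotype calls."""

    markers: pd.DataFrame  # columns: marker_id, chrom, position
    calls: pd.DataFrame  # index marker_id, one int8 column per accession

    def __post_init__(self) -> None:
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.columns)

    def subset(self, chrom: str, start: int | None = None, end: int | None = None):
        """Marker ids on a chromosome, optionally within [start, end)."""
        m = self.markers
        mask = m["chrom"] == chrom
        if start is not None:
            mask &= m["position"] >= start
        if end is not None:
            mask &= m["position"] < end
        return m.loc[mask, "marker_id"].tolist()


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def make_reference(
    chrom_lengths: list[int],
    centromere_fracs: list[float],
    seed: int,
    names: list[str] | None = None,
) -> ReferenceGenome:
    """Generate an i.i.d.-uniform reference genome.

    ``centromere_fracs`` places each centromere at ``frac * length``.
    """
    if len(chrom_lengths) != len(centromere_fracs):
        raise ValueError("chrom_lengths and centromere_fracs differ in length")
    for L in chrom_lengths:
        if L <= 0:
            raise ValueError("chromosome lengths must be positive")
    for f in centromere_fracs:
        if not 0.0 < f < 1.0:
            raise ValueError("centromere fractions must lie in (0, 1)")
    if names is None:
        names = [f"chr{i + 1}" for i in range(len(chrom_lengths))]
    rng = np.random.default_rng(seed)
    chroms = {n: random_codes(rng, L) for n, L in zip(names, chrom_lengths)}
    cens = {n: int(round(f * L)) for n, L, f in zip(names, chrom_lengths, centromere_fracs)}
    return ReferenceGenome(chroms, cens)


def make_donor(reference: ReferenceGenome, spec: DonorSpec) -> DonorGenome:
    """Derive a donor genome at the spec's divergence (and optional indels)."""
    rng = np.random.default_rng(spec.seed)
    chroms: dict[str, np.ndarray] = {}
    events: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, ref_seq in reference.chromosomes.items():
        seq = mutate_substitutions(ref_seq, spec.divergence, rng)
        pos_list: list[int] = []
        delta_list: list[int] = []
        if spec.indel_rate > 0:
            n_ev = rng.binomial(len(seq), spec.indel_rate)
            positions = np.sort(rng.choice(len(seq), size=n_ev, replace=False))
            pieces = []
            prev = 0
            for p in positions:
                p = int(p)
                if p < prev:
                    continue  # swallowed by a previous deletion
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:  # insertion before p
                    pieces.append(seq[prev:p])
                    pieces.append(random_codes(rng, length))
                    pos_list.append(p)
                    delta_list.append(length)
                    prev = p
                else:  # deletion of [p, p+length)
                    length = min(length, len(seq) - p)
                    pieces.append(seq[prev:p])
                    pos_list.append(p)
                    delta_list.append(-length)
                    prev = p + length
            pieces.append(seq[prev:])
            seq = np.concatenate(pieces)
        chroms[name] = seq
        events[name] = (np.array(pos_list, int), np.array(delta_list, int))
    return DonorGenome(spec, chroms, events)


def make_accession(
    reference: ReferenceGenome,
    donors: dict[str, DonorGenome],
    segments: list[IntrogressionSegment],
    accession: str,
) -> MosaicGenome:
    """Splice donor segments (reference coordinates) into the reference.

    DELETION segments are removed from the emitted sequence; the block table
    records the coordinate lift between reference and mosaic frames.
    """
    by_chrom: dict[str, list[IntrogressionSegment]] = {}
    for seg in segments:
        if seg.chrom not in reference.chromosomes:
            raise ValueError(f"unknown chromosome {seg.chrom}")
        if seg.end > reference.length(seg.chrom):
            raise ValueError(f"segment {seg} exceeds chromosome length")
        if seg.donor != DELETION and seg.donor not in donors:
            raise ValueError(f"unknown donor {seg.donor!r}")
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping segments on {chrom}: {a} / {b}")

    chroms: dict[str, np.ndarray] = {}
    blocks: dict[str, list[_Block]] = {}
    for chrom, ref_seq in reference.chromosomes.items():
        pieces: list[np.ndarray] = []
        blks: list[_Block] = []
        cursor = 0
        mos = 0

        def _emit(ref_a: int, ref_b: int, seq: np.ndarray, source: str) -> int:
            nonlocal mos
            blks.append(_Block(ref_a, ref_b, mos, mos + len(seq), source))
            pieces.append(seq)
            mos += len(seq)
            return mos

        for seg in by_chrom.get(chrom, []):
            if seg.start > cursor:
                _emit(cursor, seg.start, ref_seq[cursor : seg.start], "reference")
            if seg.donor == DELETION:
                blks.append(_Block(seg.start, seg.end, mos, mos, DELETION))
            else:
                donor_seq = donors[seg.donor].slice(chrom, seg.start, seg.end)
                _emit(seg.start, seg.end, donor_seq, seg.donor)
            cursor = seg.end
        if cursor < len(ref_seq):
            _emit(cursor, len(ref_seq), ref_seq[cursor:], "reference")
        chroms[chrom] = (
            np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
        )
        blocks[chrom] = blks
    return MosaicGenome(accession, chroms, sorted(segments, key=lambda s: (s.chrom, s.start)), blocks)


def _sample_arm_positions(
    rng: np.random.Generator, n: int, gradient_slope: float
) -> np.ndarray:
    """Sample normalized centromere->telomere distances x in [0,1) with
    density proportional to 1 + gradient_slope * x (inverse-CDF)."""
    u = rng.random(n)
    if abs(gradient_slope) < 1e-12:
        return u
    s = gradient_slope
    mass = 1.0 + s / 2.0
    # solve (s/2) x^2 + x = u * mass for x >= 0
    x = (-1.0 + np.sqrt(1.0 + 2.0 * s * u * mass)) / s
    return np.clip(x, 0.0, 1.0 - 1e-12)


def design_probes(
    reference: ReferenceGenome,
    n_probes: int,
    probe_len: int = 120,
    gradient_slope: float = 2.0,
    seed: int = 0,
) -> ProbeSet:
    """Place capture probes with a telomere-to-centromere density gradient.

    Probe start density is proportional to ``1 + gradient_slope * x`` where x
    is the distance from the centromere normalized by arm length (x=1 at the
    telomere), mirroring the gene-density gradient that capture designs track.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if gradient_slope < -1:
        raise ValueError("gradient_slope < -1 would imply negative density")
    min_len = min(reference.length(c) for c in reference.names)
    if probe_len > min_len:
        raise ValueError("probe_len exceeds the shortest chromosome")
    rng = np.random.default_rng(seed)

    names = reference.names
    lengths = np.array([reference.length(c) for c in names], dtype=float)
    per_chrom = rng.multinomial(n_probes, lengths / lengths.sum())

    rows = []
    sequences: dict[str, np.ndarray] = {}
    idx = 0
    for chrom, n_c in zip(names, per_chrom):
        L = reference.length(chrom)
        cen = reference.centromeres[chrom]
        arm_lens = np.array([cen, L - cen], dtype=float)
        arm_choice = rng.random(n_c) < (arm_lens[0] / arm_lens.sum())
        x = _sample_arm_positions(rng, n_c, gradient_slope)
        # left arm: telomere at 0 -> position = cen * (1 - x); right arm:
        # telomere at L -> position = cen + x * (L - cen)
        pos = np.where(arm_choice, cen * (1.0 - x), cen + x * (L - cen))
        starts = np.clip(pos.astype(np.int64), 0, L - probe_len)
        for s in np.sort(starts):
            pid = f"probe_{idx:06d}"
            rows.append((pid, chrom, int(s), int(s) + probe_len))
            sequences[pid] = reference.chromosomes[chrom][s : s + probe_len]
            idx += 1
    probes = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    return ProbeSet(probes, sequences, probe_len)


def simulate_genotypes(
    reference: ReferenceGenome,
    mosaics: list[MosaicGenome],
    n_markers: int,
    err_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    p_alt: float = 0.9,
    reference_name: str | None = "REF",
) -> GenotypeMatrix:
    """Simulate a biallelic marker matrix reflecting the mosaic truth.

    Calls are HOM_REF on reference-derived sequence; inside introgressed
    segments HOM_ALT with probability ``p_alt`` (else HET); MISSING inside
    deletions. Random call errors and missingness are applied afterwards.
    Accessions are modelled as fully homozygous inbreds, so HET arises only
    through ``p_alt`` and error.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    for r in (err_rate, missing_rate, p_alt):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    names = reference.names
    lengths = np.array([reference.length(c) for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_markers, p=lengths / lengths.sum())
    rows = []
    for c_i in range(len(names)):
        n_c = int((chrom_idx == c_i).sum())
        pos = np.sort(rng.choice(int(lengths[c_i]), size=n_c, replace=False))
        for p in pos:
            rows.append((names[c_i], int(p)))
    markers = pd.DataFrame(rows, columns=["chrom", "position"])
    markers.insert(0, "marker_id", [f"mk_{i:05d}" for i in range(len(markers))])

    cols: dict[str, np.ndarray] = {}
    if reference_name is not None:
        cols[reference_name] = np.full(len(markers), HOM_REF, dtype=np.int8)
    for mosaic in mosaics:
        calls = np.full(len(markers), HOM_REF, dtype=np.int8)
        for seg in mosaic.truth:
            inside = (
                (markers["chrom"] == seg.chrom)
                & (markers["position"] >= seg.start)
                & (markers["position"] < seg.end)
            ).to_numpy()
            n_in = int(inside.sum())
            if seg.donor == DELETION:
                calls[inside] = MISSING
            else:
                alt = rng.random(n_in) < p_alt
                calls[inside] = np.where(alt, HOM_ALT, HET)
        cols[mosaic.accession] = calls

    for name, calls in cols.items():
        flip = rng.random(len(calls)) < err_rate
        if flip.any():
            # flip to a uniformly chosen *other* non-missing state
            shift = rng.integers(1, 3, size=int(flip.sum()))
            calls[flip] = (calls[flip] + shift) % 3
        lost = rng.random(len(calls)) < missing_rate
        calls[lost] = MISSING
        cols[name] = calls

    calls_df = pd.DataFrame(cols, index=markers["marker_id"])
    return GenotypeMatrix(markers, calls_df)


# ---------------------------------------------------------------------------
# Writers / readers (plain-text interchange formats)
# ---------------------------------------------------------------------------


def write_fasta(path, sequences: dict[str, np.ndarray], width: int = 80) -> None:
    """Write code arrays as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(decode(seq)), id=name, description="")
        for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, np.ndarray]:
    """Read a FASTA file into code arrays."""
    from Bio.SeqIO import parse

    return {rec.id: encode(str(rec.seq)) for rec in parse(str(path), "fasta")}


def write_truth_bed(path, mosaics: list[MosaicGenome]) -> None:
    frames = [m.truth_frame() for m in mosaics]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            name = f"{r['accession']}|{r['donor']}"
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\n")


def write_probe_bed(path, probes: ProbeSet) -> None:
    probes.probes.to_csv(
        path, sep="\t", header=False, index=False,
        columns=["chrom", "start", "end", "probe_id"],
    )


def write_genotype_tsv(path, gm: GenotypeMatrix) -> None:
    """Genotype TSV: marker id, chrom, pos, then one AA/BB/AB/NC column per accession."""
    out = gm.markers.set_index("marker_id").copy()
    for acc in gm.accessions:
        out[acc] = [CALL_LABELS[int(c)] for c in gm.calls[acc]]
    out.to_csv(path, sep="\t", index=True, index_label="marker_id")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    markers = df[["marker_id", "chrom", "position"]].copy()
    acc_cols = [c for c in df.columns if c not in ("marker_id", "chrom", "position")]
    calls = pd.DataFrame(
        {a: [LABEL_CALLS[v] for v in df[a]] for a in acc_cols},
        index=df["marker_id"],
        dtype=np.int8,
    )
    return GenotypeMatrix(markers, calls)
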