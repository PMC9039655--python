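"""End-to-end pipeline orchestration and report arithmetic.

Drives synthetic-cohort generation, capture read simulation, mapping,
coverage profiling and drop calling, genotype clustering over a called drop,
probe-efficacy scoring, and unmapped-read attribution from a single
RunConfig; accounts reads at every stage in a per-accession statistics
table; and provides the small report arithmetic (one-decimal percentages,
CDS-to-protein length) used in the human-readable outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr
from . import cluster as clus
from . import coverage as cov
from . import efficacy as eff
from . import mapper as mapmod
from . import synthcohort as sc
from .capture import CaptureModel, ReadSet, simulate_reads

log = logging.getLogger("introcap")


# ---------------------------------------------------------------------------
# Report arithmetic
# ---------------------------------------------------------------------------


def compute_percent(numerator: float, denominator: float) -> float | None:
    """100 * numerator / denominator, rounded half-up to one decimal.

    Returns None (UNDEFINED) when the denominator is zero.
    """
    if denominator == 0:
        return None
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def protein_length_from_cds(cds_len_bp: int) -> int:
    """Amino acids encoded by a CDS (terminal stop codon excluded)."""
    if cds_len_bp % 3 != 0:
        raise ValueError(f"CDS length {cds_len_bp} is not divisible by 3")
    return cds_len_bp // 3 - 1


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class ChromSpec:
    name: str
    length: int
    centromere_frac: float


@dataclass
class SegmentSpec:
    chrom: str
    start: int
    end: int
    donor: str  # donor name or "DELETION"


@dataclass
class AccessionSpec:
    name: str
    segments: list[SegmentSpec] = field(default_factory=list)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 42
    scale: float = 100.0  # informational: 1:scale of the full wheat genome
    chromosomes: list[ChromSpec] = field(default_factory=list)
    donors: list[sc.DonorSpec] = field(default_factory=list)
    accessions: list[AccessionSpec] = field(default_factory=list)
    # capture + sequencing
    capture_tolerance: float = 0.10
    capture_mode: str = "step"
    capture_steepness: float = 80.0
    n_probes: int = 7200
    probe_len: int = 120
    gradient_slope: float = 2.0
    mean_depth: float = 15.0
    frag_mean: float = 300.0
    frag_sd: float = 30.0
    read_len: int = 150
    err_rate: float = 0.001
    adapter_rate: float = 0.0  # synthetic trimming loss; 0 = pass-through
    # mapping
    k: int = 13
    max_mismatch_frac: float = 0.06
    unique_margin: int = 1
    # coverage + drops
    bin_width: int = 50_000
    alpha: float = 0.5
    min_bins: int = 2
    # genotyping
    n_markers: int = 1200
    genotype_err: float = 0.01
    genotype_missing: float = 0.02
    # attribution
    attribution_accession: str | None = None  # default: first carrier
    attribution_chrom: str | None = None  # default: first carrier's drop chrom
    attribution_donor: str | None = None
    n_attribution_reads: int = 600
    min_identity: float = 0.80
    ambiguity_margin: float = 0.02
    word_size: int = 11
    # outputs
    write_reads: bool = False
    write_genomes: bool = False

    def capture_model(self) -> CaptureModel:
        return CaptureModel(self.capture_tolerance, self.capture_mode, self.capture_steepness)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["chromosomes"] = [ChromSpec(**c) for c in raw.get("chromosomes", [])]
        raw["donors"] = [sc.DonorSpec(**d) for d in raw.get("donors", [])]
        raw["accessions"] = [
            AccessionSpec(a["name"], [SegmentSpec(**s) for s in a.get("segments", [])])
            for a in raw.get("accessions", [])
        ]
        return cls(**raw)


def demo_config(seed: int = 42) -> RunConfig:
    """The default demo cohort: a 1:100-scale stand-in for the 12-accession
    study, with two tertiary whole-short-arm carriers (the 1RS analogue), a
    long-arm tertiary drop, a primary-genepool segment that should NOT drop,
    and a deletion/introgression equivalence pair."""
    cfg = RunConfig(seed=seed)
    cfg.chromosomes = [
        ChromSpec("chr1", 6_000_000, 0.40),  # short arm = first 2.4 Mb
        ChromSpec("chr2", 7_000_000, 0.45),
        ChromSpec("chr3", 5_000_000, 0.50),
    ]
    cfg.donors = [
        sc.DonorSpec("donor_primary", "primary", sc.TIER_DIVERGENCE["primary"], 0.0, seed + 11),
        sc.DonorSpec("donor_secondary", "secondary", sc.TIER_DIVERGENCE["secondary"], 0.0, seed + 12),
        sc.DonorSpec("donor_tertiary", "tertiary", sc.TIER_DIVERGENCE["tertiary"], 0.0, seed + 13),
    ]
    arm = SegmentSpec("chr1", 0, 2_400_000, "donor_tertiary")
    cfg.accessions = [
        AccessionSpec("W01", [arm]),
        AccessionSpec(
            "W02",
            [arm, SegmentSpec("chr2", 3_600_000, 4_100_000, "donor_primary")],
        ),
        AccessionSpec("W03", [SegmentSpec("chr2", 5_950_000, 6_800_000, "donor_tertiary")]),
        AccessionSpec("W04", [SegmentSpec("chr3", 3_500_000, 3_900_000, "donor_tertiary")]),
        AccessionSpec("W05", [SegmentSpec("chr3", 3_500_000, 3_900_000, sc.DELETION)]),
        AccessionSpec("W06", []),
    ]
    cfg.attribution_accession = "W01"
    cfg.attribution_chrom = "chr1"
    cfg.attribution_donor = "donor_tertiary"
    return cfg


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    """Everything a downstream consumer needs from one pipeline run."""

    config: RunConfig
    reference: sc.ReferenceGenome
    donors: dict[str, sc.DonorGenome]
    mosaics: list[sc.MosaicGenome]
    probes: sc.ProbeSet
    mapping: dict[str, mapmod.MappingResult]
    read_stats: pd.DataFrame
    profiles: list[cov.CoverageProfile]
    normalized: pd.DataFrame
    calls: list[cov.DropCall]
    genotypes: sc.GenotypeMatrix
    drop_similarity: pd.DataFrame | None
    drop_dendrogram: clus.Dendrogram | None
    drop_interval: tuple[str, int, int] | None
    unmapped_attribution: attr.AttributionTable | None
    mapped_attribution: attr.AttributionTable | None
    manifest: dict


def build_cohort(cfg: RunConfig):
    """Generate reference, donors, mosaics, probes, genotypes."""
    reference = sc.make_reference(
        [c.length for c in cfg.chromosomes],
        [c.centromere_frac for c in cfg.chromosomes],
        seed=cfg.seed,
        names=[c.name for c in cfg.chromosomes],
    )
    donors = {d.name: sc.make_donor(reference, d) for d in cfg.donors}
    mosaics = []
    for acc in cfg.accessions:
        segments = [
            sc.IntrogressionSegment(s.chrom, s.start, s.end, s.donor)
            for s in acc.segments
        ]
        mosaics.append(sc.make_accession(reference, donors, segments, acc.name))
    probes = sc.design_probes(
        reference, cfg.n_probes, cfg.probe_len, cfg.gradient_slope, seed=cfg.seed + 1
    )
    genotypes = sc.simulate_genotypes(
        reference,
        mosaics,
        cfg.n_markers,
        cfg.genotype_err,
        cfg.genotype_missing,
        seed=cfg.seed + 2,
    )
    return reference, donors, mosaics, probes, genotypes


def truth_intervals(mosaics: list[sc.MosaicGenome]) -> list[tuple[str, int, int, str]]:
    """Truth segments as BED-style tuples labelled accession|donor."""
    out = []
    for m in mosaics:
        for seg in m.truth:
            out.append((seg.chrom, seg.start, seg.end, f"{m.accession}|{seg.donor}"))
    return out


def read_stats_table(
    cfg: RunConfig, mapping: dict[str, mapmod.MappingResult], seed: int
) -> pd.DataFrame:
    """Per-accession read accounting with internally consistent percentages."""
    rng = np.random.default_rng(seed + 7)
    rows = []
    for acc, res in mapping.items():
        total = res.counts["total_reads"]
        if cfg.adapter_rate > 0 and total:
            trimmed = total - int(rng.binomial(total, cfg.adapter_rate))
        else:
            trimmed = total
        mapped = res.counts["mapped_pairs"]
        unique = res.counts["uniquely_mapped_pairs"]
        rows.append(
            {
                "accession": acc,
                "total_reads": total,
                "trimmed_reads": trimmed,
                "trimmed_pct": compute_percent(trimmed, total),
                "mapped_pairs": mapped,
                "uniquely_mapped_pairs": unique,
                "unique_pct_of_mapped": compute_percent(unique, mapped),
            }
        )
    return pd.DataFrame(rows)


def _largest_tertiary_call(
    calls: list[cov.DropCall], cfg: RunConfig
) -> tuple[str, int, int] | None:
    """Drop interval used for the clustering stage (largest call, by span)."""
    acc = cfg.attribution_accession
    cand = [c for c in calls if acc is None or c.accession == acc]
    if not cand:
        cand = calls
    if not cand:
        return None
    best = max(cand, key=lambda c: c.length)
    return best.chrom, best.start, best.end


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute every stage; optionally write all artifacts plus a manifest."""
    manifest: dict = {"seed": cfg.seed, "artifacts": [], "status": "running"}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def artifact(name: str, writer) -> None:
        if out is None:
            return
        path = out / name
        writer(path)
        manifest["artifacts"].append(name)

    log.info("generating cohort (seed=%d)", cfg.seed)
    reference, donors, mosaics, probes, genotypes = build_cohort(cfg)
    model = cfg.capture_model()

    artifact("truth.bed", lambda p: sc.write_truth_bed(p, mosaics))
    artifact("probes.bed", lambda p: sc.write_probe_bed(p, probes))
    artifact("genotypes.tsv", lambda p: sc.write_genotype_tsv(p, genotypes))
    if cfg.write_genomes:
        artifact("reference.fasta", lambda p: sc.write_fasta(p, reference.chromosomes))
        for name, donor in donors.items():
            artifact(f"{name}.fasta", lambda p, d=donor: sc.write_fasta(p, d.chromosomes))
        for m in mosaics:
            artifact(f"{m.accession}.fasta", lambda p, mm=m: sc.write_fasta(p, mm.chromosomes))

    log.info("simulating reads and mapping %d accessions", len(mosaics))
    index = mapmod.build_index(reference, cfg.k)
    mapping: dict[str, mapmod.MappingResult] = {}
    readsets: dict[str, ReadSet] = {}
    for i, mosaic in enumerate(mosaics):
        reads = simulate_reads(
            mosaic,
            probes,
            model,
            cfg.mean_depth,
            cfg.frag_mean,
            cfg.frag_sd,
            cfg.read_len,
            cfg.err_rate,
            seed=cfg.seed + 100 + i,
        )
        if cfg.write_reads and out is not None:
            reads.write_fastq(out / mosaic.accession)
            manifest["artifacts"] += [
                f"{mosaic.accession}_1.fastq",
                f"{mosaic.accession}_2.fastq",
            ]
        mapping[mosaic.accession] = mapmod.map_reads(
            reads, index, cfg.max_mismatch_frac, cfg.unique_margin, cfg.frag_mean, cfg.frag_sd
        )
        readsets[mosaic.accession] = reads
        log.info(
            "  %s: %d pairs, %d uniquely mapped",
            mosaic.accession,
            reads.n_pairs,
            mapping[mosaic.accession].counts["uniquely_mapped_pairs"],
        )

    stats = read_stats_table(cfg, mapping, cfg.seed)
    artifact("read_stats.tsv", lambda p: stats.to_csv(p, sep="\t", index=False))

    log.info("profiling coverage (bin width %d)", cfg.bin_width)
    profiles = [
        cov.profile_accession(mapping[m.accession], reference, cfg.bin_width)
        for m in mosaics
    ]
    normalized = cov.normalize_profiles(profiles)
    artifact("coverage.tsv", lambda p: normalized.to_csv(p, sep="\t", index=False))

    calls = cov.call_drops(normalized, cfg.alpha, cfg.min_bins)
    calls = cov.annotate_drops(calls, truth_intervals(mosaics))
    artifact(
        "drops.bed",
        lambda p: pd.DataFrame(
            [(c.chrom, c.start, c.end, c.accession) for c in calls]
        ).to_csv(p, sep="\t", header=False, index=False),
    )
    artifact("drops_annotated.tsv", lambda p: cov.drops_frame(calls).to_csv(p, sep="\t", index=False))

    # clustering over the markers spanning the principal called drop
    drop_iv = _largest_tertiary_call(calls, cfg)
    drop_similarity = None
    dendro = None
    if drop_iv is not None:
        chrom, start, end = drop_iv
        subset = genotypes.subset(chrom, start, end)
        if subset:
            drop_similarity = clus.similarity_to_reference(
                genotypes, "REF", subset, f"{chrom}:{start}-{end}"
            )
            dist = clus.distance_matrix(genotypes, subset)
            if not dist.isna().to_numpy().any():
                dendro = clus.upgma(dist)
                artifact("dendrogram.nwk", lambda p: clus.write_newick(p, dendro))
            artifact(
                "similarity.tsv",
                lambda p: drop_similarity.to_csv(p, sep="\t", index=False),
            )

    # attribution: mapped vs unmapped reads of the designated accession
    unmapped_attr = mapped_attr = None
    acc = cfg.attribution_accession
    if acc is not None and acc in mapping:
        unmapped_attr, mapped_attr = attribute_accession(cfg, reference, donors, readsets[acc], mapping[acc])
        artifact(
            "attribution_unmapped.tsv",
            lambda p: unmapped_attr.table.to_csv(p, sep="\t", index=False),
        )
        artifact(
            "attribution_summary.tsv",
            lambda p: pd.concat(
                [
                    unmapped_attr.summary.assign(read_class="unmapped"),
                    mapped_attr.summary.assign(read_class="mapped"),
                ]
            ).to_csv(p, sep="\t", index=False),
        )

    manifest["status"] = "complete"
    if out is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return RunResult(
        cfg,
        reference,
        donors,
        mosaics,
        probes,
        mapping,
        stats,
        profiles,
        normalized,
        calls,
        genotypes,
        drop_similarity,
        dendro,
        drop_iv,
        unmapped_attr,
        mapped_attr,
        manifest,
    )


def attribute_accession(
    cfg: RunConfig,
    reference: sc.ReferenceGenome,
    donors: dict[str, sc.DonorGenome],
    reads: ReadSet,
    result: mapmod.MappingResult,
) -> tuple[attr.AttributionTable, attr.AttributionTable]:
    """Classify a sample of unmapped and of mapped mates against a
    reference-vs-donor panel restricted to the focal chromosome."""
    chrom = cfg.attribution_chrom or reference.names[0]
    donor_name = cfg.attribution_donor or cfg.donors[-1].name
    panel = {
        "reference": reference.chromosomes[chrom],
        donor_name: donors[donor_name].chromosomes[chrom],
    }
    indexes = attr.build_panel(panel, cfg.word_size)

    mates = (reads.mate1, reads.mate2)
    unmapped: dict[str, np.ndarray] = {}
    mapped: dict[str, np.ndarray] = {}
    aligned_chrom = dict(
        zip(
            zip(result.alignments["pair_id"], result.alignments["mate"]),
            result.alignments["chrom"],
        )
    )
    for i, pid in enumerate(result.pair_ids):
        for m in (0, 1):
            rid = f"{pid}/{m + 1}"
            if result.status[i, m] == mapmod.UNMAPPED and len(unmapped) < cfg.n_attribution_reads:
                unmapped[rid] = mates[m][i]
            elif (
                result.status[i, m] == mapmod.UNIQUE
                and aligned_chrom.get((pid, m + 1)) == chrom
                and len(mapped) < cfg.n_attribution_reads
            ):
                mapped[rid] = mates[m][i]
    kw = dict(
        min_identity=cfg.min_identity,
        ambiguity_margin=cfg.ambiguity_margin,
        word_size=cfg.word_size,
    )
    return (
        attr.classify_reads(unmapped, indexes, **kw),
        attr.classify_reads(mapped, indexes, **kw),
    )


def probe_divergence_sweep(
    reference: sc.ReferenceGenome,
    probes: sc.ProbeSet,
    divergences: list[float],
    target_chrom: str | None = None,
    target_span: int = 200_000,
    seed: int = 0,
    min_identity: float = 0.80,
) -> pd.DataFrame:
    """Score one probe subset against targets at increasing divergence.

    Reproduces the in-silico capture-efficacy pattern: the number of probes
    with a hit and the mean best-hit identity both decay as the target
    diverges from the probes' source.
    """
    chrom = target_chrom or reference.names[0]
    ref_seq = reference.chromosomes[chrom][:target_span]
    sub = probes.probes[
        (probes.probes["chrom"] == chrom) & (probes.probes["end"] <= target_span)
    ]
    probe_seqs = {pid: probes.sequences[pid] for pid in sub["probe_id"]}
    rows = []
    for i, d in enumerate(divergences):
        spec = sc.DonorSpec(f"sweep_{d}", "tertiary" if d > 0.08 else "primary", d, 0.0, seed + i)
        rng = np.random.default_rng(spec.seed)
        from ._seq import mutate_substitutions

        target = mutate_substitutions(ref_seq, d, rng)
        summary, _ = eff.probe_hits(probe_seqs, target, min_identity=min_identity)
        rows.append(
            {
                "divergence": d,
                "n_probes": summary.n_probes,
                "n_hits": summary.n_hits,
                "n_probes_with_hit": summary.n_probes_with_hit,
                "n_single_hit_probes": summary.n_single_hit_probes,
                "mean_best_identity": summary.mean_best_identity,
            }
        )
    return pd.DataFrame(rows)
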