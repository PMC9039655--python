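"""Zero-inclusive binned coverage, cohort normalization, and drop calling.

Depth is computed from uniquely mapped, properly paired reads only; every
base — including zero-coverage bases — enters the fixed-width bin means
(5 Mb at full wheat scale, scaled with the genome in the demo cohort).
Coverage drops are called *relative to the cohort*: each accession is
library-size scaled, divided by the per-bin cohort median, and maximal runs
of consecutive low-ratio bins become DropCall intervals, which can then be
annotated against a BED of known introgressions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapper import MappingResult
from .synthcohort import ReferenceGenome


@dataclass
class CoverageProfile:
    """Binned mean depth for one accession (zero-inclusive)."""

    accession: str
    bins: pd.DataFrame  # chrom, bin_start, bin_end, mean_depth
    bin_width: int

    @property
    def genome_mean(self) -> float:
        lengths = (self.bins["bin_end"] - self.bins["bin_start"]).to_numpy()
        return float((self.bins["mean_depth"].to_numpy() * lengths).sum() / lengths.sum())


@dataclass
class DropCall:
    """A contiguous low-coverage interval in one accession."""

    accession: str
    chrom: str
    start: int
    end: int
    mean_ratio: float
    n_bins: int
    annotations: list[dict] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def depth_from_starts(starts: np.ndarray, read_len: int, chrom_len: int) -> np.ndarray:
    """Per-base depth from fixed-length read start positions."""
    starts = np.asarray(starts, dtype=np.int64)
    if len(starts) and (starts.min() < 0 or starts.max() + read_len > chrom_len):
        raise ValueError("alignment beyond chromosome bounds")
    diff = np.zeros(chrom_len + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + read_len, -1)
    return np.cumsum(diff[:-1])


def depth_per_base(
    result: MappingResult, chrom: str, chrom_len: int
) -> np.ndarray:
    """Per-base depth from uniquely mapped, properly paired mates.

    Each mate contributes independently (overlapping mates count twice).
    """
    aln = result.alignments
    starts = aln.loc[aln["chrom"] == chrom, "start"].to_numpy(dtype=np.int64)
    return depth_from_starts(starts, result.read_len, chrom_len)


def bin_coverage(depth: np.ndarray, bin_width: int) -> pd.DataFrame:
    """Mean depth over fixed-width bins; the last bin uses its true length."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    n = len(depth)
    edges = np.arange(0, n, bin_width, dtype=np.int64)
    sums = np.add.reduceat(depth, edges) if n else np.empty(0)
    ends = np.minimum(edges + bin_width, n)
    means = sums / (ends - edges)
    return pd.DataFrame(
        {"bin_start": edges, "bin_end": ends, "mean_depth": means}
    )


def profile_accession(
    result: MappingResult, reference: ReferenceGenome, bin_width: int
) -> CoverageProfile:
    """Binned coverage across all chromosomes for one accession."""
    frames = []
    for chrom in reference.names:
        depth = depth_per_base(result, chrom, reference.length(chrom))
        df = bin_coverage(depth, bin_width)
        df.insert(0, "chrom", chrom)
        frames.append(df)
    return CoverageProfile(result.accession, pd.concat(frames, ignore_index=True), bin_width)


def normalize_profiles(profiles: list[CoverageProfile]) -> pd.DataFrame:
    """Cohort-relative per-bin coverage ratios.

    Each accession is first scaled by its genome-wide mean depth (library
    size), then each bin is divided by the cohort *median* of scaled values
    (robust when several accessions share a drop). Bins whose cohort median
    is 0 get an undefined ratio (NaN, ``defined`` False).

    Returns a tidy frame: accession, chrom, bin_start, bin_end, mean_depth,
    scaled, ratio, defined.
    """
    if len(profiles) < 3:
        raise ValueError("cohort normalization needs at least 3 accessions")
    base = profiles[0].bins[["chrom", "bin_start", "bin_end"]]
    for p in profiles[1:]:
        if not p.bins[["chrom", "bin_start", "bin_end"]].equals(base):
            raise ValueError("profiles have inconsistent binning")
    frames = []
    for p in profiles:
        df = p.bins.copy()
        df.insert(0, "accession", p.accession)
        mean = p.genome_mean
        df["scaled"] = df["mean_depth"] / mean if mean > 0 else np.nan
        frames.append(df)
    tidy = pd.concat(frames, ignore_index=True)
    med = tidy.groupby(["chrom", "bin_start"])["scaled"].transform("median")
    tidy["ratio"] = np.where(med > 0, tidy["scaled"] / med, np.nan)
    tidy["defined"] = med > 0
    return tidy


def call_drops(
    normalized: pd.DataFrame, alpha: float = 0.5, min_bins: int = 2
) -> list[DropCall]:
    """Maximal runs of >= min_bins consecutive bins with ratio < alpha.

    Undefined bins break runs.
    """
    calls: list[DropCall] = []
    for (acc, chrom), grp in normalized.groupby(["accession", "chrom"], sort=False):
        grp = grp.sort_values("bin_start")
        flag = (grp["defined"] & (grp["ratio"] < alpha)).to_numpy()
        ratios = grp["ratio"].to_numpy()
        starts = grp["bin_start"].to_numpy()
        ends = grp["bin_end"].to_numpy()
        i = 0
        while i < len(flag):
            if not flag[i]:
                i += 1
                continue
            j = i
            while j < len(flag) and flag[j]:
                j += 1
            if j - i >= min_bins:
                calls.append(
                    DropCall(
                        accession=acc,
                        chrom=chrom,
                        start=int(starts[i]),
                        end=int(ends[j - 1]),
                        mean_ratio=float(np.mean(ratios[i:j])),
                        n_bins=j - i,
                    )
                )
            i = j
    return calls


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, float]:
    """Overlap length and Jaccard |A∩B| / |A∪B| of two half-open intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter, inter / union if union else 0.0


def centromere_distance_correlation(
    profile: CoverageProfile, reference: ReferenceGenome
) -> tuple[float, float]:
    """Spearman correlation of bin depth vs normalized centromere distance.

    Captures the telomere-to-centromere coverage gradient: with probes
    densest near telomeres, depth should rise with distance from the
    centromere (rho > 0).
    """
    from scipy import stats

    dist, depth = [], []
    for chrom, grp in profile.bins.groupby("chrom", sort=False):
        cen = reference.centromeres[chrom]
        L = reference.length(chrom)
        mid = (grp["bin_start"] + grp["bin_end"]).to_numpy() / 2.0
        arm_len = np.where(mid < cen, cen, L - cen)
        dist.extend((np.abs(mid - cen) / arm_len).tolist())
        depth.extend(grp["mean_depth"].tolist())
    rho, p = stats.spearmanr(dist, depth)
    return float(rho), float(p)


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Parse a minimal BED (chrom, start, end[, name]); 0-based half-open."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start >= end:
                    raise ValueError
            except (IndexError, ValueError):
                raise ValueError(f"malformed BED line {ln}: {line!r}") from None
            name = parts[3] if len(parts) > 3 else f"interval_{ln}"
            out.append((chrom, start, end, name))
    return out


def annotate_drops(
    calls: list[DropCall], known: list[tuple[str, int, int, str]]
) -> list[DropCall]:
    """Attach all overlapping known intervals (overlap length + Jaccard)."""
    for call in calls:
        call.annotations = []
        for chrom, start, end, name in known:
            if chrom != call.chrom:
                continue
            ov, jac = interval_overlap((call.start, call.end), (start, end))
            if ov > 0:
                call.annotations.append(
                    {"label": name, "overlap": ov, "jaccard": jac}
                )
    return calls


def drops_frame(calls: list[DropCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        labels = ";".join(a["label"] for a in c.annotations)
        rows.append(
            (c.accession, c.chrom, c.start, c.end, c.n_bins, c.mean_ratio, labels)
        )
    return pd.DataFrame(
        rows,
        columns=["accession", "chrom", "start", "end", "n_bins", "mean_ratio", "known"],
    )


def plot_coverage(normalized: pd.DataFrame, accession: str, path) -> None:
    """Per-chromosome binned coverage plot for one accession."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = normalized[normalized["accession"] == accession]
    chroms = sub["chrom"].unique()
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2.2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        grp = sub[sub["chrom"] == chrom]
        ax.fill_between(grp["bin_start"] / 1e6, grp["mean_depth"], step="post", alpha=0.7)
        ax.set_ylabel("depth")
        ax.set_title(f"{accession} {chrom}")
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
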