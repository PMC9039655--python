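# Methods

## Model overview

`introcap` models the chain of events by which an alien chromosome segment
in an inbred hexaploid accession becomes visible — or invisible — to
exome-capture sequencing:

```
mosaic genome → probe hybridization → fragments/reads → unique alignment
             → binned depth → cohort-relative ratio → drop calls
```

Two divergence-dependent filters shape the signal. **Capture**: a probe
hybridizes to its homologous target with probability `p(d)` where `d` is the
realized per-base mismatch fraction over the probe window; in `step` mode
`p = 1 iff d ≤ T` (default tolerance `T = 0.10`, the conservative end of
vendor figures), in `logistic` mode `p = 1/(1 + e^{k(d−T)})` with
steepness `k = 80` so the curve falls from 0.9 to 0.1 over ≈ 5.5 percentage
points of divergence. Both modes are provided because the realized
capture-vs-divergence curve is not published; the step model is the default.
The capture decision uses the mean divergence over the whole probe window,
not the longest mismatch run, matching how hybridization tolerance is
usually quoted. **Alignment**: reads are accepted at a locus only within a
mismatch budget `m` (default 0.06 of read length) and only counted when the
best locus beats the second best by ≥ `unique_margin` (default 1) mismatch
and the pair is properly oriented within `frag_mean + 4·frag_sd`.

A consequence worth stating explicitly: at the tertiary tier (d = 0.12) the
*realized* divergence of a 120 bp probe is binomial with SD ≈ 0.03, so
roughly a quarter of tertiary probes fall at or below a 0.10 tolerance and
do capture. Their reads then fail the 6% mapping budget. This is exactly the
two-stage loss the pipeline is built to expose: tertiary segments produce
near-zero *unique-mapped* coverage while still shedding captured-but-
unmapped reads that the attribution stage traces back to the donor.

## Synthetic cohort (what it emulates, and what it does not)

The generator is a statistical stand-in for a 12-accession wheat study at
1:100 scale: three chromosomes of 6/7/5 Mb (centromeres at fractions
0.40/0.45/0.50), 50 kb coverage bins (5 Mb at full scale), six accessions,
and segment sizes scaled the same way — a 2.4 Mb whole-short-arm swap
(≈ 240 Mb full scale), a 0.85 Mb long-arm segment (≈ 85 Mb), a 0.4 Mb
segment and an equal-span deletion (≈ 40 Mb), and a 0.5 Mb primary-genepool
segment that should *not* produce a drop. Donor tiers are fixed calibration
choices — primary 1.5%, secondary 6%, tertiary 12% substitutions/base —
chosen to bracket the mapper budget (6%) and capture tolerance (10%); true
wheat–relative divergences are not published and these values are flagged
as calibration, not measurement.

Sequences are i.i.d. uniform bases. Donor genomes substitute each base
independently (optionally with geometric-length indels, tracked by a
reference→donor coordinate lift); mosaics splice donor sequence at identical
reference coordinates (perfect synteny), and deletions remove sequence while
recording the coordinate lift. Accessions are fully homozygous; HET calls
arise only via the `p_alt = 0.9` draw inside introgressions and the 1% call
error. Probes (7,200 × 120 bp) are placed with linear density
`1 + slope·x` in normalized centromere→telomere distance `x` (slope 2),
giving the telomere-biased gradient; the probe count keeps every 50 kb bin
populated (≈ 20 probes expected, ≥ ~10 near centromeres), as in real capture
designs where a 5 Mb bin holds hundreds of probes. Mean target depth is 15,
reads are 2×150 bp from Normal(300, 30) fragments, sequencing error 0.1%,
genotype matrix 1,200 markers with 1% error and 2% missingness.

Not modelled (deliberately): recombination, repeat families, polyploid
homoeologues, GC/PCR bias, off-target capture, base-quality variation
(qualities are constant Q30), gene annotation. Passing tests therefore show
that the *detection logic* is correct under the stated divergence geometry —
not that real wheat repeats or homoeologous mapping noise are handled; on
real data the uniqueness filter has far more work to do, and drop calls will
be noisier than the near-binary ratios seen here.

## Read-count calibration

The per-probe pair count is Poisson, thinned by `p(d)`. The Poisson rate is
calibrated so the *expected depth over probe-covered bases* equals
`mean_depth`: one pair deposits `2·read_len` sequenced bases over a roughly
`frag_mean`-wide footprint centred on its probe, so closely spaced probes
add depth to each other's bases. The rate divides `mean_depth` by the mask
average of `(2·read_len)/(frag_mean·probe_len) × Σ` probe-window occupancy
over the fragment window — a closed-form correction for footprint overlap
(fragment-length randomness cancels to first order because the mate gap for
long fragments offsets the mate overlap for short ones).

## Numerical and algorithmic choices

- **Coordinates** are 0-based half-open everywhere internally and in BED;
  1-based inclusive appears only in prose.
- **Mapper**: exact k-mer seeds (k = 13) at non-overlapping offsets tiling
  the read plus one end-anchored seed, so any locus within 10 mismatches of
  a 150 bp read is guaranteed a clean seed (pigeonhole over 11 disjoint
  seeds); candidates are scored by full-read Hamming distance on both
  strands. Mapping is deterministic; score ties between distinct loci are
  always non-unique. Alignment is ungapped by design — indel-bearing or
  highly diverged reads go unmapped and are handed to attribution; gapped
  comparison lives in the locus aligner.
- **Coverage**: depth counts each mate independently (overlapping mates
  count twice); bin means include zero-depth bases and the short final bin
  uses its true length, so `Σ(mean × len) = Σ depth` exactly.
- **Normalization**: per-accession library-size scaling (genome-wide mean),
  then per-bin division by the cohort *median* of scaled values — median
  rather than mean so that a drop shared by a minority of accessions (three
  1RS carriers in the motivating study) does not drag the baseline down.
  Cohorts of fewer than three accessions are refused. Bins with zero cohort
  median are UNDEFINED and break drop runs. The per-accession normalization
  used for the published coverage figures is unstated; this choice is
  isolated in `normalize_profiles`.
- **Drop calling**: `alpha = 0.5`, `min_bins = 2` are explicit defaults (the
  original drops were judged visually); both are CLI flags.
- **UPGMA**: average linkage; tie-breaking picks the lexicographically
  smallest pair of cluster keys (sorted leaf-name tuples); node heights are
  half the merge distance, so cophenetic distances reproduce ultrametric
  inputs exactly. IBS distance is not metric under missingness; triangle
  violations are reported, not rejected. HET is its own category (HET vs
  HOM_REF is a mismatch) — configurable, since the published similarity
  statistic does not say how heterozygotes were treated.
- **Hit engine**: a hit covers ≥ 80% of the probe at ≥ 80% identity
  (identity = matches / probe length), word size 11, both strands — explicit
  stand-ins for unstated local-search defaults; the 0.80 floor echoes the
  widest quoted capture tolerance.
- **Global aligner**: Needleman–Wunsch with match +1 / mismatch −1 /
  gap −2 (linear), row-vectorized DP with a running-max trick for the
  in-row gap recurrence; traceback prefers diagonal > up > left, making the
  reported alignment (and indel positions) deterministic. Quadratic memory
  restricts it to loci ≤ ~100 kb.
- **Attribution**: best-hit label must reach 80% identity; top-two
  candidates within 0.02 are AMBIGUOUS; the panel is an explicit small set
  of candidate genomes restricted to the focal chromosome (the published
  comparison likewise used a two-sequence database), replacing any large
  translated-database search.
- **Trimming** is modelled as a pass-through count (100%) unless a synthetic
  adapter-contamination rate is configured — quality trimming is a
  third-party preprocessing step, not part of the detection logic. "Mapped
  pairs" counts pairs while "total reads" counts reads, matching the usual
  read-accounting convention. A mate that maps uniquely but whose pair is
  improper is reported in the "multimapped" id set so the three id sets
  partition the input reads.

## Problem sizes

The demo cohort (18 Mb of genome across six accessions, ≈ 100k read pairs
per accession) runs the full pipeline in ≈ 2 minutes on one CPU; the unit
and property suites use 5–300 kb genomes and run in seconds. These sizes
were chosen so the whole-arm drop spans 48 bins and the smallest detectable
segment spans 8, preserving the drop/bin geometry of the full-scale study
at desk scale.

## Known limitations

- Uniform base composition and absence of repeats make unique mapping far
  easier than in real wheat; the uniqueness margin is exercised only by the
  synthetic duplication tests.
- The capture model treats probes independently; competitive hybridization
  and off-target pull-down are ignored.
- Attribution identity is ungapped; a donor segment with dense indels would
  be under-attributed (it would surface as NO_HIT).
- Genotype simulation ties marker state directly to segment truth; linkage
  disequilibrium and ascertainment bias of real array markers are not
  modelled, so real-data similarity percentages will sit far from the
  near-0%/near-100% extremes seen here (the published contrast was 13.3%
  vs 59.1%) even though the direction is the same.
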